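"""Exception hierarchy for screen processing.

Every error raised by the library derives from :class:`ScreenError`, so callers
(and the CLI) can distinguish pipeline failures from programming errors.
"""


class ScreenError(Exception):
    """Base class for all screen-processing errors."""


class FormatError(ScreenError):
    """A file or table does not conform to the expected schema."""


class IntegrityError(ScreenError):
    """A dataset violates an internal invariant (duplicates, bad stage, ...)."""


class ProcessingError(ScreenError):
    """A pipeline stage cannot be applied to the given data."""


class AssignmentError(ScreenError):
    """A plate cannot be assigned to a batch."""


class ConfigError(ScreenError):
    """Inconsistent simulation or pipeline configuration."""


class GeneNotFoundError(ScreenError):
    """A requested gene identifier is not present in the dataset."""
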