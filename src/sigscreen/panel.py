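"""Probe panel definitions.

The screen measures an eight-mRNA panel per well: six *signature* probes whose
joint expression pattern proxies disruption of the KSR1 scaffold, and two
*housekeeping* probes (PPIB, HPRT) assumed invariant to the perturbation and
used for per-well cell-number correction via their geometric mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

from .errors import IntegrityError

SIGNATURE = "signature"
HOUSEKEEPING = "housekeeping"


@dataclass(frozen=True)
class Probe:
    """One mRNA probe of the panel.

    Parameters
    ----------
    name
        Probe (gene) symbol, unique within a panel.
    role
        Either ``"signature"`` or ``"housekeeping"``.
    entrez_id
        Optional Entrez gene identifier, stored as an annotation only.
    """

    name: str
    role: str
    entrez_id: Optional[int] = None

    def __post_init__(self) -> None:
        if self.role not in (SIGNATURE, HOUSEKEEPING):
            raise IntegrityError(f"unknown probe role: {self.role!r}")


@dataclass(frozen=True)
class ProbePanel:
    """An ordered collection of probes with exactly two housekeeping members."""

    probes: tuple[Probe, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        names = [p.name for p in self.probes]
        if len(set(names)) != len(names):
            raise IntegrityError("probe names must be unique within a panel")
        n_hk = sum(p.role == HOUSEKEEPING for p in self.probes)
        if n_hk != 2:
            raise IntegrityError(
                f"panel must contain exactly two housekeeping probes, found {n_hk}"
            )

    def __iter__(self) -> Iterator[Probe]:
        return iter(self.probes)

    def __len__(self) -> int:
        return len(self.probes)

    @property
    def names(self) -> list[str]:
        return [p.name for p in self.probes]

    @property
    def signature_names(self) -> list[str]:
        return [p.name for p in self.probes if p.role == SIGNATURE]

    @property
    def housekeeping_names(self) -> list[str]:
        return [p.name for p in self.probes if p.role == HOUSEKEEPING]

    def __contains__(self, name: str) -> bool:
        return name in self.names


def default_panel() -> ProbePanel:
    """The screen's eight-probe panel.

    Signature probes are ordered as deposited (BNIP3L, NDRG1, ALDOC, LOXL2,
    BNIP3, ACSL5); this order defines the layout of every signature vector.
    Entrez identifiers are annotations carried verbatim from the screen's
    metadata (HPRT is listed there with a rodent identifier; it is not
    resolved here).
    """
    return ProbePanel(
        (
            Probe("BNIP3L", SIGNATURE, 665),
            Probe("NDRG1", SIGNATURE, 10397),
            Probe("ALDOC", SIGNATURE, 230),
            Probe("LOXL2", SIGNATURE, 4017),
            Probe("BNIP3", SIGNATURE, 664),
            Probe("ACSL5", SIGNATURE, 51703),
            Probe("PPIB", HOUSEKEEPING, 5479),
            Probe("HPRT", HOUSEKEEPING, 15452),
        )
    )


def panel_from_names(
    signature: Sequence[str], housekeeping: Sequence[str]
) -> ProbePanel:
    """Build a panel from plain probe-name lists (no Entrez annotations)."""
    return ProbePanel(
        tuple(Probe(n, SIGNATURE) for n in signature)
        + tuple(Probe(n, HOUSEKEEPING) for n in housekeeping)
    )
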