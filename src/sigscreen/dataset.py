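"""Screen dataset container and canonical serialization.

A :class:`ScreenDataset` holds one well per row of a pandas DataFrame — plate,
batch, technical replicate, position, role, targeted-gene annotations, QC
flags, and one column per probe — together with the probe panel, the plate
layout and a processing-stage tag. Stages move strictly forward::

    raw -> bgsub -> geomean -> normalized_log2

The canonical on-disk form is a UTF-8 CSV (one row per well, one column per
probe) preceded by a single ``# stage=<stage>`` metadata line. The reader
tolerates common column-name variants of the identity fields.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Optional

import numpy as np
import pandas as pd

from .errors import AssignmentError, FormatError, IntegrityError
from .layout import (
    BLANK_COLUMNS,
    N_COLS,
    ROWS,
    BatchMap,
    PlateLayout,
    WellRole,
    default_layout,
)
from .panel import ProbePanel, default_panel


class Stage(str, enum.Enum):
    """Processing stage of a dataset (strictly forward transitions)."""

    raw = "raw"
    bgsub = "bgsub"
    geomean = "geomean"
    normalized_log2 = "normalized_log2"

    @property
    def order(self) -> int:
        return list(Stage).index(self)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: identity columns, in canonical order, preceding the probe columns
ID_COLUMNS = [
    "plate",
    "batch",
    "replicate",
    "row",
    "column",
    "role",
    "gene_symbol",
    "entrez_id",
    "flags",
]

_COLUMN_ALIASES = {
    "plate": {"plate", "plate_id", "plate_number", "platenumber", "plate number"},
    "batch": {"batch", "batch_id", "experimental_group", "group", "experimental group/batch"},
    "replicate": {"replicate", "rep", "technical_replicate", "replicate_id"},
    "row": {"row", "plate_row", "well_row"},
    "column": {"column", "col", "plate_column", "well_column"},
    "role": {"role", "well_role", "well_type"},
    "gene_symbol": {"gene_symbol", "gene", "symbol", "ncbi_gene_symbol", "gene symbol"},
    "entrez_id": {"entrez_id", "entrez", "entrez_gene_id", "entrez gene id", "gene_id"},
    "flags": {"flags", "qc_flags"},
}

AVG_REPLICATE = "avg"


@dataclass(frozen=True)
class WellRecord:
    """One well's identity and per-probe values."""

    plate_id: int
    batch_id: Optional[int]
    replicate: str
    row: str
    column: int
    role: WellRole
    gene_symbol: Optional[str]
    entrez_id: Optional[int]
    values: dict[str, float]
    stage: Stage
    flags: frozenset[str] = frozenset()


def _join_flags(flags: Iterable[str]) -> str:
    return ";".join(sorted(set(flags)))


def _split_flags(text: object) -> frozenset[str]:
    if text is None or (isinstance(text, float) and np.isnan(text)) or text == "":
        return frozenset()
    return frozenset(str(text).split(";"))


@dataclass
class ScreenDataset:
    """A collection of wells sharing a processing stage.

    The backing ``frame`` is the canonical in-memory representation; all
    pipeline operations are vectorized over it. ``(plate, replicate, row,
    column)`` is unique.
    """

    frame: pd.DataFrame
    panel: ProbePanel = field(default_factory=default_panel)
    stage: Stage = Stage.raw
    layout: PlateLayout = field(default_factory=default_layout)
    batches: Optional[BatchMap] = None

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ------------------------------------------------------

    def validate(self) -> None:
        df = self.frame
        missing = [c for c in ID_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"dataset frame missing columns: {missing}")
        for probe in self.panel.names:
            if probe not in df.columns:
                raise FormatError(f"dataset frame missing probe column {probe!r}")
        if len(df):
            bad_row = ~df["row"].isin(ROWS)
            bad_col = ~df["column"].between(1, N_COLS)
            if bad_row.any() or bad_col.any():
                raise IntegrityError(
                    f"{int(bad_row.sum())} wells with invalid row and "
                    f"{int(bad_col.sum())} with invalid column"
                )
            key = df[["plate", "replicate", "row", "column"]]
            if key.duplicated().any():
                dupes = key[key.duplicated()].head(3).to_dict("records")
                raise IntegrityError(f"duplicate well positions, e.g. {dupes}")
            if self.stage is Stage.raw:
                probe_vals = df[self.panel.names]
                if probe_vals.isna().any().any():
                    n = int(probe_vals.isna().any(axis=1).sum())
                    raise IntegrityError(
                        f"{n} wells missing probe values at stage=raw"
                    )

    # -- convenience -----------------------------------------------------

    @property
    def probe_names(self) -> list[str]:
        return self.panel.names

    @property
    def signature_names(self) -> list[str]:
        return self.panel.signature_names

    @property
    def housekeeping_names(self) -> list[str]:
        return self.panel.housekeeping_names

    @property
    def replicates(self) -> list[str]:
        return sorted(self.frame["replicate"].unique())

    def mask(self, role: WellRole | str) -> pd.Series:
        return self.frame["role"] == WellRole(role).value

    def with_frame(self, frame: pd.DataFrame, stage: Optional[Stage] = None) -> "ScreenDataset":
        """Copy of this dataset with a new frame, optionally advancing stage."""
        new_stage = self.stage if stage is None else stage
        if new_stage.order < self.stage.order:
            raise IntegrityError(
                f"stage transitions are forward-only: {self.stage} -> {new_stage}"
            )
        return replace(self, frame=frame, stage=new_stage)

    def advance(self, stage: Stage) -> "ScreenDataset":
        if stage.order <= self.stage.order:
            raise IntegrityError(
                f"stage transitions are forward-only: {self.stage} -> {stage}"
            )
        return replace(self, stage=stage)

    def add_flag(self, mask: pd.Series, flag: str) -> None:
        """Set ``flag`` on every well selected by boolean ``mask`` (in place)."""
        idx = self.frame.index[mask]
        current = self.frame.loc[idx, "flags"].map(_split_flags)
        self.frame.loc[idx, "flags"] = [
            _join_flags(f | {flag}) for f in current
        ]

    def flags_of(self, index) -> frozenset[str]:
        return _split_flags(self.frame.at[index, "flags"])

    def has_flag(self, flag: str) -> pd.Series:
        return self.frame["flags"].map(lambda t: flag in _split_flags(t))

    def records(self) -> Iterator[WellRecord]:
        for _, r in self.frame.iterrows():
            yield WellRecord(
                plate_id=int(r["plate"]),
                batch_id=None if pd.isna(r["batch"]) else int(r["batch"]),
                replicate=str(r["replicate"]),
                row=str(r["row"]),
                column=int(r["column"]),
                role=WellRole(r["role"]),
                gene_symbol=None if pd.isna(r["gene_symbol"]) else str(r["gene_symbol"]),
                entrez_id=None if pd.isna(r["entrez_id"]) else int(r["entrez_id"]),
                values={p: float(r[p]) for p in self.panel.names},
                stage=self.stage,
                flags=_split_flags(r["flags"]),
            )

    def sorted_frame(self) -> pd.DataFrame:
        df = self.frame
        order = df.sort_values(
            ["plate", "replicate", "row", "column"], kind="mergesort"
        ).index
        return df.loc[order, ID_COLUMNS + self.panel.names]


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def write_screen_csv(ds: ScreenDataset, path: str | Path) -> None:
    """Write a dataset as canonical CSV with a ``# stage=`` metadata line.

    Row order (plate, replicate, row, column) and column order are
    deterministic, so identical datasets serialize to identical bytes.
    """
    path = Path(path)
    df = ds.sorted_frame().copy()
    df["batch"] = df["batch"].astype("Int64")
    df["entrez_id"] = df["entrez_id"].astype("Int64")
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# stage={ds.stage.value}\n")
        df.to_csv(fh, index=False, lineterminator="\n")


def _canonicalize_columns(df: pd.DataFrame, panel: ProbePanel) -> pd.DataFrame:
    probe_by_lower = {p.lower(): p for p in panel.names}
    rename: dict[str, str] = {}
    for col in df.columns:
        low = str(col).strip().lower()
        if low in probe_by_lower:
            rename[col] = probe_by_lower[low]
            continue
        for canon, aliases in _COLUMN_ALIASES.items():
            if low in aliases:
                rename[col] = canon
                break
    return df.rename(columns=rename)


def read_screen_csv(
    path: str | Path,
    panel: Optional[ProbePanel] = None,
    layout: Optional[PlateLayout] = None,
    batches: Optional[BatchMap] = None,
) -> ScreenDataset:
    """Read a canonical (or near-canonical) screen CSV.

    The first line may be a ``# stage=<stage>`` metadata comment; absent that,
    stage defaults to ``raw``. Common header variants of the identity columns
    are accepted; probe columns are matched case-insensitively against the
    panel. Malformed rows are reported with their 1-based line numbers.
    """
    panel = panel or default_panel()
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline()
    stage = Stage.raw
    skip = 0
    if first.startswith("#"):
        skip = 1
        if "stage=" in first:
            token = first.split("stage=", 1)[1].strip()
            try:
                stage = Stage(token)
            except ValueError:
                raise FormatError(f"unknown stage token {token!r} in {path}") from None

    df = pd.read_csv(
        path, skiprows=skip, dtype={"flags": "string"}, float_precision="round_trip"
    )
    df = _canonicalize_columns(df, panel)
    data_start = skip + 2  # 1-based line number of the first data row

    for probe in panel.names:
        if probe not in df.columns:
            raise FormatError(f"missing probe column {probe!r} in {path}")
    required = ["plate", "replicate", "row", "column", "role"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"missing required columns {missing} in {path}")

    if "batch" not in df.columns:
        df["batch"] = np.nan
    if "gene_symbol" not in df.columns:
        df["gene_symbol"] = pd.NA
    if "entrez_id" not in df.columns:
        df["entrez_id"] = np.nan
    if "flags" not in df.columns:
        df["flags"] = ""
    df["flags"] = df["flags"].fillna("")

    valid_roles = {r.value for r in WellRole}
    bad_role = ~df["role"].isin(valid_roles)
    if bad_role.any():
        lines = [int(i) + data_start for i in df.index[bad_role][:5]]
        tokens = sorted(df.loc[bad_role, "role"].unique())
        raise FormatError(
            f"unknown role token(s) {tokens} at line(s) {lines} in {path}"
        )

    bad_row = ~df["row"].isin(ROWS) | ~df["column"].between(1, N_COLS)
    if bad_row.any():
        lines = [int(i) + data_start for i in df.index[bad_row][:5]]
        raise FormatError(f"malformed well positions at line(s) {lines} in {path}")

    key = df[["plate", "replicate", "row", "column"]]
    dup = key.duplicated(keep=False)
    if dup.any():
        lines = [int(i) + data_start for i in df.index[key.duplicated()][:5]]
        raise IntegrityError(
            f"duplicate (plate, replicate, position) at line(s) {lines} in {path}"
        )

    df["plate"] = df["plate"].astype(int)
    df["column"] = df["column"].astype(int)
    df["replicate"] = df["replicate"].astype(str)
    df["batch"] = pd.to_numeric(df["batch"], errors="coerce")
    df["entrez_id"] = pd.to_numeric(df["entrez_id"], errors="coerce")
    for probe in panel.names:
        df[probe] = pd.to_numeric(df[probe], errors="coerce")

    df = df[ID_COLUMNS + panel.names].reset_index(drop=True)
    return ScreenDataset(
        frame=df,
        panel=panel,
        stage=stage,
        layout=layout or default_layout(),
        batches=batches,
    )


# ---------------------------------------------------------------------------
# layout validation and batch assembly
# ---------------------------------------------------------------------------


def validate_layout(ds: ScreenDataset) -> pd.DataFrame:
    """Report every plate×replicate whose role counts deviate from the layout.

    Returns a table with columns (plate, replicate, kind, role, expected,
    found, message); an empty table means the dataset conforms fully,
    including the blank-only constraint on columns 1 and 24.
    """
    rows: list[dict] = []
    expected = {r.value: n for r, n in ds.layout.control_counts.items()}
    for (plate, rep), grp in ds.frame.groupby(["plate", "replicate"], sort=True):
        counts = grp["role"].value_counts().to_dict()
        for role, exp in expected.items():
            found = int(counts.get(role, 0))
            if found != exp:
                rows.append(
                    dict(
                        plate=plate,
                        replicate=rep,
                        kind="role_count",
                        role=role,
                        expected=exp,
                        found=found,
                        message=f"expected {exp} {role} wells, found {found}",
                    )
                )
        in_blank_cols = grp["column"].isin(BLANK_COLUMNS)
        offenders = grp[in_blank_cols & (grp["role"] != WellRole.blank.value)]
        for _, off in offenders.iterrows():
            rows.append(
                dict(
                    plate=plate,
                    replicate=rep,
                    kind="blank_column",
                    role=off["role"],
                    expected=0,
                    found=1,
                    message=(
                        f"blank column violated: {off['role']} well at "
                        f"{off['row']}{off['column']}"
                    ),
                )
            )
    return pd.DataFrame(
        rows,
        columns=["plate", "replicate", "kind", "role", "expected", "found", "message"],
    )


def assemble_batches(ds: ScreenDataset, batch_map: BatchMap) -> ScreenDataset:
    """Stamp ``batch`` on every well according to ``batch_map`` (idempotent)."""
    plate_to_batch = batch_map.plate_to_batch
    unknown = sorted(set(ds.frame["plate"].unique()) - set(plate_to_batch))
    if unknown:
        raise AssignmentError(
            f"plate(s) {unknown} not assigned to any batch in the map"
        )
    df = ds.frame.copy()
    df["batch"] = df["plate"].map(plate_to_batch).astype(float)
    out = replace(ds, frame=df, batches=batch_map)
    return out
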