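"""Technical-validation battery.

Read-only diagnostics mirroring the checks run on the deposited screen:
pairwise probe covariation on normalized data, raw-scale control-well
behaviour per plate, plate-position (row/column) effects, technical-replicate
consistency of the PPIB housekeeping probe, and an indirect viability proxy
from raw housekeeping expression relative to the non-targeting controls.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import ScreenDataset, Stage
from .errors import ProcessingError
from .layout import BLANK_COLUMNS, CONTROL_COLUMNS, WellRole

LOW_VIABILITY_FLAG = "low_viability"


def probe_covariation(ds: ScreenDataset) -> pd.DataFrame:
    """Pairwise Pearson correlation between signature probes over sample wells.

    Probes that change expression independently across gene depletions are the
    most informative reporters; high covariation means partially redundant
    probes. Computed on normalized log2 data. A constant probe yields NaN
    entries (flagged missing, never 0).
    """
    if ds.stage is not Stage.normalized_log2:
        raise ProcessingError("probe covariation is defined on normalized data")
    samples = ds.frame[ds.mask(WellRole.sample)]
    if len(samples) < 3:
        raise ProcessingError("need >= 3 sample wells for probe covariation")
    sig = ds.signature_names
    mat = samples[sig].corr(method="pearson")
    np.fill_diagonal(mat.to_numpy(), 1.0)
    return mat


def control_summary(ds: ScreenDataset) -> pd.DataFrame:
    """Per-plate, per-role summary of the PPIB housekeeping probe.

    Operates on raw or background-subtracted data (the scale on which
    control-well behaviour is interpretable: blanks near background, lethal
    and siPPIB wells low, non-targeting controls high). Roles are ordered by
    mean PPIB within each plate.
    """
    if ds.stage not in (Stage.raw, Stage.bgsub):
        raise ProcessingError("control summary expects raw or bgsub data")
    df = ds.frame
    out = (
        df.groupby(["plate", "role"], sort=True)["PPIB"]
        .agg(count="count", mean="mean", sd="std")
        .reset_index()
    )
    out = out.sort_values(["plate", "mean"], kind="mergesort").reset_index(drop=True)
    return out


def position_effects(
    ds: ScreenDataset, stage: Stage | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-row and per-column center/spread per probe.

    Columns 1 and 24 hold only blanks and are excluded outright. Column
    statistics cover all remaining non-blank, non-empty wells, with columns 3
    and 22 annotated ``control_column`` (their readings reflect non-random
    plating of the repeated controls, not position). Row statistics are
    computed over sample wells only, so that the fixed placement of controls
    within specific rows of the control columns cannot masquerade as a row
    effect. Spread is reported as the IQR (robust to the heavy tails of MFI
    data). Returns ``(row_table, column_table)``.
    """
    if stage is not None and ds.stage is not stage:
        raise ProcessingError(f"dataset is at stage {ds.stage}, requested {stage}")
    df = ds.frame
    probes = ds.probe_names

    def iqr(x: pd.Series) -> float:
        return float(x.quantile(0.75) - x.quantile(0.25))

    samples = df[ds.mask(WellRole.sample)]
    rows = []
    for row_label, grp in samples.groupby("row", sort=True):
        for probe in probes:
            rows.append(
                dict(
                    row=row_label,
                    probe=probe,
                    n=len(grp),
                    mean=float(grp[probe].mean()),
                    iqr=iqr(grp[probe]),
                )
            )
    row_table = pd.DataFrame(rows)

    keep = ~df["column"].isin(BLANK_COLUMNS) & ~df["role"].isin(
        [WellRole.blank.value, WellRole.empty.value]
    )
    cols = []
    for col, grp in df[keep].groupby("column", sort=True):
        for probe in probes:
            cols.append(
                dict(
                    column=int(col),
                    probe=probe,
                    n=len(grp),
                    mean=float(grp[probe].mean()),
                    iqr=iqr(grp[probe]),
                    control_column=int(col) in CONTROL_COLUMNS,
                )
            )
    col_table = pd.DataFrame(cols)
    return row_table, col_table


def replicate_consistency(ds: ScreenDataset, probe: str = "PPIB") -> pd.DataFrame:
    """Pairwise Pearson correlation of one probe between technical replicates.

    Computed on raw values across all matched wells; mismatched well sets are
    intersected with a warning. Returns a table (rep_a, rep_b, pearson, n).
    """
    reps = ds.replicates
    if len(reps) < 2:
        raise ProcessingError("replicate consistency requires >= 2 replicates")
    wide = ds.frame.pivot_table(
        index=["plate", "row", "column"], columns="replicate", values=probe
    )
    rows = []
    for i, ra in enumerate(reps):
        for rb in reps[i + 1 :]:
            pair = wide[[ra, rb]].dropna()
            if len(pair) < len(wide):
                warnings.warn(
                    f"replicates {ra}/{rb} share only {len(pair)}/{len(wide)} wells",
                    stacklevel=2,
                )
            r = float(np.corrcoef(pair[ra], pair[rb])[0, 1])
            rows.append(dict(rep_a=ra, rep_b=rb, pearson=r, n=len(pair)))
    return pd.DataFrame(rows)


def viability_proxy(
    ds: ScreenDataset, threshold: float = 0.25
) -> pd.DataFrame:
    """Relative housekeeping score per library gene as a viability surrogate.

    For each well, the geometric mean of the two housekeeping probes is
    divided by the median of the same quantity over the plate's siCont wells;
    a gene's score is the mean of its wells' ratios across replicates. Scores
    below ``threshold`` are flagged low-viability. Defined on raw or
    background-subtracted data (housekeeping levels lose their cell-number
    meaning after the geomean correction).
    """
    if ds.stage not in (Stage.raw, Stage.bgsub):
        raise ProcessingError("viability proxy expects raw or bgsub data")
    df = ds.frame
    hk = ds.housekeeping_names
    g = np.sqrt(df[hk[0]].to_numpy().clip(min=0) * df[hk[1]].to_numpy().clip(min=0))
    gser = pd.Series(g, index=df.index, name="hk_geomean")
    sicont = ds.mask(WellRole.sicont)
    if not sicont.any():
        raise ProcessingError("no sicont wells for viability reference")
    med = (
        gser[sicont]
        .groupby([df.loc[sicont, "plate"], df.loc[sicont, "replicate"]])
        .median()
    )
    ref = med.reindex(pd.MultiIndex.from_frame(df[["plate", "replicate"]])).to_numpy()
    ratio = np.divide(g, ref, out=np.full_like(g, np.nan), where=ref > 0)
    tmp = df.assign(viability_score=ratio)
    samples = tmp[ds.mask(WellRole.sample)]
    out = (
        samples.groupby("gene_symbol", sort=True)
        .agg(
            entrez_id=("entrez_id", "first"),
            plate=("plate", "first"),
            viability_score=("viability_score", "mean"),
            n_wells=("viability_score", "count"),
        )
        .reset_index()
    )
    out["low_viability"] = out["viability_score"] < threshold
    return out


def qc_report(
    raw: ScreenDataset,
    normalized: ScreenDataset | None = None,
    viability_threshold: float = 0.25,
) -> dict:
    """Assemble the QC battery into a dict of tables plus a JSON-able summary."""
    report: dict = {}
    report["control_summary"] = control_summary(raw)
    row_t, col_t = position_effects(raw)
    report["position_rows"] = row_t
    report["position_columns"] = col_t
    if len(raw.replicates) >= 2:
        report["replicate_consistency"] = replicate_consistency(raw)
    report["viability"] = viability_proxy(raw, threshold=viability_threshold)
    if normalized is not None:
        report["probe_covariation"] = probe_covariation(normalized)
    summary = {
        "n_wells": int(len(raw.frame)),
        "n_plates": int(raw.frame["plate"].nunique()),
        "n_replicates": len(raw.replicates),
        "n_low_viability_genes": int(report["viability"]["low_viability"].sum()),
    }
    if "replicate_consistency" in report:
        summary["replicate_ppib_pearson"] = [
            round(float(x), 6) for x in report["replicate_consistency"]["pearson"]
        ]
    report["summary"] = summary
    return report


def write_qc_report(report: dict, outdir: str | Path) -> None:
    """Write the QC tables as CSVs plus a single JSON summary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, table in report.items():
        if isinstance(table, pd.DataFrame):
            table.to_csv(outdir / f"{name}.csv", index=name == "probe_covariation")
    with open(outdir / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(report["summary"], fh, indent=1)
        fh.write("\n")
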