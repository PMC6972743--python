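"""Stage 1 processing: background, flooring, housekeeping correction, averaging.

Order is fixed: plate-wise blank-well background subtraction, then flooring of
nonpositive values to the plate's positive probe minimum, then division of
every probe by the per-well geometric mean of the two housekeeping probes
(cell-number correction). Flooring precedes the geometric mean so that the
mean is always taken over strictly positive values. Technical replicates may
be averaged (arithmetic mean per well per probe) at any stage; the default
pipeline averages after housekeeping correction.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from .dataset import AVG_REPLICATE, ScreenDataset, Stage
from .errors import IntegrityError, ProcessingError
from .layout import WellRole

LOW_HOUSEKEEPING_FLAG = "low_housekeeping"
FLOOR_EPSILON_FLAG = "floored_epsilon"


def subtract_background(
    ds: ScreenDataset, center: str = "mean"
) -> tuple[ScreenDataset, pd.DataFrame]:
    """Subtract the blank-well background per plate × replicate × probe.

    ``center`` is the statistic of the blank wells used as the background
    estimate (``"mean"``, the default, or ``"median"``). Blank wells are
    themselves transformed. Negative results are retained; flooring is a
    separate stage. Returns the background-subtracted dataset and a
    ``BlankStats`` audit table (plate, replicate, probe, center, n_blank).

    Raises :class:`ProcessingError` if any plate × replicate has no blanks.
    """
    if ds.stage is not Stage.raw:
        raise ProcessingError(f"background subtraction expects stage=raw, got {ds.stage}")
    if center not in ("mean", "median"):
        raise ProcessingError(f"unknown blank center statistic {center!r}")
    df = ds.frame.copy()
    probes = ds.probe_names
    blanks = df[ds.mask(WellRole.blank)]
    have = set(map(tuple, blanks[["plate", "replicate"]].drop_duplicates().to_numpy()))
    all_units = set(map(tuple, df[["plate", "replicate"]].drop_duplicates().to_numpy()))
    missing = sorted(all_units - have)
    if missing:
        raise ProcessingError(
            f"no blank wells on plate×replicate unit(s) {missing[:5]}"
        )

    agg = "mean" if center == "mean" else "median"
    stats = blanks.groupby(["plate", "replicate"])[probes].agg([agg, "count"])
    centers = stats.xs(agg, axis=1, level=1)
    df[probes] = df[probes] - centers.reindex(
        pd.MultiIndex.from_frame(df[["plate", "replicate"]])
    ).to_numpy()

    audit = (
        centers.stack()
        .rename("center")
        .reset_index()
        .rename(columns={"level_2": "probe"})
    )
    counts = (
        stats.xs("count", axis=1, level=1)
        .stack()
        .rename("n_blank")
        .reset_index()
        .rename(columns={"level_2": "probe"})
    )
    audit = audit.merge(counts, on=["plate", "replicate", "probe"])
    return ds.with_frame(df, Stage.bgsub), audit


def floor_negatives(
    ds: ScreenDataset, epsilon: float = 1.0
) -> tuple[ScreenDataset, pd.DataFrame]:
    """Replace nonpositive values by the plate's positive probe minimum.

    For each plate × replicate × probe, every value ≤ 0 is set to the minimum
    strictly-positive value of that probe among the plate's non-blank,
    non-empty wells (blanks would floor to ≈ 0 and re-break positivity). If no
    positive value exists, ``epsilon`` is used and the affected wells are
    flagged. The floor is applied to every well, blanks included, so that
    subsequent geometric-mean correction is defined everywhere.

    Returns the floored dataset (still stage ``bgsub``) and a ``FloorRecord``
    audit table (plate, replicate, probe, floor, n_floored, epsilon_used).
    """
    if ds.stage is not Stage.bgsub:
        raise ProcessingError(f"flooring expects stage=bgsub, got {ds.stage}")
    df = ds.frame.copy()
    probes = ds.probe_names
    informative = ~df["role"].isin([WellRole.blank.value, WellRole.empty.value])
    rows: list[dict] = []
    out = ds.with_frame(df)  # same stage; mutate frame in place below
    for (plate, rep), idx in df.groupby(["plate", "replicate"]).groups.items():
        sub = df.loc[idx]
        inf_sub = sub[informative.loc[idx]]
        for probe in probes:
            vals = inf_sub[probe].to_numpy()
            pos = vals[vals > 0]
            eps_used = len(pos) == 0
            floor = epsilon if eps_used else float(pos.min())
            needs = sub.index[sub[probe] <= 0]
            if len(needs):
                df.loc[needs, probe] = floor
                if eps_used:
                    mask = pd.Series(False, index=df.index)
                    mask.loc[needs] = True
                    out.add_flag(mask, FLOOR_EPSILON_FLAG)
            rows.append(
                dict(
                    plate=plate,
                    replicate=rep,
                    probe=probe,
                    floor=floor,
                    n_floored=int(len(needs)),
                    epsilon_used=eps_used,
                )
            )
    audit = pd.DataFrame(rows)
    return out, audit


def geomean_normalize(
    ds: ScreenDataset, low_housekeeping_threshold: float = 0.25
) -> ScreenDataset:
    """Divide every probe by the well's housekeeping geometric mean.

    For each well, ``g = sqrt(PPIB * HPRT)`` (more generally the geometric
    mean of the panel's two housekeeping probes); every probe value is divided
    by ``g``, correcting the signature for per-well cell number. Wells whose
    ``g`` falls below ``low_housekeeping_threshold`` times the plate's siCont
    median ``g`` are flagged ``low_housekeeping`` but still computed.
    """
    if ds.stage is not Stage.bgsub:
        raise ProcessingError(f"geomean normalization expects stage=bgsub, got {ds.stage}")
    df = ds.frame.copy()
    hk = ds.housekeeping_names
    with np.errstate(invalid="ignore"):
        g = np.sqrt(df[hk[0]].to_numpy() * df[hk[1]].to_numpy())
    if not np.all(g > 0) or not np.all(np.isfinite(g)):
        n = int(np.sum(~(g > 0) | ~np.isfinite(g)))
        raise IntegrityError(
            f"{n} wells with nonpositive housekeeping geomean; floor first"
        )
    out = ds.with_frame(df, Stage.geomean)
    # flag before dividing: thresholds are on the raw-scale geomean
    sicont = ds.mask(WellRole.sicont).to_numpy()
    gser = pd.Series(g, index=df.index)
    med = (
        gser[sicont]
        .groupby([df.loc[sicont, "plate"], df.loc[sicont, "replicate"]])
        .median()
    )
    if len(med):
        ref = med.reindex(
            pd.MultiIndex.from_frame(df[["plate", "replicate"]])
        ).to_numpy()
        low = g < low_housekeeping_threshold * ref
        out.add_flag(pd.Series(low, index=df.index), LOW_HOUSEKEEPING_FLAG)
    df[ds.probe_names] = df[ds.probe_names].to_numpy() / g[:, None]
    return out


def average_replicates(ds: ScreenDataset) -> ScreenDataset:
    """Arithmetic per-well mean across technical replicates.

    Identity fields are taken from the first replicate (they are shared by
    construction); QC flags are unioned; the resulting replicate label is
    ``"avg"``. A single-replicate dataset passes through unchanged apart from
    the label.
    """
    df = ds.frame
    probes = ds.probe_names

    def union_flags(series: pd.Series) -> str:
        out: set[str] = set()
        for t in series:
            if t:
                out |= set(str(t).split(";"))
        return ";".join(sorted(out))

    grouped = df.groupby(["plate", "row", "column"], sort=True)
    ident = grouped[["batch", "role", "gene_symbol", "entrez_id"]].first()
    vals = grouped[probes].mean()
    flags = grouped["flags"].agg(union_flags)
    out = ident.join(vals).join(flags).reset_index()
    out["replicate"] = AVG_REPLICATE
    from .dataset import ID_COLUMNS

    out = out[ID_COLUMNS + probes]
    return ds.with_frame(out.reset_index(drop=True))
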