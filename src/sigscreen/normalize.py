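"""Stage 2: control-median normalization, Grubbs outlier exclusion, similarity.

Geomean-corrected signature values are divided by the median of the
non-targeting (siCont) control wells — per plate, per batch, or screen-wide —
and log2-transformed. Repeated control wells (siCont per plate, positive
control per batch) are then screened for outliers with an iterative Grubbs
test applied to each well's Euclidean distance from its group's mean
signature. The per-batch target signature is the mean of the surviving
positive-control wells, and every library gene is scored against it by
Euclidean distance and Pearson correlation, per replicate and on
replicate-averaged signatures.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .dataset import AVG_REPLICATE, ScreenDataset, Stage
from .errors import GeneNotFoundError, ProcessingError
from .layout import WellRole
from .preprocess import average_replicates

OUTLIER_FLAG = "outlier"

_SCOPES = ("plate", "batch", "screen")


@dataclass(frozen=True)
class SignatureVector:
    """Ordered log2 signature values for one well or aggregate."""

    values: tuple[float, ...]
    probes: tuple[str, ...]
    provenance: str = ""
    scope: str = ""

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class OutlierDecision:
    """Audit record of iterative Grubbs screening for one control group."""

    group: tuple
    role: str
    alpha: float
    min_n: int
    n_initial: int
    removed: list[tuple] = field(default_factory=list)  # well keys in removal order
    removed_scalars: list[float] = field(default_factory=list)
    skipped: bool = False

    @property
    def n_final(self) -> int:
        return self.n_initial - len(self.removed)


def _scope_cols(scope: str, with_replicate: bool = True) -> list[str]:
    if scope not in _SCOPES:
        raise ProcessingError(f"unknown scope {scope!r}; choose from {_SCOPES}")
    base = {"plate": ["plate"], "batch": ["batch"], "screen": []}[scope]
    return base + (["replicate"] if with_replicate else [])


def control_median_normalize(ds: ScreenDataset, scope: str = "plate") -> ScreenDataset:
    """Divide signature probes by the scope's siCont median, then log2.

    ``scope`` is ``plate`` (recommended for target-based scoring), ``batch``,
    or ``screen`` (required for gene-vs-gene comparisons). The siCont median
    is computed per scope unit × replicate × probe. Housekeeping probes are
    carried through unchanged (their information was consumed by the
    geometric-mean correction and is kept on that scale for QC).
    """
    if ds.stage is not Stage.geomean:
        raise ProcessingError(
            f"control normalization expects stage=geomean, got {ds.stage}"
        )
    cols = _scope_cols(scope)
    df = ds.frame.copy()
    sig = ds.signature_names
    sicont = df[ds.mask(WellRole.sicont)]
    if sicont.empty:
        raise ProcessingError("no sicont wells in dataset")
    if cols:
        med = sicont.groupby(cols)[sig].median()
        have = set(med.index)
        units = set(map(tuple, df[cols].drop_duplicates().to_numpy())) if len(cols) > 1 else set(df[cols[0]].unique())
        if len(cols) == 1:
            missing = sorted(units - {i for i in have})
        else:
            missing = sorted(units - have)
        if missing:
            raise ProcessingError(
                f"scope unit(s) without sicont wells: {missing[:5]} (scope={scope})"
            )
        ref = med.reindex(pd.MultiIndex.from_frame(df[cols]) if len(cols) > 1 else df[cols[0]]).to_numpy()
    else:  # pragma: no cover - scope always includes replicate
        ref = sicont[sig].median().to_numpy()[None, :]
    vals = df[sig].to_numpy()
    if np.any(vals <= 0) or np.any(ref <= 0):
        raise ProcessingError("control-median normalization requires positive values")
    df[sig] = np.log2(vals / ref)
    return ds.with_frame(df, Stage.normalized_log2)


# ---------------------------------------------------------------------------
# Grubbs test
# ---------------------------------------------------------------------------


def grubbs_critical_value(n: int, alpha: float) -> float:
    """Two-sided Grubbs critical value G_crit(n, alpha).

    ``G_crit = ((n-1)/sqrt(n)) * sqrt(t^2 / (n - 2 + t^2))`` with ``t`` the
    upper ``alpha/(2n)`` quantile of Student's t with ``n-2`` degrees of
    freedom.
    """
    t = sps.t.ppf(1.0 - alpha / (2.0 * n), n - 2)
    return (n - 1) / np.sqrt(n) * np.sqrt(t * t / (n - 2 + t * t))


def grubbs_step(values: np.ndarray, alpha: float = 0.05) -> int | None:
    """One step of the two-sided Grubbs outlier test.

    Returns the index of the single most extreme value iff its standardized
    deviation ``G = max|x - mean| / sd`` exceeds the two-sided critical value
    at ``alpha``; returns ``None`` otherwise (including the degenerate
    ``sd = 0`` case). Requires ``n >= 3`` finite values.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or len(x) < 3:
        raise ProcessingError(f"grubbs_step requires a 1-d vector with n >= 3, got n={x.size}")
    if not np.all(np.isfinite(x)):
        raise ProcessingError("grubbs_step requires finite values")
    sd = x.std(ddof=1)
    if sd == 0:
        return None
    dev = np.abs(x - x.mean())
    idx = int(np.argmax(dev))
    g = dev[idx] / sd
    return idx if g > grubbs_critical_value(len(x), alpha) else None


def exclude_control_outliers(
    ds: ScreenDataset,
    role: WellRole | str,
    group_scope: str = "plate",
    alpha: float = 0.05,
    min_n: int = 6,
    pool_replicates: bool = True,
) -> tuple[ScreenDataset, list[OutlierDecision]]:
    """Iteratively flag Grubbs outliers among repeated control wells.

    Within each group (plate or batch; replicates pooled by default so that
    per-plate control groups reach the printed floor of 6 on triplicate
    data), each well's scalar is the Euclidean distance of its signature
    vector to the group mean signature. One well at a time is tested with
    :func:`grubbs_step`; after each removal the mean and distances are
    recomputed. Removal stops when no outlier is found or when another
    removal would drop the group below ``min_n``. Groups smaller than
    ``min_n`` at the start are skipped with a warning. Flagged wells stay in
    the dataset, marked ``outlier``.
    """
    if ds.stage is not Stage.normalized_log2:
        raise ProcessingError(
            f"outlier exclusion expects stage=normalized_log2, got {ds.stage}"
        )
    role = WellRole(role)
    cols = _scope_cols(group_scope, with_replicate=not pool_replicates)
    if group_scope == "screen":
        raise ProcessingError("outlier groups are per plate or per batch")
    df = ds.frame
    sig = ds.signature_names
    out = ds.with_frame(df.copy())
    decisions: list[OutlierDecision] = []
    members = out.frame[out.mask(role)]
    if members.empty:
        raise ProcessingError(f"no {role.value} wells present")
    for key, grp in members.groupby(cols, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        decision = OutlierDecision(
            group=key,
            role=role.value,
            alpha=alpha,
            min_n=min_n,
            n_initial=len(grp),
        )
        decisions.append(decision)
        if len(grp) < min_n:
            decision.skipped = True
            warnings.warn(
                f"{role.value} group {key} has {len(grp)} wells < min_n={min_n}; skipped",
                stacklevel=2,
            )
            continue
        remaining = list(grp.index)
        X = grp[sig].to_numpy(dtype=float)
        alive = np.ones(len(X), dtype=bool)
        while alive.sum() > min_n:
            sub = X[alive]
            dist = np.linalg.norm(sub - sub.mean(axis=0), axis=1)
            hit = grubbs_step(dist, alpha)
            if hit is None:
                break
            local = np.flatnonzero(alive)[hit]
            alive[local] = False
            well_idx = remaining[local]
            row = grp.loc[well_idx]
            decision.removed.append(
                (int(row["plate"]), str(row["replicate"]), str(row["row"]), int(row["column"]))
            )
            decision.removed_scalars.append(float(dist[hit]))
            mask = pd.Series(False, index=out.frame.index)
            mask.loc[well_idx] = True
            out.add_flag(mask, OUTLIER_FLAG)
    return out, decisions


def outlier_decisions_table(decisions: list[OutlierDecision]) -> pd.DataFrame:
    """Flatten decisions into an audit CSV table (one row per group)."""
    rows = []
    for d in decisions:
        rows.append(
            dict(
                group="/".join(str(k) for k in d.group),
                role=d.role,
                alpha=d.alpha,
                min_n=d.min_n,
                n_initial=d.n_initial,
                n_removed=len(d.removed),
                n_final=d.n_final,
                skipped=d.skipped,
                removed_wells=";".join(
                    f"{p}:{r}:{row}{c}" for p, r, row, c in d.removed
                ),
                removed_scalars=";".join(f"{s:.6g}" for s in d.removed_scalars),
            )
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# target signature and similarity metrics
# ---------------------------------------------------------------------------


def compute_target_signature(
    ds: ScreenDataset, batch_id: int | None = None, min_n: int = 1
) -> SignatureVector:
    """Mean signature of non-outlier positive-control wells.

    With ``batch_id`` given, restricts to that batch (the recommended,
    per-batch target); otherwise averages over the whole dataset (screen-wide
    target). Wells flagged ``outlier`` are excluded.
    """
    df = ds.frame
    sel = ds.mask(WellRole.si_target) & ~ds.has_flag(OUTLIER_FLAG)
    scope = "screen"
    if batch_id is not None:
        sel &= df["batch"] == batch_id
        scope = "batch"
    wells = df[sel]
    if len(wells) < max(min_n, 1):
        raise ProcessingError(
            f"only {len(wells)} non-outlier positive-control wells "
            f"(batch={batch_id}), need >= {max(min_n, 1)}"
        )
    sig = ds.signature_names
    return SignatureVector(
        values=tuple(wells[sig].mean().to_numpy(dtype=float)),
        probes=tuple(sig),
        provenance=f"mean of {len(wells)} positive-control wells",
        scope=scope,
    )


def _as_vec(v) -> np.ndarray:
    if isinstance(v, SignatureVector):
        return v.as_array()
    return np.asarray(v, dtype=float)


def euclidean_distance(a, b) -> float:
    """Euclidean distance between two signature vectors."""
    av, bv = _as_vec(a), _as_vec(b)
    if av.shape != bv.shape:
        raise ProcessingError(f"length mismatch: {av.shape} vs {bv.shape}")
    return float(np.linalg.norm(av - bv))


def pearson_correlation(a, b) -> float:
    """Sample Pearson correlation; NaN (never a sentinel) if undefined."""
    av, bv = _as_vec(a), _as_vec(b)
    if av.shape != bv.shape:
        raise ProcessingError(f"length mismatch: {av.shape} vs {bv.shape}")
    if av.size < 3:
        raise ProcessingError("pearson correlation requires length >= 3")
    if np.ptp(av) == 0 or np.ptp(bv) == 0:
        return float("nan")
    return float(np.corrcoef(av, bv)[0, 1])


def _rowwise_metrics(X: np.ndarray, t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized distance and correlation of each row of X against t."""
    dist = np.linalg.norm(X - t[None, :], axis=1)
    Xc = X - X.mean(axis=1, keepdims=True)
    tc = t - t.mean()
    xnorm = np.linalg.norm(Xc, axis=1)
    tnorm = np.linalg.norm(tc)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (Xc @ tc) / (xnorm * tnorm)
    corr[(xnorm == 0) | (tnorm == 0)] = np.nan
    return dist, corr


def score_screen(
    ds: ScreenDataset,
    targets: dict,
    similarity_scope: str = "batch",
    averaged: ScreenDataset | None = None,
) -> pd.DataFrame:
    """Score every library gene against the target signature.

    ``targets`` maps batch id → :class:`SignatureVector` when
    ``similarity_scope == "batch"``; for ``"screen"`` it must contain the
    single key ``"screen"``. Metrics are computed per technical replicate and
    on replicate-averaged signatures (column families ``dist_rep<k>`` /
    ``corr_rep<k>``, ``dist_avg_of_metrics`` / ``corr_avg_of_metrics`` for
    the mean of per-replicate metrics, and ``dist_of_avg`` / ``corr_of_avg``
    for metrics of the averaged signature). Pass the pipeline's
    replicate-averaged normalized dataset as ``averaged`` so the averaging
    happens on the geomean scale before the log2 transform (the pipeline
    default); absent that, the log2 values themselves are averaged. Ranks
    (1 = most similar) are assigned on the averaged-signature metrics —
    ascending distance, descending correlation — with ties broken
    lexicographically by gene symbol; genes with undefined correlation rank
    last.
    """
    if ds.stage is not Stage.normalized_log2:
        raise ProcessingError(f"scoring expects stage=normalized_log2, got {ds.stage}")
    if similarity_scope not in ("batch", "screen"):
        raise ProcessingError(f"similarity scope must be batch or screen")
    sig = ds.signature_names
    samples = ds.frame[ds.mask(WellRole.sample)]
    if samples.empty:
        raise ProcessingError("no sample wells to score")

    def target_for(batch: float) -> np.ndarray:
        if similarity_scope == "screen":
            key = "screen"
        else:
            key = int(batch)
        if key not in targets:
            raise ProcessingError(f"no target signature for batch {key!r}")
        return _as_vec(targets[key])

    reps = [r for r in sorted(samples["replicate"].unique()) if r != AVG_REPLICATE]
    if averaged is not None:
        if averaged.stage is not Stage.normalized_log2:
            raise ProcessingError("averaged dataset must be at stage=normalized_log2")
        avg = averaged.frame[averaged.mask(WellRole.sample)].reset_index(drop=True)
    elif reps:
        avg = average_replicates(ds.with_frame(samples.reset_index(drop=True))).frame
    else:
        avg = samples

    result = avg[["gene_symbol", "entrez_id", "batch", "plate"]].copy()
    result["batch"] = result["batch"].astype(int)
    per_rep_dist: dict[str, pd.Series] = {}
    per_rep_corr: dict[str, pd.Series] = {}
    for rep in reps:
        sub = samples[samples["replicate"] == rep].set_index("gene_symbol")
        dists = np.empty(len(sub))
        corrs = np.empty(len(sub))
        for batch, bidx in sub.groupby("batch").groups.items():
            t = target_for(batch)
            d, c = _rowwise_metrics(sub.loc[bidx, sig].to_numpy(dtype=float), t)
            pos = sub.index.get_indexer(bidx)
            dists[pos] = d
            corrs[pos] = c
        per_rep_dist[rep] = pd.Series(dists, index=sub.index)
        per_rep_corr[rep] = pd.Series(corrs, index=sub.index)

    genes = result["gene_symbol"]
    for rep in reps:
        result[f"dist_rep{rep}"] = per_rep_dist[rep].reindex(genes).to_numpy()
        result[f"corr_rep{rep}"] = per_rep_corr[rep].reindex(genes).to_numpy()
    if reps:
        result["dist_avg_of_metrics"] = result[[f"dist_rep{r}" for r in reps]].mean(axis=1)
        result["corr_avg_of_metrics"] = result[[f"corr_rep{r}" for r in reps]].mean(axis=1)

    dists = np.empty(len(avg))
    corrs = np.empty(len(avg))
    for batch, bidx in avg.groupby("batch").groups.items():
        t = target_for(batch)
        d, c = _rowwise_metrics(avg.loc[bidx, sig].to_numpy(dtype=float), t)
        pos = avg.index.get_indexer(bidx)
        dists[pos] = d
        corrs[pos] = c
    result["dist_of_avg"] = dists
    result["corr_of_avg"] = corrs

    order_d = result.sort_values(["dist_of_avg", "gene_symbol"], kind="mergesort").index
    result.loc[order_d, "rank_distance"] = np.arange(1, len(result) + 1)
    neg = -result["corr_of_avg"]
    neg = neg.fillna(np.inf)  # undefined correlation ranks last
    tmp = result.assign(_negcorr=neg)
    order_c = tmp.sort_values(["_negcorr", "gene_symbol"], kind="mergesort").index
    result.loc[order_c, "rank_correlation"] = np.arange(1, len(result) + 1)
    result["rank_distance"] = result["rank_distance"].astype(int)
    result["rank_correlation"] = result["rank_correlation"].astype(int)
    return result.sort_values("gene_symbol", kind="mergesort").reset_index(drop=True)


def signature_of_gene(ds: ScreenDataset, gene: str) -> SignatureVector:
    """Replicate-averaged signature vector of one library gene."""
    rows = ds.frame[(ds.frame["gene_symbol"] == gene) & ds.mask(WellRole.sample)]
    if rows.empty:
        raise GeneNotFoundError(f"gene {gene!r} not present among sample wells")
    sig = ds.signature_names
    return SignatureVector(
        values=tuple(rows[sig].mean().to_numpy(dtype=float)),
        probes=tuple(sig),
        provenance=f"gene {gene} (mean of {len(rows)} wells)",
        scope="screen",
    )


def pairwise_gene_similarity(
    ds: ScreenDataset, gene_a: str, gene_b: str
) -> tuple[float, float]:
    """(Euclidean distance, Pearson correlation) between two genes.

    Gene-vs-gene comparisons are only meaningful under screen-wide
    normalization, so ``ds`` must be normalized with ``scope="screen"``;
    replicates are averaged before computing the metrics. Symmetric in its
    arguments.
    """
    if ds.stage is not Stage.normalized_log2:
        raise ProcessingError("pairwise similarity expects stage=normalized_log2")
    a = signature_of_gene(ds, gene_a)
    b = signature_of_gene(ds, gene_b)
    return euclidean_distance(a, b), pearson_correlation(a, b)
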