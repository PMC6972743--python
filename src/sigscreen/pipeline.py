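"""End-to-end pipeline orchestration.

``run_pipeline`` executes the full processing chain on a raw dataset::

    subtract_background -> floor_negatives -> geomean_normalize
        -> average_replicates (kept alongside per-replicate data)
        -> control_median_normalize -> exclude_control_outliers
        -> compute_target_signature -> score_screen

and returns every intermediate product plus audit tables. All parameters
live in :class:`PipelineConfig`; a run manifest (config hash, input hash,
versions, per-stage counts) documents each run for reproducibility.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from .dataset import ScreenDataset, Stage, write_screen_csv
from .errors import ConfigError
from .layout import WellRole
from .normalize import (
    compute_target_signature,
    control_median_normalize,
    exclude_control_outliers,
    outlier_decisions_table,
    score_screen,
)
from .preprocess import (
    average_replicates,
    floor_negatives,
    geomean_normalize,
    subtract_background,
)


@dataclass
class PipelineConfig:
    """All tunable parameters of a pipeline run (defaults as recommended)."""

    normalization_scope: str = "plate"
    similarity_scope: str = "batch"
    blank_center: str = "mean"
    floor_epsilon: float = 1.0
    low_housekeeping_threshold: float = 0.25
    grubbs_alpha: float = 0.05
    min_n_sicont: int = 6  # per plate
    min_n_target: int = 20  # per batch
    pool_replicates_for_outliers: bool = True
    viability_threshold: float = 0.25

    def validate(self) -> None:
        if self.normalization_scope not in ("plate", "batch", "screen"):
            raise ConfigError(f"bad normalization scope {self.normalization_scope!r}")
        if self.similarity_scope not in ("batch", "screen"):
            raise ConfigError(f"bad similarity scope {self.similarity_scope!r}")
        if self.min_n_sicont < 3 or self.min_n_target < 3:
            raise ConfigError("min_n values must be >= 3")
        if not 0 < self.grubbs_alpha < 1:
            raise ConfigError("grubbs_alpha must lie in (0, 1)")

    def sha256(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


@dataclass
class PipelineResult:
    """Every product of one pipeline run."""

    bgsub: ScreenDataset
    geomean: ScreenDataset
    geomean_avg: ScreenDataset
    normalized: ScreenDataset  # per-replicate, outlier-flagged
    normalized_avg: ScreenDataset  # replicate-averaged, outlier-flagged
    blank_stats: pd.DataFrame
    floor_record: pd.DataFrame
    outlier_decisions: pd.DataFrame
    targets: dict
    similarity: pd.DataFrame
    manifest: dict = field(default_factory=dict)


def run_pipeline(ds: ScreenDataset, cfg: PipelineConfig | None = None) -> PipelineResult:
    """Run the full analysis on a raw-stage dataset."""
    cfg = cfg or PipelineConfig()
    cfg.validate()
    if ds.stage is not Stage.raw:
        raise ConfigError(f"pipeline input must be at stage=raw, got {ds.stage}")

    bgsub, blank_stats = subtract_background(ds, center=cfg.blank_center)
    floored, floor_record = floor_negatives(bgsub, epsilon=cfg.floor_epsilon)
    geo = geomean_normalize(
        floored, low_housekeeping_threshold=cfg.low_housekeeping_threshold
    )
    geo_avg = average_replicates(geo)

    norm = control_median_normalize(geo, scope=cfg.normalization_scope)
    norm_avg = control_median_normalize(geo_avg, scope=cfg.normalization_scope)

    # outlier screening: siCont per plate, positive control per batch,
    # pooling technical replicates so the per-plate group reaches its floor
    norm, dec_sicont = exclude_control_outliers(
        norm,
        WellRole.sicont,
        group_scope="plate",
        alpha=cfg.grubbs_alpha,
        min_n=cfg.min_n_sicont,
        pool_replicates=cfg.pool_replicates_for_outliers,
    )
    norm, dec_target = exclude_control_outliers(
        norm,
        WellRole.si_target,
        group_scope="batch",
        alpha=cfg.grubbs_alpha,
        min_n=cfg.min_n_target,
        pool_replicates=cfg.pool_replicates_for_outliers,
    )
    decisions = outlier_decisions_table(dec_sicont + dec_target)

    # propagate per-replicate outlier flags onto the averaged dataset: a well
    # flagged in any replicate is excluded from the averaged target too
    from .normalize import OUTLIER_FLAG

    flagged = norm.frame[norm.has_flag(OUTLIER_FLAG)][["plate", "row", "column"]]
    if len(flagged):
        key = set(map(tuple, flagged.to_numpy()))
        mask = norm_avg.frame.apply(
            lambda r: (r["plate"], r["row"], r["column"]) in key, axis=1
        )
        norm_avg.add_flag(mask, OUTLIER_FLAG)

    if cfg.similarity_scope == "batch":
        batches = sorted(int(b) for b in norm_avg.frame["batch"].dropna().unique())
        targets = {
            b: compute_target_signature(norm_avg, batch_id=b) for b in batches
        }
    else:
        targets = {"screen": compute_target_signature(norm_avg)}

    similarity = score_screen(
        norm, targets, similarity_scope=cfg.similarity_scope, averaged=norm_avg
    )

    manifest = {
        "config": asdict(cfg),
        "config_sha256": cfg.sha256(),
        "stage_counts": {
            "wells": int(len(ds.frame)),
            "wells_floored": int(floor_record["n_floored"].sum()),
            "outliers_removed": int(decisions["n_removed"].sum()) if len(decisions) else 0,
            "groups_skipped": int(decisions["skipped"].sum()) if len(decisions) else 0,
            "genes_scored": int(len(similarity)),
        },
        "versions": _versions(),
    }
    return PipelineResult(
        bgsub=bgsub,
        geomean=geo,
        geomean_avg=geo_avg,
        normalized=norm,
        normalized_avg=norm_avg,
        blank_stats=blank_stats,
        floor_record=floor_record,
        outlier_decisions=decisions,
        targets=targets,
        similarity=similarity,
        manifest=manifest,
    )


def _versions() -> dict:
    import numpy
    import scipy

    from . import __version__

    return {
        "sigscreen": __version__,
        "numpy": numpy.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
    }


def sha256_of_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_pipeline_outputs(result: PipelineResult, outdir: str | Path) -> None:
    """Write stage tables, audit logs, similarity table and manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_screen_csv(result.bgsub, outdir / "stage_bgsub.csv")
    write_screen_csv(result.geomean, outdir / "stage_geomean.csv")
    write_screen_csv(result.normalized, outdir / "stage_normalized_log2.csv")
    write_screen_csv(result.normalized_avg, outdir / "stage_normalized_log2_avg.csv")
    result.blank_stats.to_csv(outdir / "audit_blank_stats.csv", index=False)
    result.floor_record.to_csv(outdir / "audit_floor_record.csv", index=False)
    result.outlier_decisions.to_csv(outdir / "audit_outliers.csv", index=False)
    result.similarity.to_csv(outdir / "similarity.csv", index=False)
    targets = {
        str(k): {"probes": list(v.probes), "values": list(v.values)}
        for k, v in result.targets.items()
    }
    with open(outdir / "targets.json", "w", encoding="utf-8") as fh:
        json.dump(targets, fh, indent=1)
        fh.write("\n")
    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(result.manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
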