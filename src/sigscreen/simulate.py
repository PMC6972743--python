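"""Synthetic screen generator with known ground truth.

The generator emulates the deposited screen's shape — 384-well plates with
blank columns 1/24, quintuplicate siCont / siKSR1 / siPLK1 / siPPIB controls
in columns 3/22, 320 library wells per plate, plates grouped into batches,
technical triplicates — and a multiplicative-lognormal signal model above an
additive fluorescence background:

    E[well, probe j] = v_g * s_plate * s_batch * s_edge(row, col)
                       * 2 ** (mu_j + delta_gj)
    MFI              = B_j + E * exp(eps),   eps ~ Normal(0, sigma_tech^2)

where ``v_g`` is the targeted gene's viability, ``s_*`` are per-plate /
per-batch / positional multiplicative artifacts, ``mu_j`` the baseline log2
expression of probe j, and ``delta_gj`` the true log2 effect of depleting
gene g on probe j (zero for the two housekeeping probes). Blank and unused
wells read background only. siPPIB wells additionally multiply the PPIB probe
by a knockdown fraction. Technical replicates share the gene assignment and
the plate/batch artifacts but redraw the well-level background and noise.

All randomness flows from a single integer seed through one
``numpy.random.Generator``; the same seed reproduces the dataset and truth
byte-for-byte.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .dataset import ID_COLUMNS, ScreenDataset, Stage
from .errors import ConfigError
from .layout import (
    CONTROL_GENES,
    BatchMap,
    PlateLayout,
    WellRole,
    batch_map_for_plates,
    default_layout,
)
from .panel import ProbePanel, default_panel

#: default log2 baseline expression per probe (arbitrary, MFI-scale realistic)
DEFAULT_BASELINE_LOG2: dict[str, float] = {
    "BNIP3L": 8.8,
    "NDRG1": 9.5,
    "ALDOC": 8.5,
    "LOXL2": 8.0,
    "BNIP3": 9.0,
    "ACSL5": 8.2,
    "PPIB": 10.0,
    "HPRT": 9.3,
}

#: default true log2 effect of the positive-control depletion on the six
#: signature probes (order BNIP3L, NDRG1, ALDOC, LOXL2, BNIP3, ACSL5) —
#: consistently negative with graded magnitudes
DEFAULT_TARGET_EFFECT: tuple[float, ...] = (-2.0, -1.5, -1.2, -0.9, -0.7, -0.4)


@dataclass
class SimConfig:
    """Configuration of one synthetic screen.

    Scales with a ``_sd`` suffix are standard deviations on a natural-log
    (multiplicative) scale unless noted; ``*_log2`` quantities are log2.
    """

    n_plates: int = 10
    plates_per_batch: int = 5
    n_replicates: int = 3
    panel: ProbePanel = field(default_factory=default_panel)
    target_effect: tuple[float, ...] = DEFAULT_TARGET_EFFECT
    n_planted: int = 20
    planted_scale: float = 1.0
    n_lethal: int = 10
    background_mean: Mapping[str, float] | float = 30.0
    background_cv: float = 0.15
    baseline_log2_expression: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BASELINE_LOG2)
    )
    sigma_tech: float = 0.10
    sigma_effect: float = 0.10
    null_effect_sd: float = 0.15
    plate_scale_sd: float = 0.10
    batch_scale_sd: float = 0.15
    viability_sd: float = 0.05
    edge_effect: Optional[dict] = None  # {"rows": {"A": 2.0}, "cols": {...}}
    lethal_viability: float = 0.1
    target_viability: float = 0.6
    si_probe_viability: float = 1.0
    si_probe_knockdown: float = 0.1
    seed: int = 0

    # -- derived ---------------------------------------------------------

    @property
    def n_sample_wells_per_plate(self) -> int:
        return 320

    @property
    def n_genes(self) -> int:
        return self.n_plates * self.n_sample_wells_per_plate

    def background_mean_of(self, probe: str) -> float:
        if isinstance(self.background_mean, Mapping):
            return float(self.background_mean[probe])
        return float(self.background_mean)

    def validate(self) -> None:
        sig = self.panel.signature_names
        if len(self.target_effect) != len(sig):
            raise ConfigError(
                f"target_effect has {len(self.target_effect)} entries for "
                f"{len(sig)} signature probes"
            )
        for name in (
            "background_cv sigma_tech sigma_effect null_effect_sd "
            "plate_scale_sd batch_scale_sd viability_sd".split()
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be nonnegative")
        if not (0 < self.lethal_viability <= 1):
            raise ConfigError("lethal_viability must lie in (0, 1]")
        if self.n_planted + self.n_lethal > self.n_genes:
            raise ConfigError(
                f"n_planted + n_lethal = {self.n_planted + self.n_lethal} exceeds "
                f"{self.n_genes} sample genes"
            )
        if self.n_plates < 1 or self.n_replicates < 1 or self.plates_per_batch < 1:
            raise ConfigError("plate/replicate counts must be positive")
        for probe in self.panel.names:
            if probe not in self.baseline_log2_expression:
                raise ConfigError(f"baseline_log2_expression missing probe {probe!r}")

    # -- (de)serialization ----------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["panel"] = {
            "signature": self.panel.signature_names,
            "housekeeping": self.panel.housekeeping_names,
        }
        d["target_effect"] = list(self.target_effect)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimConfig":
        d = dict(d)
        panel = d.pop("panel", None)
        if panel is not None and not isinstance(panel, ProbePanel):
            from .panel import panel_from_names

            panel = panel_from_names(panel["signature"], panel["housekeeping"])
        kwargs = dict(d)
        if panel is not None:
            kwargs["panel"] = panel
        if "target_effect" in kwargs:
            kwargs["target_effect"] = tuple(kwargs["target_effect"])
        return cls(**kwargs)


@dataclass
class GroundTruth:
    """Per-gene true effects and viabilities, plus plate/batch artifacts.

    ``genes`` has one row per sample gene: symbol, entrez_id, planted and
    lethal flags, viability, and one ``delta_<probe>`` column per signature
    probe. Control wells are implicit: siCont has delta = 0 and v = 1;
    the positive control carries ``target_effect``.
    """

    genes: pd.DataFrame
    plate_scales: dict[int, float]
    batch_scales: dict[int, float]
    target_effect: tuple[float, ...]
    signature_probes: tuple[str, ...]

    @property
    def planted_symbols(self) -> list[str]:
        return list(self.genes.loc[self.genes["planted"], "gene_symbol"])

    @property
    def lethal_symbols(self) -> list[str]:
        return list(self.genes.loc[self.genes["lethal"], "gene_symbol"])

    def delta_of(self, gene_symbol: str) -> np.ndarray:
        row = self.genes.loc[self.genes["gene_symbol"] == gene_symbol]
        if row.empty:
            raise KeyError(gene_symbol)
        cols = [f"delta_{p}" for p in self.signature_probes]
        return row[cols].to_numpy(dtype=float)[0]

    def to_dict(self) -> dict:
        return {
            "signature_probes": list(self.signature_probes),
            "target_effect": list(self.target_effect),
            "plate_scales": {str(k): v for k, v in self.plate_scales.items()},
            "batch_scales": {str(k): v for k, v in self.batch_scales.items()},
            "genes": self.genes.to_dict(orient="list"),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "GroundTruth":
        genes = pd.DataFrame(d.get("genes", {}))
        return cls(
            genes=genes,
            plate_scales={int(k): float(v) for k, v in d.get("plate_scales", {}).items()},
            batch_scales={int(k): float(v) for k, v in d.get("batch_scales", {}).items()},
            target_effect=tuple(d.get("target_effect", ())),
            signature_probes=tuple(d.get("signature_probes", ())),
        )


def write_ground_truth(gt: GroundTruth, path: str | Path) -> None:
    """JSON-serialize a :class:`GroundTruth` (floats round-trip bit-exactly)."""
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(gt.to_dict(), fh, indent=1)
        fh.write("\n")


def read_ground_truth(path: str | Path) -> GroundTruth:
    with open(path, "r", encoding="utf-8") as fh:
        return GroundTruth.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def _edge_multipliers(cfg: SimConfig, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
    mult = np.ones(len(rows))
    if cfg.edge_effect:
        for r, f in cfg.edge_effect.get("rows", {}).items():
            mult[rows == r] *= float(f)
        for c, f in cfg.edge_effect.get("cols", {}).items():
            mult[cols == int(c)] *= float(f)
    return mult


def simulate_screen(
    cfg: SimConfig, layout: Optional[PlateLayout] = None
) -> tuple[ScreenDataset, GroundTruth]:
    """Generate a raw-stage screen dataset and its ground truth.

    The gene→effect assignment is drawn once and shared across technical
    replicates; well-level background and lognormal noise are redrawn per
    replicate. Fully reproducible from ``cfg.seed``.
    """
    cfg.validate()
    layout = layout or default_layout()
    panel = cfg.panel
    probes = panel.names
    sig = panel.signature_names
    n_sig = len(sig)
    rng = np.random.default_rng(cfg.seed)

    plate_ids = list(range(1, cfg.n_plates + 1))
    batch_map = batch_map_for_plates(plate_ids, cfg.plates_per_batch)
    plate_to_batch = batch_map.plate_to_batch
    n_batches = len(batch_map.batches)

    # --- gene-level truth (shared across replicates) --------------------
    n_genes = cfg.n_genes
    width = max(5, len(str(n_genes)))
    symbols = np.array([f"G{i:0{width}d}" for i in range(1, n_genes + 1)])
    entrez = np.arange(100_001, 100_001 + n_genes)

    delta = rng.normal(0.0, cfg.null_effect_sd, size=(n_genes, n_sig))
    special = rng.choice(n_genes, size=cfg.n_planted + cfg.n_lethal, replace=False)
    planted_idx = np.sort(special[: cfg.n_planted])
    lethal_idx = np.sort(special[cfg.n_planted :])
    target = np.asarray(cfg.target_effect, dtype=float)
    delta[planted_idx] = cfg.planted_scale * target + rng.normal(
        0.0, cfg.sigma_effect, size=(cfg.n_planted, n_sig)
    )
    viability = np.exp(rng.normal(0.0, cfg.viability_sd, size=n_genes))
    viability[lethal_idx] = cfg.lethal_viability

    plate_scales = np.exp(rng.normal(0.0, cfg.plate_scale_sd, size=cfg.n_plates))
    batch_scales = np.exp(rng.normal(0.0, cfg.batch_scale_sd, size=n_batches))

    # --- per-plate static well table ------------------------------------
    positions = sorted(layout.role_map)  # (row, col), row-major
    pos_rows = np.array([p[0] for p in positions])
    pos_cols = np.array([p[1] for p in positions], dtype=int)
    pos_roles = np.array([layout.role_map[p].value for p in positions])
    sample_mask_plate = pos_roles == WellRole.sample.value

    plates_col, rows_col, cols_col, roles_col = [], [], [], []
    gene_col: list[object] = []
    entrez_col: list[object] = []
    gene_index = np.full(cfg.n_plates * len(positions), -1, dtype=int)
    next_gene = 0
    for pi, plate in enumerate(plate_ids):
        plates_col.append(np.full(len(positions), plate))
        rows_col.append(pos_rows)
        cols_col.append(pos_cols)
        roles_col.append(pos_roles)
        genes_here = np.full(len(positions), None, dtype=object)
        entrez_here = np.full(len(positions), np.nan)
        which = np.flatnonzero(sample_mask_plate)
        idx = np.arange(next_gene, next_gene + len(which))
        genes_here[which] = symbols[idx]
        entrez_here[which] = entrez[idx]
        gene_index[pi * len(positions) + which] = idx
        next_gene += len(which)
        for role, (gsym, gid) in CONTROL_GENES.items():
            m = pos_roles == role.value
            genes_here[m] = gsym
            entrez_here[m] = gid
        gene_col.append(genes_here)
        entrez_col.append(entrez_here)

    base = pd.DataFrame(
        {
            "plate": np.concatenate(plates_col),
            "row": np.concatenate(rows_col),
            "column": np.concatenate(cols_col),
            "role": np.concatenate(roles_col),
            "gene_symbol": np.concatenate(gene_col),
            "entrez_id": np.concatenate(entrez_col),
        }
    )
    base["batch"] = base["plate"].map(plate_to_batch).astype(float)
    n_base = len(base)

    # --- expected signal (replicate-invariant) ---------------------------
    mu = np.array([cfg.baseline_log2_expression[p] for p in probes])
    delta_wells = np.zeros((n_base, len(probes)))
    sig_pos = [probes.index(p) for p in sig]
    sampled = gene_index >= 0
    delta_wells[np.ix_(sampled, sig_pos)] = delta[gene_index[sampled]]
    role_arr = base["role"].to_numpy()
    t_mask = role_arr == WellRole.si_target.value
    delta_wells[np.ix_(t_mask, sig_pos)] = target

    v = np.ones(n_base)
    v[sampled] = viability[gene_index[sampled]]
    v[t_mask] = cfg.target_viability
    v[role_arr == WellRole.si_lethal.value] = cfg.lethal_viability
    v[role_arr == WellRole.si_probe.value] = cfg.si_probe_viability
    v[role_arr == WellRole.blank.value] = 0.0
    v[role_arr == WellRole.empty.value] = 0.0

    knock = np.ones((n_base, len(probes)))
    ppib_j = probes.index("PPIB") if "PPIB" in probes else None
    if ppib_j is not None:
        knock[role_arr == WellRole.si_probe.value, ppib_j] = cfg.si_probe_knockdown

    s_plate = plate_scales[base["plate"].to_numpy() - 1]
    s_batch = batch_scales[(base["batch"].to_numpy(dtype=int)) - 1]
    s_edge = _edge_multipliers(cfg, base["row"].to_numpy(), base["column"].to_numpy())
    scale = v * s_plate * s_batch * s_edge
    expected = scale[:, None] * np.power(2.0, mu[None, :] + delta_wells) * knock

    # --- replicates: redraw background and noise -------------------------
    bg_mean = np.array([cfg.background_mean_of(p) for p in probes])
    frames = []
    for rep in range(1, cfg.n_replicates + 1):
        bg = bg_mean[None, :] * (
            1.0 + cfg.background_cv * rng.standard_normal((n_base, len(probes)))
        )
        np.clip(bg, 0.0, None, out=bg)
        eps = rng.standard_normal((n_base, len(probes))) * cfg.sigma_tech
        mfi = bg + expected * np.exp(eps)
        df = base.copy()
        df["replicate"] = str(rep)
        df["flags"] = ""
        for j, p in enumerate(probes):
            df[p] = mfi[:, j]
        frames.append(df)

    frame = pd.concat(frames, ignore_index=True)[ID_COLUMNS + probes]
    ds = ScreenDataset(
        frame=frame, panel=panel, stage=Stage.raw, layout=layout, batches=batch_map
    )

    genes_df = pd.DataFrame(
        {
            "gene_symbol": symbols,
            "entrez_id": entrez,
            "planted": np.isin(np.arange(n_genes), planted_idx),
            "lethal": np.isin(np.arange(n_genes), lethal_idx),
            "viability": viability,
        }
    )
    for k, p in enumerate(sig):
        genes_df[f"delta_{p}"] = delta[:, k]
    gt = GroundTruth(
        genes=genes_df,
        plate_scales={p: float(s) for p, s in zip(plate_ids, plate_scales)},
        batch_scales={b: float(s) for b, s in zip(sorted(batch_map.batches), batch_scales)},
        target_effect=tuple(target),
        signature_probes=tuple(sig),
    )
    return ds, gt


def make_default_config(scale: str = "demo", seed: int = 0) -> SimConfig:
    """Preset configurations.

    - ``tiny``: 1 plate × 1 replicate (384 wells, 320 sample genes)
    - ``demo``: 10 plates × 3 replicates (3,200 sample genes, 2 batches)
    - ``paperlike``: 45 plates × 3 replicates (14,400 sample genes, matching
      the real screen's ~14,355 depletions to within 0.5%), 8 plates/batch
    """
    presets = {
        "tiny": dict(n_plates=1, plates_per_batch=1, n_replicates=1, n_planted=2, n_lethal=1),
        "demo": dict(n_plates=10, plates_per_batch=5, n_replicates=3, n_planted=20, n_lethal=10),
        "paperlike": dict(n_plates=45, plates_per_batch=8, n_replicates=3, n_planted=90, n_lethal=45),
    }
    if scale not in presets:
        raise ConfigError(f"unknown scale {scale!r}; choose from {sorted(presets)}")
    return SimConfig(seed=seed, **presets[scale])


def noise_free(cfg: SimConfig) -> SimConfig:
    """Copy of ``cfg`` with every stochastic scale set to zero."""
    return replace(
        cfg,
        background_cv=0.0,
        sigma_tech=0.0,
        sigma_effect=0.0,
        null_effect_sd=0.0,
        plate_scale_sd=0.0,
        batch_scale_sd=0.0,
        viability_sd=0.0,
    )
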