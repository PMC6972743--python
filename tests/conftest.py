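"""Shared fixtures: seeded simulations reused across the suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import sigscreen as ss
from sigscreen.dataset import ID_COLUMNS
from sigscreen.simulate import noise_free

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")

#: single fixed seed for every seeded fixture in the suite
SEED = 20


@pytest.fixture(scope="session")
def demo_sim():
    """Demo-scale screen (10 plates x 3 replicates, 20 planted, 10 lethal)."""
    cfg = ss.make_default_config("demo", seed=SEED)
    ds, gt = ss.simulate_screen(cfg)
    return cfg, ds, gt


@pytest.fixture(scope="session")
def demo_result(demo_sim):
    _, ds, _ = demo_sim
    return ss.run_pipeline(ds)


@pytest.fixture(scope="session")
def tiny_sim():
    cfg = ss.make_default_config("tiny", seed=SEED)
    ds, gt = ss.simulate_screen(cfg)
    return cfg, ds, gt


@pytest.fixture(scope="session")
def tiny_noise_free():
    """1 plate, 1 replicate, all stochastic scales zero (exact expectations)."""
    cfg = noise_free(ss.make_default_config("tiny", seed=SEED))
    ds, gt = ss.simulate_screen(cfg)
    return cfg, ds, gt


def make_control_dataset(
    X: np.ndarray,
    role: str = "sicont",
    stage: ss.Stage = ss.Stage.normalized_log2,
    plate: int = 1,
    batch: int = 1,
) -> ss.ScreenDataset:
    """Build a minimal dataset whose ``role`` wells carry the given signature
    matrix (one row per well); housekeeping probes are filled with 1.0."""
    panel = ss.default_panel()
    X = np.asarray(X, dtype=float)
    n = len(X)
    rows = [chr(ord("A") + (i // 24) % 16) for i in range(n)]
    cols = [(i % 24) + 1 for i in range(n)]
    reps = [str(1 + i // 384) for i in range(n)]
    df = pd.DataFrame(
        {
            "plate": plate,
            "batch": float(batch),
            "replicate": reps,
            "row": rows,
            "column": cols,
            "role": role,
            "gene_symbol": [f"W{i}" for i in range(n)],
            "entrez_id": np.nan,
            "flags": "",
        }
    )
    for j, p in enumerate(panel.signature_names):
        df[p] = X[:, j]
    for p in panel.housekeeping_names:
        df[p] = 1.0
    return ss.ScreenDataset(frame=df[ID_COLUMNS + panel.names], panel=panel, stage=stage)
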