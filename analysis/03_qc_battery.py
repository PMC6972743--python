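#!/usr/bin/env python
"""Run the technical-validation battery on the simulated screen.

Computes control-well behaviour (raw PPIB by role and plate), plate-position
row/column effects, technical-replicate consistency, the raw-housekeeping
viability proxy, and probe covariation on the normalized data; writes the
tables plus a JSON summary under results/qc/.
"""

from pathlib import Path

import sigscreen as ss
from sigscreen.qc import write_qc_report

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    raw_path = ROOT / "results" / "screen" / "screen_raw.csv"
    if not raw_path.exists():
        raise SystemExit("run analysis/01_simulate_screen.py first")
    ds = ss.read_screen_csv(raw_path)
    normalized = ss.run_pipeline(ds).normalized
    report = ss.qc_report(ds, normalized=normalized)
    outdir = ROOT / "results" / "qc"
    write_qc_report(report, outdir)

    print("QC summary:", report["summary"])
    cs = report["control_summary"]
    order = cs.groupby("role")["mean"].mean().sort_values()
    print("role ordering by mean raw PPIB (low -> high):")
    for role, mean in order.items():
        print(f"  {role:>10s}: {mean:10.1f}")
    cov = report["probe_covariation"]
    off = cov.where(~(cov == 1.0)).abs().max().max()
    print(f"max off-diagonal probe covariation: {off:.3f}")
    print(f"outputs -> {outdir}")


if __name__ == "__main__":
    main()
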