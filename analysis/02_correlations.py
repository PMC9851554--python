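#!/usr/bin/env python
"""Utility-entropy correlation tables from the simulated controller trials.

Reads the metrics tables written by 01_simulate_controllers.py and writes
per-length + pooled Spearman/Pearson correlations of utility with each
information metric, one file per arm:

    correlations_noiseless.csv
    correlations_obs_noise.csv

plus the mean per-trial entropy gap H(S) - H(S'|A) and its consistency
with the mean mutual information I(A;S').
"""

import argparse
from pathlib import Path

import pandas as pd

from pendulum_entropy import analysis

METRICS = ["H_A_given_S", "H_S", "H_Sprime_given_A", "I_A_Sprime"]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--results-dir", type=Path, default=Path("results"))
    args = ap.parse_args()

    for arm in ("noiseless", "obs_noise"):
        src = args.results_dir / f"controller_metrics_{arm}.csv"
        if not src.exists():
            raise SystemExit(f"{src} missing - run 01_simulate_controllers.py first")
        table = pd.read_csv(src)
        reports = [
            analysis.correlate(table, m, "utility", by_length=True) for m in METRICS
        ]
        report = pd.concat(reports, ignore_index=True)
        out = args.results_dir / f"correlations_{arm}.csv"
        report.to_csv(out, index=False, float_format="%.4g")
        pooled = report[report.length.isna()].set_index("x")
        gap = analysis.entropy_gap(table)
        print(f"[{arm}] wrote {out}")
        for m in METRICS:
            row = pooled.loc[m]
            print(
                f"  pooled U ~ {m:17s}: rho = {row.spearman_rho:+.3f} "
                f"(p = {row.spearman_p:.2g}), r = {row.pearson_r:+.3f}"
            )
        print(
            f"  mean H(S) - H(S'|A) gap = {gap['mean_gap']:.3f} bits "
            f"(mean I(A;S') = {gap['mean_I_A_Sprime']:.3f} bits)"
        )


if __name__ == "__main__":
    main()
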