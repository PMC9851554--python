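#!/usr/bin/env python
"""Scatter figures of utility against each entropy metric, per arm.

Reads the metrics tables written by 01_simulate_controllers.py and saves
PNG scatter plots (points coloured by pendulum length) under
results/figures/.
"""

import argparse
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

LABELS = {
    "H_A_given_S": "H(A|S) (bits)",
    "H_S": "H(S) (bits)",
    "H_Sprime_given_A": "H(S'|A) (bits)",
    "I_A_Sprime": "I(A;S') (bits)",
}


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--results-dir", type=Path, default=Path("results"))
    args = ap.parse_args()
    fig_dir = args.results_dir / "figures"
    fig_dir.mkdir(parents=True, exist_ok=True)

    for arm in ("noiseless", "obs_noise"):
        src = args.results_dir / f"controller_metrics_{arm}.csv"
        if not src.exists():
            raise SystemExit(f"{src} missing - run 01_simulate_controllers.py first")
        table = pd.read_csv(src)
        for metric, label in LABELS.items():
            fig, ax = plt.subplots(figsize=(5.5, 4))
            sc = ax.scatter(
                table[metric], table["utility"], c=table["length"],
                cmap="viridis", s=14
            )
            fig.colorbar(sc, label="pendulum length L (m)")
            ax.set_xlabel(label)
            ax.set_ylabel("utility U")
            ax.set_title(arm.replace("_", " "))
            fig.tight_layout()
            path = fig_dir / f"{arm}_utility_vs_{metric}.png"
            fig.savefig(path, dpi=150)
            plt.close(fig)
            print(f"wrote {path}")


if __name__ == "__main__":
    main()
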