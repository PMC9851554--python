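"""Reproduction driver for the controller study's headline numbers.

Runs the epsilon-greedy controller family over the eight study lengths
under two noise settings — noiseless, and observation noise with angle
sd 0.1 rad / speed sd 0.2 rad/s — and pools the utility-entropy
correlations over all 26 x 8 = 208 trials per setting.

Study-scale choices (see docs/methods.md for rationale):

* MDP grid 64 x 64 over [0, 2*pi) x [-10, 10] with bilinear successor
  interpolation (the full-scale grid is 1000 x 1000; the coarse grid's
  intrinsic interpolation diffusion doubles as the regularisation that
  keeps the greedy policy robust when deployed under observation noise);
* skill family eps_n = n/26, n = 0..25;
* metric estimation decimates each trial by 4 (one sample every 68 ms)
  before binning at the 1000 x 200 analysis binning, with the
  action-to-outcome lag of 270 ms = 4 decimated samples.

The headline quantities are:

* noiseless: pooled Spearman rho of H(S) with utility (strongly
  negative), and of H(A|S) with utility (positive but non-monotone:
  action entropy falls again at the high-utility end);
* observation noise: pooled Spearman and Pearson of H(A|S) with utility
  (both strongly positive — the qualitative flip the noise produces).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import analysis, controllers
from .controllers import GridSpec, NoiseParams
from .dynamics import Trajectory
from .infotheory import BinningSpec

#: observation-noise setting of the noisy arm (rad, rad/s)
OBS_NOISE = NoiseParams(sigma_angle_o=0.1, sigma_speed_o=0.2)
#: reduced MDP grid used for the scaled-down reproduction
REDUCED_GRID = GridSpec(angle_bins=64, speed_bins=64)
#: keep one sample in DECIMATION for metric estimation
DECIMATION = 4
#: action-to-outcome lag in decimated samples (~270 ms)
DECIMATED_LAG = 4


def decimate(trajectory: Trajectory, factor: int = DECIMATION) -> Trajectory:
    """Every ``factor``-th sample of a trial (states and actions together)."""
    if factor < 1:
        raise ValueError("decimation factor must be >= 1")
    return Trajectory(
        trajectory.angles[::factor],
        trajectory.speeds[::factor],
        trajectory.actions[::factor],
        dt=trajectory.dt * factor,
    )


def study_metrics_table(
    records,
    binning: BinningSpec = BinningSpec(),
    decimation: int = DECIMATION,
    lag_samples: int = DECIMATED_LAG,
) -> pd.DataFrame:
    """Per-trial metrics on decimated series (utility keeps all samples)."""
    slim = []
    for rec in records:
        r = controllers.TrialRecord(
            trajectory=decimate(rec.trajectory, decimation),
            length=rec.length,
            utility=rec.utility,
            source=rec.source,
            skill_level=rec.skill_level,
            epsilon=rec.epsilon,
            participant=rec.participant,
            seed=rec.seed,
        )
        slim.append(r)
    return analysis.metrics_table(slim, binning, lag_samples)


@dataclass
class StudyArm:
    """Metrics table and pooled correlations of one noise setting."""

    table: pd.DataFrame
    spearman_U_HS: float
    spearman_U_HAgS: float
    pearson_U_HAgS: float


def run_arm(
    noise: NoiseParams,
    seed: int,
    grid: GridSpec = REDUCED_GRID,
    lengths=controllers.STUDY_LENGTHS,
    n_levels: int = controllers.STUDY_SKILL_LEVELS,
    n_steps: int = controllers.STUDY_TRIAL_SAMPLES,
    binning: BinningSpec = BinningSpec(),
    decimation: int = DECIMATION,
    lag_samples: int = DECIMATED_LAG,
    progress=None,
) -> StudyArm:
    """One noise setting: simulate the grid, score and correlate."""
    records = controllers.run_grid(
        lengths=lengths,
        n_levels=n_levels,
        noise=noise,
        grid=grid,
        n_steps=n_steps,
        base_seed=seed,
        progress=progress,
    )
    table = study_metrics_table(records, binning, decimation, lag_samples)
    c_hs = analysis.correlate(table, "H_S", "utility")
    c_hags = analysis.correlate(table, "H_A_given_S", "utility")
    return StudyArm(
        table=table,
        spearman_U_HS=c_hs["spearman_rho"].iloc[-1],
        spearman_U_HAgS=c_hags["spearman_rho"].iloc[-1],
        pearson_U_HAgS=c_hags["pearson_r"].iloc[-1],
    )


def controller_study(
    seed: int,
    grid: GridSpec = REDUCED_GRID,
    n_steps: int = controllers.STUDY_TRIAL_SAMPLES,
    n_levels: int = controllers.STUDY_SKILL_LEVELS,
    progress=None,
) -> dict[str, StudyArm]:
    """Both arms of the controller study, seeded independently per arm."""
    seeds = controllers.derive_seeds(seed, 2)
    return {
        "noiseless": run_arm(
            NoiseParams(), int(seeds[0]), grid, n_steps=n_steps,
            n_levels=n_levels, progress=progress,
        ),
        "obs_noise": run_arm(
            OBS_NOISE, int(seeds[1]), grid, n_steps=n_steps,
            n_levels=n_levels, progress=progress,
        ),
    }
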