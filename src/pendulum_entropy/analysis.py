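"""Result layer: per-trial metrics tables, utility-entropy correlations,
balancing-region/key-press statistics and phase-space support summaries.

The central object is a pandas ``DataFrame`` with one row per trial
(columns ``source``, ``trial_id``, ``length``, ``utility``, ``H_S``,
``H_A_given_S``, ``H_Sprime_given_A``, ``I_A_Sprime``, ``binning``),
built from human or synthetic trials alike.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .controllers import TrialRecord
from .dynamics import TWO_PI, Trajectory
from .infotheory import DEFAULT_LAG_SAMPLES, BinningSpec, discretize, trial_metrics
from .task import RewardParams, _circular_distance

METRIC_COLUMNS = ["utility", "H_S", "H_A_given_S", "H_Sprime_given_A", "I_A_Sprime"]


def metrics_table(
    records: list[TrialRecord],
    spec: BinningSpec = BinningSpec(),
    lag_samples: int = DEFAULT_LAG_SAMPLES,
) -> pd.DataFrame:
    """One metrics row per trial, all under the same binning."""
    rows = []
    for i, rec in enumerate(records):
        m = trial_metrics(rec.trajectory, rec.utility, spec, lag_samples)
        rows.append(
            {
                "source": rec.source,
                "trial_id": rec.participant if rec.participant is not None else i,
                "skill_level": rec.skill_level,
                "epsilon": rec.epsilon,
                "length": rec.length,
                "utility": m.utility,
                "H_S": m.H_S,
                "H_A_given_S": m.H_A_given_S,
                "H_Sprime_given_A": m.H_Sprime_given_A,
                "I_A_Sprime": m.I_A_Sprime,
                "binning": m.binning,
            }
        )
    return pd.DataFrame(rows)


def correlate(
    table: pd.DataFrame, x: str, y: str, by_length: bool = False
) -> pd.DataFrame:
    """Spearman and Pearson correlations of two metric columns.

    Pooled over all rows by default, or per pendulum length with a
    pooled row appended (``length = NaN``).  Spearman uses average ranks
    for ties; p-values are two-sided.  Groups with a constant column get
    NaN coefficients; groups with fewer than 3 rows are rejected.
    """
    def one(df: pd.DataFrame) -> dict:
        if len(df) < 3:
            raise ValueError("need >= 3 rows per group for a correlation")
        xv, yv = df[x].to_numpy(), df[y].to_numpy()
        if np.ptp(xv) == 0 or np.ptp(yv) == 0:
            return {"spearman_rho": np.nan, "spearman_p": np.nan,
                    "pearson_r": np.nan, "pearson_p": np.nan, "n": len(df)}
        sp = stats.spearmanr(xv, yv)
        pe = stats.pearsonr(xv, yv)
        return {
            "spearman_rho": float(sp.statistic),
            "spearman_p": float(sp.pvalue),
            "pearson_r": float(pe.statistic),
            "pearson_p": float(pe.pvalue),
            "n": len(df),
        }

    rows = []
    if by_length:
        for length, df in table.groupby("length"):
            rows.append({"length": length, "x": x, "y": y, **one(df)})
    rows.append({"length": np.nan, "x": x, "y": y, **one(table)})
    return pd.DataFrame(rows)


@dataclass
class Episode:
    """A maximal run of consecutive identical non-`n` actions."""

    action: int
    start: int
    duration: int
    inside: bool
    distance: float  # |unwrapped angle traveled| during the episode, rad


@dataclass
class BalancingStats:
    fraction_in_region: float
    episodes: list[Episode]
    presses_inside: int
    presses_outside: int


def _signed_increments(angles: np.ndarray) -> np.ndarray:
    """Per-step angle increments unwrapped to (-pi, pi]."""
    d = np.diff(angles)
    return (d + np.pi) % TWO_PI - np.pi


def balancing_stats(
    trajectory: Trajectory,
    reward_params: RewardParams = RewardParams(),
    inside_by: str = "start",
) -> BalancingStats:
    """Time-in-region fraction and key-press episode statistics.

    The region here is angular only (within the angle halfwidth of
    upright, no speed condition).  An episode is a maximal run of equal
    non-`n` actions; it counts as "inside" if its start sample is inside
    (``inside_by="start"``) or if most of its samples are
    (``inside_by="majority"``).  Distance is the absolute sum of
    unwrapped per-step angle increments over the episode, so a full
    revolution counts as 2*pi.
    """
    if len(trajectory) == 0:
        raise ValueError("empty trajectory")
    if inside_by not in ("start", "majority"):
        raise ValueError("inside_by must be 'start' or 'majority'")
    inside = (
        _circular_distance(trajectory.angles, reward_params.upright_angle)
        < reward_params.angle_halfwidth
    )
    fraction = float(inside.mean())
    increments = _signed_increments(trajectory.angles)
    acts = trajectory.actions
    episodes: list[Episode] = []
    k = 0
    n_code = 1  # Action.N
    while k < len(acts):
        if acts[k] == n_code:
            k += 1
            continue
        start = k
        while k < len(acts) and acts[k] == acts[start]:
            k += 1
        duration = k - start
        if inside_by == "start":
            is_inside = bool(inside[start])
        else:
            is_inside = bool(inside[start:k].mean() > 0.5)
        # increments[j] is the angle change from sample j to j+1
        dist = float(abs(increments[start : min(k, len(increments))].sum()))
        episodes.append(Episode(int(acts[start]), start, duration, is_inside, dist))
    n_in = sum(e.inside for e in episodes)
    return BalancingStats(fraction, episodes, n_in, len(episodes) - n_in)


@dataclass
class PhaseSupport:
    """Distinct visited phase-plane cells and their occupancy counts."""

    cells: np.ndarray  # flat symbol ids, sorted
    counts: np.ndarray

    @property
    def size(self) -> int:
        return len(self.cells)


def phase_support(trajectory: Trajectory, spec: BinningSpec = BinningSpec()) -> PhaseSupport:
    series = discretize(trajectory.angles, trajectory.speeds, spec)
    cells, counts = np.unique(series.symbols, return_counts=True)
    return PhaseSupport(cells, counts)


def aggregate_by_length(table: pd.DataFrame, column: str) -> pd.DataFrame:
    """Per-length mean of a metric column, with group sizes."""
    g = table.groupby("length")[column].agg(["mean", "count"]).reset_index()
    return g.rename(columns={"mean": f"{column}_mean", "count": "n"})


def entropy_gap(table: pd.DataFrame) -> dict:
    """Mean per-trial gap ``H(S) - H(S'|A)`` and the matching mean ``I(A;S')``.

    Under stationarity ``H(S) ~ H(S')`` the gap should approximate the
    mutual information between the action and the lagged state.
    """
    gaps = table["H_S"] - table["H_Sprime_given_A"]
    return {
        "mean_gap": float(gaps.mean()),
        "per_trial_gap": gaps.to_numpy(),
        "mean_I_A_Sprime": float(table["I_A_Sprime"].mean()),
    }
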