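"""Binned plug-in estimators of entropy and mutual information on trials.

States are discretised on a uniform grid over the phase plane — by
default 1000 equal angle bins over ``[0, 2*pi)`` and 200 equal speed bins
over ``[-10, 10] rad/s`` (speeds outside the range are clamped to the
edge bins) — and every estimator is the maximum-likelihood ("plug-in")
estimator on the empirical symbol distribution, in bits.

Binned entropies carry an offset that depends only on the binning, so
they are comparable across trials only under one fixed
:class:`BinningSpec`; :func:`trial_metrics` therefore stamps its output
with the spec's fingerprint.

The lagged state ``S'`` is the state visited a fixed number of samples
after an action was selected (default 16 samples ~ 270 ms, approximating
motor-execution delay); ``I(A; S')`` measures how much the chosen key
tells about the state it produces.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .dynamics import TWO_PI, Trajectory

#: default lag between an action and the state it is paired with, in samples
DEFAULT_LAG_SAMPLES = 16  # round(0.270 s / 0.017 s)


@dataclass(frozen=True)
class BinningSpec:
    """Uniform discretisation of the phase plane used by the estimators."""

    angle_bins: int = 1000
    speed_bins: int = 200
    speed_lo: float = -10.0
    speed_hi: float = 10.0

    def __post_init__(self) -> None:
        if self.angle_bins < 1 or self.speed_bins < 1:
            raise ValueError("bin counts must be >= 1")
        if not self.speed_lo < self.speed_hi:
            raise ValueError("speed range must be non-empty")

    @property
    def n_symbols(self) -> int:
        return self.angle_bins * self.speed_bins

    def fingerprint(self) -> str:
        return (
            f"angle[0,2pi)x{self.angle_bins}|"
            f"speed[{self.speed_lo:g},{self.speed_hi:g}]x{self.speed_bins}"
        )

    def angle_bin(self, angles) -> np.ndarray:
        idx = np.floor(np.asarray(angles) % TWO_PI / (TWO_PI / self.angle_bins))
        # angles just below 2*pi can round up to the bin count in float
        return np.minimum(idx.astype(np.int64), self.angle_bins - 1)

    def speed_bin(self, speeds) -> np.ndarray:
        width = (self.speed_hi - self.speed_lo) / self.speed_bins
        idx = np.floor((np.asarray(speeds) - self.speed_lo) / width).astype(np.int64)
        return np.clip(idx, 0, self.speed_bins - 1)


@dataclass
class SymbolSeries:
    """A discrete time series together with its alphabet size."""

    symbols: np.ndarray
    alphabet_size: int

    def __post_init__(self) -> None:
        self.symbols = np.asarray(self.symbols, dtype=np.int64)
        if len(self.symbols) and self.symbols.max() >= self.alphabet_size:
            raise ValueError("symbol out of alphabet range")
        if len(self.symbols) and self.symbols.min() < 0:
            raise ValueError("negative symbol")

    def __len__(self) -> int:
        return len(self.symbols)


def discretize(angles, speeds, spec: BinningSpec = BinningSpec()) -> SymbolSeries:
    """Map states to flat symbols ``angle_bin * speed_bins + speed_bin``."""
    sym = spec.angle_bin(angles) * spec.speed_bins + spec.speed_bin(speeds)
    return SymbolSeries(sym, spec.n_symbols)


def _entropy_from_counts(counts: np.ndarray) -> float:
    counts = counts[counts > 0]
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def entropy(x: SymbolSeries) -> float:
    """Plug-in Shannon entropy of the empirical distribution, in bits."""
    if len(x) == 0:
        raise ValueError("empty series")
    _, counts = np.unique(x.symbols, return_counts=True)
    return _entropy_from_counts(counts)


def _joint_symbols(x: SymbolSeries, y: SymbolSeries) -> SymbolSeries:
    if len(x) != len(y):
        raise ValueError(f"length mismatch: {len(x)} vs {len(y)}")
    return SymbolSeries(
        x.symbols.astype(np.int64) * y.alphabet_size + y.symbols,
        x.alphabet_size * y.alphabet_size,
    )


def joint_entropy(x: SymbolSeries, y: SymbolSeries) -> float:
    return entropy(_joint_symbols(x, y))


def conditional_entropy(x: SymbolSeries, given: SymbolSeries) -> float:
    """``H(X | Y) = H(X, Y) - H(Y)`` from the empirical joint, in bits."""
    return joint_entropy(x, given) - entropy(given)


def mutual_information(x: SymbolSeries, y: SymbolSeries) -> float:
    """``I(X; Y) = H(X) + H(Y) - H(X, Y)`` >= 0, in bits."""
    i = entropy(x) + entropy(y) - joint_entropy(x, y)
    return max(i, 0.0)  # clip tiny negative float residue


def lagged_pairs(actions: np.ndarray, angles, speeds, lag_samples: int):
    """Pair each action with the state ``lag_samples`` later.

    Returns ``(actions[:F-lag], angles[lag:], speeds[lag:])``, all of
    length ``F - lag``.
    """
    n = len(actions)
    if lag_samples < 0:
        raise ValueError("lag must be >= 0")
    if lag_samples >= n:
        raise ValueError(f"lag {lag_samples} >= series length {n}")
    if lag_samples == 0:
        return actions, np.asarray(angles), np.asarray(speeds)
    return (
        actions[: n - lag_samples],
        np.asarray(angles)[lag_samples:],
        np.asarray(speeds)[lag_samples:],
    )


@dataclass(frozen=True)
class EntropyMetrics:
    """Per-trial utility and information-theoretic summary, all in bits."""

    utility: float
    H_S: float
    H_A_given_S: float
    H_Sprime_given_A: float
    I_A_Sprime: float
    lag_samples: int
    binning: str


def trial_metrics(
    trajectory: Trajectory,
    utility: float,
    spec: BinningSpec = BinningSpec(),
    lag_samples: int = DEFAULT_LAG_SAMPLES,
) -> EntropyMetrics:
    """All per-trial metrics under one shared binning.

    ``H(S)`` and ``H(A|S)`` use every recorded sample; ``H(S'|A)`` and
    ``I(A; S')`` use the action/lagged-state pairing and are computed
    from the same joint table, so ``I = H(S') - H(S'|A)`` holds exactly.
    """
    if len(trajectory) <= lag_samples:
        raise ValueError("trial shorter than the lag")
    s = discretize(trajectory.angles, trajectory.speeds, spec)
    a = SymbolSeries(trajectory.actions, 3)
    h_s = entropy(s)
    h_a_given_s = conditional_entropy(a, s)
    a_lag, ang_lag, spd_lag = lagged_pairs(
        trajectory.actions, trajectory.angles, trajectory.speeds, lag_samples
    )
    sprime = discretize(ang_lag, spd_lag, spec)
    a_paired = SymbolSeries(a_lag, 3)
    h_sprime_given_a = conditional_entropy(sprime, a_paired)
    i_a_sprime = mutual_information(a_paired, sprime)
    return EntropyMetrics(
        utility=float(utility),
        H_S=h_s,
        H_A_given_S=h_a_given_s,
        H_Sprime_given_A=h_sprime_given_a,
        I_A_Sprime=i_a_sprime,
        lag_samples=lag_samples,
        binning=spec.fingerprint(),
    )
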