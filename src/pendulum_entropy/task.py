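"""Reward and utility scoring of balancing trials.

A sample earns reward 0 when the pendulum is close to the balanced
configuration — angle within the open interval ``(pi - 0.27, pi + 0.27)``
(circular distance to upright) and ``|angular speed| < 0.2 rad/s`` — and
a fixed penalty ``c < 0`` otherwise.  The utility of a trial is the sum
of rewards over its recorded samples, so a trial that is never balanced
scores the floor ``F * c``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .dynamics import TWO_PI, State, Trajectory


@dataclass(frozen=True)
class RewardParams:
    penalty: float = -3e-3
    angle_halfwidth: float = 0.27
    speed_threshold: float = 0.2
    upright_angle: float = math.pi

    def __post_init__(self) -> None:
        if not self.penalty < 0:
            raise ValueError("penalty must be negative")
        if not (self.angle_halfwidth > 0 and self.speed_threshold > 0):
            raise ValueError("thresholds must be positive")


def _circular_distance(angle, target):
    d = np.abs(np.asarray(angle) - target) % TWO_PI
    return np.minimum(d, TWO_PI - d)


def in_balancing_region(
    state: State, params: RewardParams = RewardParams(), *, angle_only: bool = False
) -> bool:
    """Whether a state lies in the balancing region.

    ``angle_only=True`` tests only the angular condition (the region used
    by the time-in-region and key-press statistics); ``angle_only=False``
    additionally requires the speed condition of the reward.
    """
    ok = _circular_distance(state.angle, params.upright_angle) < params.angle_halfwidth
    if not angle_only:
        ok = ok and abs(state.angular_speed) < params.speed_threshold
    return bool(ok)


def reward(state: State, params: RewardParams = RewardParams()) -> float:
    """Per-sample reward: 0 in the balanced region, the penalty ``c`` outside."""
    return 0.0 if in_balancing_region(state, params) else params.penalty


def reward_array(angles, speeds, params: RewardParams = RewardParams()) -> np.ndarray:
    """Vectorised reward over parallel angle/speed arrays."""
    inside = (_circular_distance(angles, params.upright_angle) < params.angle_halfwidth) & (
        np.abs(speeds) < params.speed_threshold
    )
    return np.where(inside, 0.0, params.penalty)


def utility(trajectory: Trajectory, params: RewardParams = RewardParams()) -> float:
    """Sum of rewards over every recorded sample; 0 iff always balanced."""
    if len(trajectory) == 0:
        raise ValueError("cannot score an empty trajectory")
    return float(reward_array(trajectory.angles, trajectory.speeds, params).sum())
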