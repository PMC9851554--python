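"""Deterministic pendulum simulator with a three-key control interface.

The controlled system is a point mass on a weightless rod.  The angle
``theta`` is measured from the downward rest position and lives on
``[0, 2*pi)``; the upright (goal) configuration is ``theta = pi``.  The
controller contributes a tangential acceleration ``u`` of fixed magnitude
through three actions: push clockwise (``l``, ``-u``), do nothing
(``n``, ``0``) and push anti-clockwise (``r``, ``+u``).

Integration uses semi-implicit Euler by default: the angular speed is
updated first (with a per-step damping factor) and the angle is advanced
with the *new* speed, which keeps the undriven oscillation close to
energy-conserving at the study's step size.  Explicit Euler (angle
advanced with the old speed) is available as a switch.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np

TWO_PI = 2.0 * math.pi


class Action(enum.IntEnum):
    """Three-valued control: ``L`` applies ``-u``, ``N`` nothing, ``R`` ``+u``.

    ``R`` pushes anti-clockwise (increasing angle), ``L`` clockwise.
    The integer codes (0, 1, 2) are the internal alphabet used by the
    entropy estimators and the MDP policies; the on-disk trial dialect
    uses a different coding, translated in :mod:`pendulum_entropy.io`.
    """

    L = 0
    N = 1
    R = 2

    @property
    def sign(self) -> int:
        return {Action.L: -1, Action.N: 0, Action.R: 1}[self]


#: signs indexed by action code, for vectorised code paths
ACTION_SIGNS = np.array([-1.0, 0.0, 1.0])


@dataclass(frozen=True)
class PendulumParams:
    """Physical and numerical constants of the simulated pendulum.

    Defaults are the study conditions: unit mass, ``g = 1 m s^-2``,
    per-step damping ``5e-6``, key acceleration ``0.27 m s^-2`` and a
    sample interval of ``0.017 s``.
    """

    length: float = 0.5
    mass: float = 1.0
    gravity: float = 1.0
    damping: float = 5e-6
    control_accel: float = 0.27
    dt: float = 0.017
    semi_implicit: bool = True

    def __post_init__(self) -> None:
        if not (self.length > 0):
            raise ValueError(f"length must be positive, got {self.length}")
        if not (self.dt > 0):
            raise ValueError(f"dt must be positive, got {self.dt}")
        if not (0 <= self.damping < 1):
            raise ValueError(f"damping must be in [0, 1), got {self.damping}")
        if self.control_accel < 0:
            raise ValueError("control_accel must be >= 0")


@dataclass(frozen=True)
class State:
    """Pendulum state at one sample: wrapped angle and angular speed."""

    angle: float
    angular_speed: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.angle) and math.isfinite(self.angular_speed)):
            raise ValueError(f"non-finite state ({self.angle}, {self.angular_speed})")
        object.__setattr__(self, "angle", self.angle % TWO_PI)


@dataclass
class Trajectory:
    """Paired state and action time series of one trial.

    ``angles``/``speeds``/``actions`` all have length ``F`` (the number
    of recorded samples); ``actions[k]`` is the control chosen at sample
    ``k``.  Angles are stored wrapped to ``[0, 2*pi)``.
    """

    angles: np.ndarray
    speeds: np.ndarray
    actions: np.ndarray
    dt: float = 0.017

    def __post_init__(self) -> None:
        self.angles = np.asarray(self.angles, dtype=float)
        self.speeds = np.asarray(self.speeds, dtype=float)
        self.actions = np.asarray(self.actions, dtype=np.int64)
        if not (len(self.angles) == len(self.speeds) == len(self.actions)):
            raise ValueError("angles, speeds and actions must have equal length")

    def __len__(self) -> int:
        return len(self.angles)

    def state(self, k: int) -> State:
        return State(self.angles[k], self.speeds[k])


def angular_acceleration(state: State, u: float, params: PendulumParams) -> float:
    """Tangential angular acceleration ``(u - g sin(theta)) / L``."""
    if not math.isfinite(u):
        raise ValueError("control value must be finite")
    return (u - params.gravity * math.sin(state.angle)) / params.length


def step(state: State, action: Action, params: PendulumParams) -> State:
    """Advance one sample interval.

    Speed update: ``v' = (1 - d) v + a dt``.  Angle update: semi-implicit
    (``theta' = theta + v' dt``, default) or explicit (old ``v``).
    """
    u = Action(action).sign * params.control_accel
    acc = angular_acceleration(state, u, params)
    new_speed = (1.0 - params.damping) * state.angular_speed + acc * params.dt
    advance = new_speed if params.semi_implicit else state.angular_speed
    new_angle = (state.angle + advance * params.dt) % TWO_PI
    return State(new_angle, new_speed)


def simulate(
    policy,
    params: PendulumParams,
    n_steps: int,
    start: State | None = None,
    rng_seed: int | np.random.Generator | None = None,
) -> Trajectory:
    """Closed-loop rollout of ``policy`` for exactly ``n_steps`` samples.

    ``policy(state, rng)`` must return an :class:`Action` (stochastic
    policies draw from the passed generator, so a fixed seed makes the
    trajectory reproducible).  ``states[0]`` is ``start`` (downward and
    still by default) and ``states[k+1] = step(states[k], actions[k])``.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    s = start if start is not None else State(0.0, 0.0)
    angles = np.empty(n_steps)
    speeds = np.empty(n_steps)
    actions = np.empty(n_steps, dtype=np.int64)
    for k in range(n_steps):
        a = policy(s, rng)
        if a not in (Action.L, Action.N, Action.R):
            raise ValueError(f"policy returned non-action {a!r}")
        angles[k], speeds[k], actions[k] = s.angle, s.angular_speed, int(a)
        s = step(s, a, params)
    return Trajectory(angles, speeds, actions, dt=params.dt)


def total_energy(state: State, params: PendulumParams) -> float:
    """Mechanical energy per unit mass: ``0.5 L^2 v^2 + g L (1 - cos theta)``."""
    return 0.5 * params.length**2 * state.angular_speed**2 + params.gravity * params.length * (
        1.0 - math.cos(state.angle)
    )
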