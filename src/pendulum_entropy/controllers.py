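"""Synthetic-trial generator: an MDP controller family of graded skill.

The pendulum task is discretised on a uniform phase-plane grid and cast
as a Markov decision process ``(S, A, T, r)`` whose reward is the
balancing reward evaluated at bin centres.  The optimal policy is found
by value iteration and degraded into a family of epsilon-greedy
controllers: skill level ``n`` of ``N`` follows the optimal action with
probability ``1 - eps_n`` and acts uniformly at random otherwise, with
``eps_n = n / (N - 1)`` so the extremes are exactly the optimal and the
uniform-random controller (default ``N = 26`` levels).

Two disturbance channels mimic human sensorimotor noise, both zero-mean
scaled-binomial approximations of Gaussians: *observation* noise is
added to the state the controller perceives before it is binned and fed
to the policy, and *transition* noise is added to the angle and speed
difference equations.  The closed loop records the TRUE continuous
states, so the analysis stage sees exactly what the human-trial files
record.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from . import _kernels
from .dynamics import TWO_PI, ACTION_SIGNS, Action, PendulumParams, State, Trajectory
from .infotheory import BinningSpec
from .task import RewardParams, reward_array, utility as trial_utility

#: pendulum lengths of the study, metres (hardest to easiest)
STUDY_LENGTHS = (0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9)
#: samples per trial (2-minute trials at the study's sample interval)
STUDY_TRIAL_SAMPLES = 7026
#: number of epsilon-greedy skill levels
STUDY_SKILL_LEVELS = 26


@dataclass(frozen=True)
class GridSpec(BinningSpec):
    """Uniform MDP grid over the phase plane (default 1000 x 1000)."""

    angle_bins: int = 1000
    speed_bins: int = 1000

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.angle_bins < 2 or self.speed_bins < 2:
            raise ValueError("grid needs at least 2 bins per dimension")

    def bin_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Flat arrays of (angle, speed) centres for all ``n_symbols`` bins."""
        a = (np.arange(self.angle_bins) + 0.5) * (TWO_PI / self.angle_bins)
        w = (self.speed_hi - self.speed_lo) / self.speed_bins
        v = self.speed_lo + (np.arange(self.speed_bins) + 0.5) * w
        aa, vv = np.meshgrid(a, v, indexing="ij")
        return aa.ravel(), vv.ravel()


@dataclass(frozen=True)
class NoiseParams:
    """Transition (``_t``) and observation (``_o``) disturbance scales.

    Each disturbance is a scaled, centred ``Binomial(trials, 1/2)`` draw
    with the given standard deviation; ``binomial_trials`` controls how
    finely the Gaussian is approximated (support ``+/- sigma*sqrt(trials)``).
    """

    sigma_angle_t: float = 0.0
    sigma_speed_t: float = 0.0
    sigma_angle_o: float = 0.0
    sigma_speed_o: float = 0.0
    binomial_trials: int = 40

    def __post_init__(self) -> None:
        for s in (self.sigma_angle_t, self.sigma_speed_t, self.sigma_angle_o, self.sigma_speed_o):
            if s < 0:
                raise ValueError("noise sigmas must be >= 0")
        if self.binomial_trials < 2 or self.binomial_trials % 2:
            raise ValueError("binomial_trials must be even and >= 2")


@dataclass(frozen=True)
class SkillLevel:
    """Skill level ``n`` of ``N`` controllers: ``epsilon = n / N``.

    Level 0 is the optimal controller; level ``N - 1`` is almost fully
    random (``epsilon = (N-1)/N``).  ``spread="unit"`` rescales to
    ``epsilon = n / (N - 1)`` so the last level is exactly the uniform
    random controller.
    """

    level: int
    n_levels: int = STUDY_SKILL_LEVELS
    spread: str = "ratio"

    def __post_init__(self) -> None:
        if not (0 <= self.level < self.n_levels):
            raise ValueError(f"level must be in [0, {self.n_levels - 1}]")
        if self.spread not in ("ratio", "unit"):
            raise ValueError("spread must be 'ratio' or 'unit'")

    @property
    def epsilon(self) -> float:
        if self.spread == "unit":
            return self.level / (self.n_levels - 1)
        return self.level / self.n_levels


@dataclass
class Policy:
    """Per-state probability vectors over the three actions."""

    probs: np.ndarray  # (n_states, 3)

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 3:
            raise ValueError("policy must be (n_states, 3)")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("policy rows must sum to 1")

    @classmethod
    def from_actions(cls, actions: np.ndarray) -> "Policy":
        """One-hot deterministic policy from an action-code array."""
        probs = np.zeros((len(actions), 3))
        probs[np.arange(len(actions)), actions] = 1.0
        return cls(probs)

    @property
    def n_states(self) -> int:
        return self.probs.shape[0]


def sample_binomial_gaussian(sigma: float, trials: int, rng: np.random.Generator) -> float:
    """Zero-mean scaled-binomial draw: sd exactly ``sigma``, 0 if ``sigma == 0``."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return 0.0
    b = rng.binomial(trials, 0.5)
    return (b - trials / 2.0) * 2.0 * sigma / math.sqrt(trials)


def binomial_offsets(sigma: float, trials: int) -> tuple[np.ndarray, np.ndarray]:
    """Support and pmf of the scaled-binomial disturbance (a point mass at 0
    when ``sigma == 0``); used to convolve the MDP transition model."""
    if sigma == 0:
        return np.zeros(1), np.ones(1)
    k = np.arange(trials + 1)
    offsets = (k - trials / 2.0) * 2.0 * sigma / math.sqrt(trials)
    return offsets, stats.binom.pmf(k, trials, 0.5)


def noisy_step(
    state: State,
    action: Action,
    params: PendulumParams,
    noise: NoiseParams,
    rng: np.random.Generator,
) -> State:
    """Deterministic step, then transition disturbances, then wrap.

    With all transition sigmas zero this equals :func:`dynamics.step`.
    """
    from .dynamics import step

    s = step(state, action, params)
    if noise.sigma_angle_t == 0 and noise.sigma_speed_t == 0:
        return s
    d_angle = sample_binomial_gaussian(noise.sigma_angle_t, noise.binomial_trials, rng)
    d_speed = sample_binomial_gaussian(noise.sigma_speed_t, noise.binomial_trials, rng)
    return State(s.angle + d_angle, s.angular_speed + d_speed)


def observe(
    state: State, noise: NoiseParams, rng: np.random.Generator, grid: GridSpec
) -> int:
    """Corrupt the state with observation noise, then bin on the MDP grid.

    Returns the flat state-bin index the controller's policy is indexed by.
    """
    a = state.angle + sample_binomial_gaussian(noise.sigma_angle_o, noise.binomial_trials, rng)
    v = state.angular_speed + sample_binomial_gaussian(
        noise.sigma_speed_o, noise.binomial_trials, rng
    )
    return int(grid.angle_bin(a % TWO_PI) * grid.speed_bins + grid.speed_bin(v))


@dataclass
class MDP:
    """Tabular transition model and reward on the discretised phase plane.

    ``succ_idx[s, a, k]`` / ``succ_p[s, a, k]`` enumerate the successor
    bins of state bin ``s`` under action ``a`` and their probabilities
    (``k`` ranges over the disturbance support; a single column when the
    transition noise is zero).  ``rewards`` is the balancing reward at
    bin centres.
    """

    succ_idx: np.ndarray
    succ_p: np.ndarray
    rewards: np.ndarray
    grid: GridSpec
    params: PendulumParams

    @property
    def n_states(self) -> int:
        return len(self.rewards)


def _rebin_bilinear(grid: GridSpec, thetas: np.ndarray, speeds: np.ndarray):
    """Distribute each continuous successor over the 4 surrounding bin
    centres with bilinear weights (angle periodic, speed clamped).

    Nearest-bin rounding cannot represent drift smaller than a grid cell
    (every slow state becomes absorbing), so the tabular model is built
    with this stochastic interpolation instead: the successor *expectation*
    equals the continuous successor, at the cost of a one-cell diffusion.
    Returns (idx, w) of shape (..., 4).
    """
    aw = TWO_PI / grid.angle_bins
    vw = (grid.speed_hi - grid.speed_lo) / grid.speed_bins
    # fractional index relative to bin centres
    fa = (np.asarray(thetas) % TWO_PI) / aw - 0.5
    fv = (np.asarray(speeds) - grid.speed_lo) / vw - 0.5
    fv = np.clip(fv, 0.0, grid.speed_bins - 1.0)
    a0 = np.floor(fa).astype(np.int64)
    v0 = np.floor(fv).astype(np.int64)
    v0 = np.minimum(v0, grid.speed_bins - 2) if grid.speed_bins > 1 else v0 * 0
    ta = fa - a0
    tv = fv - v0
    a0 = a0 % grid.angle_bins
    a1 = (a0 + 1) % grid.angle_bins
    v1 = np.minimum(v0 + 1, grid.speed_bins - 1)
    idx = np.stack(
        [a0 * grid.speed_bins + v0, a0 * grid.speed_bins + v1,
         a1 * grid.speed_bins + v0, a1 * grid.speed_bins + v1], axis=-1
    )
    w = np.stack(
        [(1 - ta) * (1 - tv), (1 - ta) * tv, ta * (1 - tv), ta * tv], axis=-1
    )
    return idx, w


def build_mdp(
    params: PendulumParams,
    grid: GridSpec,
    noise: NoiseParams = NoiseParams(),
    reward_params: RewardParams = RewardParams(),
    interpolation: str = "bilinear",
) -> MDP:
    """Enumerate ``T(s'|s,a)`` by propagating bin centres through the step.

    Each bin-centre state is advanced deterministically for every action
    and the result convolved with the discrete angle/speed disturbance
    laws; each successor is wrapped (angle), clamped (speed) and mapped
    back to the grid.  With ``interpolation="bilinear"`` (default) the
    successor mass is split over the 4 surrounding cells so that slow
    drift survives discretisation (see :func:`_rebin_bilinear`);
    ``"nearest"`` rounds to the containing cell, giving exactly one
    successor per disturbance outcome.  Rows sum to 1 exactly.
    """
    if interpolation not in ("bilinear", "nearest"):
        raise ValueError(f"unknown interpolation {interpolation!r}")
    angles, speeds = grid.bin_centers()
    n_states = len(angles)
    a_off, a_pmf = binomial_offsets(noise.sigma_angle_t, noise.binomial_trials)
    v_off, v_pmf = binomial_offsets(noise.sigma_speed_t, noise.binomial_trials)
    n_out = len(a_off) * len(v_off)
    stencil = 4 if interpolation == "bilinear" else 1
    succ_idx = np.empty((n_states, 3, n_out * stencil), dtype=np.int64)
    succ_p = np.empty((n_states, 3, n_out * stencil))
    joint_p = np.outer(a_pmf, v_pmf).ravel()
    for code in range(3):
        u = ACTION_SIGNS[code] * params.control_accel
        acc = (u - params.gravity * np.sin(angles)) / params.length
        new_speed = (1.0 - params.damping) * speeds + acc * params.dt
        advance = new_speed if params.semi_implicit else speeds
        new_angle = angles + advance * params.dt
        # broadcast bin centres against the disturbance support
        na = (new_angle[:, None, None] + a_off[None, :, None]) % TWO_PI
        nv = new_speed[:, None, None] + v_off[None, None, :]
        na = np.broadcast_to(na, (n_states, len(a_off), len(v_off))).reshape(n_states, n_out)
        nv = np.broadcast_to(nv, (n_states, len(a_off), len(v_off))).reshape(n_states, n_out)
        if interpolation == "bilinear":
            idx, w = _rebin_bilinear(grid, na, nv)  # (n_states, n_out, 4)
            succ_idx[:, code, :] = idx.reshape(n_states, -1)
            succ_p[:, code, :] = (w * joint_p[None, :, None]).reshape(n_states, -1)
        else:
            idx = grid.angle_bin(na) * grid.speed_bins + grid.speed_bin(nv)
            succ_idx[:, code, :] = idx
            succ_p[:, code, :] = joint_p[None, :]
    rewards = reward_array(angles, speeds, reward_params)
    return MDP(succ_idx, succ_p, rewards, grid, params)


@dataclass(frozen=True)
class ValueIterationResult:
    values: np.ndarray
    policy: Policy
    greedy_actions: np.ndarray
    sweeps: int
    residual: float
    converged: bool


def value_iteration(
    mdp: MDP,
    gamma: float = 0.999,
    tol: float = 1e-6,
    max_sweeps: int = 10_000,
) -> ValueIterationResult:
    """Solve for the optimal values and a deterministic greedy policy.

    Discounted Bellman backups ``Q(s,a) = sum_{s'} T(s'|s,a) (r(s') +
    gamma V(s'))`` until the sup-norm change drops below ``tol``; the
    greedy policy breaks ties toward the lowest action code (l < n < r).
    Non-convergence is reported in the result, not raised.
    """
    values, sweeps, residual = _kernels.vi_sweeps(
        mdp.succ_idx, mdp.succ_p, mdp.rewards, gamma, tol, max_sweeps
    )
    acts = _kernels.greedy_actions(mdp.succ_idx, mdp.succ_p, mdp.rewards, values, gamma)
    return ValueIterationResult(
        values=values,
        policy=Policy.from_actions(acts),
        greedy_actions=acts,
        sweeps=sweeps,
        residual=residual,
        converged=residual < tol,
    )


def epsilon_greedy_policy(optimal: Policy, skill: SkillLevel) -> Policy:
    """Mix the optimal policy with the uniform policy.

    Per state, the optimal action gets ``(1 - eps) + eps/3`` and each
    other action ``eps/3``.
    """
    eps = skill.epsilon
    probs = (1.0 - eps) * optimal.probs + eps / 3.0
    return Policy(probs)


@dataclass
class TrialRecord:
    """One synthetic trial: trajectory plus provenance metadata."""

    trajectory: Trajectory
    length: float
    utility: float
    source: str = "controller"
    skill_level: int | None = None
    epsilon: float | None = None
    participant: int | None = None
    seed: int | None = None


def run_controller(
    policy: Policy,
    params: PendulumParams,
    grid: GridSpec,
    noise: NoiseParams = NoiseParams(),
    n_steps: int = STUDY_TRIAL_SAMPLES,
    seed: int = 0,
    start: State | None = None,
    reward_params: RewardParams = RewardParams(),
) -> TrialRecord:
    """Run the closed loop for ``n_steps`` samples and score the trial.

    Loop per sample: true state -> noisy observation -> binned policy
    lookup -> sampled action -> noisy step.  The recorded series are the
    true continuous states and the chosen actions; identical seeds give
    bit-identical records.
    """
    if policy.n_states != grid.n_symbols:
        raise ValueError("policy size does not match the grid")
    s0 = start if start is not None else State(0.0, 0.0)
    angles, speeds, actions = _kernels.rollout(
        np.ascontiguousarray(policy.probs),
        grid.angle_bins,
        grid.speed_bins,
        grid.speed_lo,
        grid.speed_hi,
        params.length,
        params.gravity,
        params.damping,
        params.control_accel,
        params.dt,
        params.semi_implicit,
        noise.sigma_angle_t,
        noise.sigma_speed_t,
        noise.sigma_angle_o,
        noise.sigma_speed_o,
        noise.binomial_trials,
        n_steps,
        seed,
        s0.angle,
        s0.angular_speed,
    )
    traj = Trajectory(angles, speeds, actions, dt=params.dt)
    return TrialRecord(
        trajectory=traj,
        length=params.length,
        utility=trial_utility(traj, reward_params),
        seed=seed,
    )


def derive_seeds(base_seed: int, n: int) -> np.ndarray:
    """Deterministic per-trial seeds below 2**31 from one base seed."""
    return np.random.SeedSequence(base_seed).generate_state(n) & 0x7FFFFFFF


def run_grid(
    lengths=STUDY_LENGTHS,
    n_levels: int = STUDY_SKILL_LEVELS,
    noise: NoiseParams = NoiseParams(),
    base_params: PendulumParams = PendulumParams(),
    grid: GridSpec = GridSpec(),
    n_steps: int = STUDY_TRIAL_SAMPLES,
    base_seed: int = 0,
    gamma: float = 0.999,
    tol: float = 1e-6,
    max_sweeps: int = 10_000,
    model_transition_noise: bool = True,
    reward_params: RewardParams = RewardParams(),
    skill_spread: str = "ratio",
    progress=None,
) -> list[TrialRecord]:
    """The full controller study: one trial per (length, skill level).

    Value iteration runs once per length (on the transition model, which
    includes the transition noise unless ``model_transition_noise`` is
    off) and the resulting optimal policy is degraded into ``n_levels``
    epsilon-greedy controllers, each rolled out for ``n_steps`` samples
    with a seed derived deterministically from ``base_seed``.
    """
    lengths = list(lengths)
    seeds = derive_seeds(base_seed, len(lengths) * n_levels)
    model_noise = noise if model_transition_noise else replace(
        noise, sigma_angle_t=0.0, sigma_speed_t=0.0
    )
    records: list[TrialRecord] = []
    for i, length in enumerate(lengths):
        params = replace(base_params, length=length)
        mdp = build_mdp(params, grid, model_noise, reward_params)
        vi = value_iteration(mdp, gamma=gamma, tol=tol, max_sweeps=max_sweeps)
        for n in range(n_levels):
            skill = SkillLevel(n, n_levels, skill_spread)
            pol = epsilon_greedy_policy(vi.policy, skill)
            rec = run_controller(
                pol,
                params,
                grid,
                noise=noise,
                n_steps=n_steps,
                seed=int(seeds[i * n_levels + n]),
                reward_params=reward_params,
            )
            rec.skill_level = n
            rec.epsilon = skill.epsilon
            records.append(rec)
            if progress is not None:
                progress()
    return records
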