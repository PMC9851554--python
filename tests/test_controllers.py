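"""MDP controller family: disturbances, model building, value iteration
against brute-force policy enumeration, and closed-loop behaviour."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from pendulum_entropy.controllers import (
    MDP,
    GridSpec,
    NoiseParams,
    Policy,
    SkillLevel,
    binomial_offsets,
    build_mdp,
    epsilon_greedy_policy,
    noisy_step,
    observe,
    run_controller,
    run_grid,
    sample_binomial_gaussian,
    value_iteration,
)
from pendulum_entropy.dynamics import Action, PendulumParams, State, step
from pendulum_entropy.infotheory import SymbolSeries, conditional_entropy, discretize


# --- binomial-Gaussian disturbances ------------------------------------------

def test_binomial_gaussian_zero_sigma(rng):
    assert all(sample_binomial_gaussian(0.0, 40, rng) == 0.0 for _ in range(10))


def test_binomial_gaussian_moments(rng):
    draws = np.array([sample_binomial_gaussian(0.1, 40, rng) for _ in range(100_000)])
    assert abs(draws.mean()) < 3 * 0.1 / math.sqrt(100_000)
    assert draws.std() == pytest.approx(0.1, rel=0.03)
    bound = 0.1 * math.sqrt(40)
    assert np.all(np.abs(draws) <= bound + 1e-12)
    # symmetric support
    assert -draws.min() == pytest.approx(draws.max(), rel=0.5)


def test_binomial_offsets_are_exact_law():
    off, pmf = binomial_offsets(0.25, 40)
    assert pmf.sum() == pytest.approx(1.0, abs=1e-12)
    assert (off * pmf).sum() == pytest.approx(0.0, abs=1e-12)
    assert (off**2 * pmf).sum() == pytest.approx(0.25**2, rel=1e-9)
    off0, pmf0 = binomial_offsets(0.0, 40)
    assert list(off0) == [0.0] and list(pmf0) == [1.0]


def test_noise_params_validation():
    with pytest.raises(ValueError):
        NoiseParams(sigma_angle_t=-0.1)
    with pytest.raises(ValueError):
        NoiseParams(binomial_trials=7)


# --- noisy step and observation ----------------------------------------------

def test_noisy_step_zero_sigma_equals_step(params, rng):
    s = State(1.0, 0.5)
    exact = step(s, Action.R, params)
    noisy = noisy_step(s, Action.R, params, NoiseParams(), rng)
    assert (noisy.angle, noisy.angular_speed) == (exact.angle, exact.angular_speed)


def test_noisy_step_speed_spread(params):
    noise = NoiseParams(sigma_speed_t=0.014)
    rng = np.random.default_rng(5)
    outs = np.array(
        [
            noisy_step(State(1.0, 0.5), Action.N, params, noise, rng).angular_speed
            for _ in range(10_000)
        ]
    )
    assert outs.std() == pytest.approx(0.014, rel=0.05)


def test_noisy_step_seeded_reproducible(params):
    noise = NoiseParams(sigma_angle_t=0.01, sigma_speed_t=0.02)
    a = noisy_step(State(1.0, 0.5), Action.L, params, noise, np.random.default_rng(9))
    b = noisy_step(State(1.0, 0.5), Action.L, params, noise, np.random.default_rng(9))
    assert (a.angle, a.angular_speed) == (b.angle, b.angular_speed)


def test_observe_zero_noise_is_direct_binning(small_grid, rng):
    s = State(2.0, -1.0)
    idx = observe(s, NoiseParams(), rng, small_grid)
    assert idx == discretize([s.angle], [s.angular_speed], small_grid).symbols[0]


def test_observe_offset_distribution_matches_binomial_law(small_grid):
    """Empirical (observed - true) angle-bin offsets follow the scaled law."""
    noise = NoiseParams(sigma_angle_o=1.0)
    rng = np.random.default_rng(11)
    s = State(math.pi, 0.0)
    true_bin = discretize([s.angle], [0.0], small_grid).symbols[0] // small_grid.speed_bins
    obs_bins = np.array(
        [observe(s, noise, rng, small_grid) // small_grid.speed_bins for _ in range(20_000)]
    )
    # with sigma >> bin width the observed bin differs except when the
    # scaled-binomial offset is exactly zero (probability C(40,20)/2^40 ~ 0.125)
    assert (obs_bins != true_bin).mean() == pytest.approx(1 - 0.1254, abs=0.02)
    # analytic law: each binomial offset lands in a known bin
    off, pmf = binomial_offsets(1.0, noise.binomial_trials)
    width = 2 * math.pi / small_grid.angle_bins
    expected = np.zeros(small_grid.angle_bins)
    for o, p in zip(off, pmf):
        expected[int(((s.angle + o) % (2 * math.pi)) / width)] += p
    empirical = np.bincount(obs_bins, minlength=small_grid.angle_bins) / len(obs_bins)
    assert np.abs(empirical - expected).sum() / 2 < 0.02  # total variation


# --- transition model ---------------------------------------------------------

def test_build_mdp_zero_noise_nearest_single_successor(params):
    grid = GridSpec(angle_bins=20, speed_bins=20, speed_lo=-5, speed_hi=5)
    mdp = build_mdp(params, grid, interpolation="nearest")
    assert mdp.succ_idx.shape == (400, 3, 1)
    assert np.all(mdp.succ_p == 1.0)


@pytest.mark.parametrize("interp", ["nearest", "bilinear"])
def test_build_mdp_rows_stochastic_with_noise(params, interp):
    grid = GridSpec(angle_bins=20, speed_bins=20, speed_lo=-5, speed_hi=5)
    noise = NoiseParams(sigma_angle_t=0.05, sigma_speed_t=0.1, binomial_trials=8)
    mdp = build_mdp(params, grid, noise, interpolation=interp)
    sums = mdp.succ_p.sum(axis=2)
    assert np.allclose(sums, 1.0, atol=1e-9)


def test_build_mdp_matches_hand_convolution(params):
    """Toy grid, speed noise of one bin width: successor mass equals the
    explicitly convolved binomial law."""
    grid = GridSpec(angle_bins=10, speed_bins=10, speed_lo=-2, speed_hi=2)
    width = 0.4
    noise = NoiseParams(sigma_speed_t=width, binomial_trials=8)
    mdp = build_mdp(params, grid, noise, interpolation="nearest")
    angles, speeds = grid.bin_centers()
    off, pmf = binomial_offsets(width, 8)
    s, code = 37, 2
    succ = step(State(angles[s], speeds[s]), Action(code), params)
    expected = np.zeros(100)
    for o, p in zip(off, pmf):
        a_bin = grid.angle_bin(succ.angle)
        v_bin = grid.speed_bin(succ.angular_speed + o)
        expected[int(a_bin) * 10 + int(v_bin)] += p
    got = np.zeros(100)
    np.add.at(got, mdp.succ_idx[s, code], mdp.succ_p[s, code])
    assert np.allclose(got, expected, atol=1e-12)


# --- value iteration ----------------------------------------------------------

def _chain_mdp(rewards, gamma_grid=None):
    """3-state chain: action 0 stays, 1 moves right, 2 moves left."""
    succ = np.zeros((3, 3, 1), dtype=np.int64)
    for s in range(3):
        succ[s, 0, 0] = s
        succ[s, 1, 0] = min(s + 1, 2)
        succ[s, 2, 0] = max(s - 1, 0)
    probs = np.ones((3, 3, 1))
    grid = GridSpec(angle_bins=2, speed_bins=2)
    return MDP(succ, probs, np.asarray(rewards, float), grid, PendulumParams())


def _enumerate_optimal(mdp, gamma):
    """Exact values of every deterministic policy by linear solve."""
    n = mdp.n_states
    best_v, best_pi = None, None
    for pi in itertools.product(range(3), repeat=n):
        t = np.zeros((n, n))
        for s in range(n):
            t[s, mdp.succ_idx[s, pi[s], 0]] = 1.0
        v = np.linalg.solve(np.eye(n) - gamma * t, t @ mdp.rewards)
        if best_v is None or v.sum() > best_v.sum() + 1e-12:
            best_v, best_pi = v, pi
    return best_v, best_pi


def test_value_iteration_zero_rewards():
    mdp = _chain_mdp([0.0, 0.0, 0.0])
    vi = value_iteration(mdp, gamma=0.9)
    assert np.allclose(vi.values, 0.0)
    assert vi.converged


def test_value_iteration_matches_policy_enumeration():
    mdp = _chain_mdp([-1.0, -0.5, 0.0])
    gamma = 0.9
    vi = value_iteration(mdp, gamma=gamma, tol=1e-12)
    best_v, _ = _enumerate_optimal(mdp, gamma)
    assert np.allclose(vi.values, best_v, atol=1e-8)
    # from every state the optimal move heads toward the absorbing goal
    assert list(vi.greedy_actions) == [1, 1, 0]


def test_value_iteration_values_nonpositive(solved_l05):
    _, _, vi = solved_l05
    assert np.all(vi.values <= 1e-12)


def test_value_iteration_reports_nonconvergence():
    # all states cost something, so values keep shrinking geometrically and
    # three sweeps cannot reach the tolerance
    mdp = _chain_mdp([-1.0, -0.5, -0.1])
    vi = value_iteration(mdp, gamma=0.999, tol=1e-14, max_sweeps=3)
    assert not vi.converged
    assert vi.sweeps == 3 and vi.residual > 1e-14


# --- policies -----------------------------------------------------------------

def test_epsilon_greedy_mixture():
    base = Policy.from_actions(np.array([0, 1, 2, 1]))
    assert np.allclose(epsilon_greedy_policy(base, SkillLevel(0)).probs, base.probs)
    uniform = epsilon_greedy_policy(base, SkillLevel(25, spread="unit"))
    assert np.allclose(uniform.probs, 1 / 3)
    half = epsilon_greedy_policy(base, SkillLevel(13, 26, spread="unit"))  # eps = 0.52
    eps = 13 / 25
    assert half.probs[0, 0] == pytest.approx(1 - eps + eps / 3)
    assert half.probs[0, 1] == pytest.approx(eps / 3)


def test_skill_level_epsilon_families():
    assert SkillLevel(0).epsilon == 0.0
    assert SkillLevel(25).epsilon == pytest.approx(25 / 26)
    assert SkillLevel(25, spread="unit").epsilon == 1.0
    with pytest.raises(ValueError):
        SkillLevel(26)


def test_policy_rows_must_sum_to_one():
    with pytest.raises(ValueError):
        Policy(np.full((2, 3), 0.5))


# --- closed loop --------------------------------------------------------------

def test_run_controller_reproducible(solved_l05, small_grid):
    p, _, vi = solved_l05
    a = run_controller(vi.policy, p, small_grid, n_steps=500, seed=99)
    b = run_controller(vi.policy, p, small_grid, n_steps=500, seed=99)
    assert np.array_equal(a.trajectory.angles, b.trajectory.angles)
    assert np.array_equal(a.trajectory.actions, b.trajectory.actions)
    assert a.utility == b.utility


def test_random_controller_action_frequencies(solved_l05, small_grid):
    p, _, vi = solved_l05
    pol = epsilon_greedy_policy(vi.policy, SkillLevel(25, spread="unit"))
    rec = run_controller(pol, p, small_grid, n_steps=6000, seed=4)
    freqs = np.bincount(rec.trajectory.actions, minlength=3) / 6000
    assert np.allclose(freqs, 1 / 3, atol=0.03)


def test_optimal_beats_random(solved_l05, small_grid):
    p, _, vi = solved_l05
    rand = epsilon_greedy_policy(vi.policy, SkillLevel(25, spread="unit"))
    u_opt = run_controller(vi.policy, p, small_grid, n_steps=7026, seed=8).utility
    u_rand = run_controller(rand, p, small_grid, n_steps=7026, seed=8).utility
    assert u_opt > u_rand


def test_zero_noise_deterministic_policy_has_zero_grid_action_entropy(
    solved_l05, small_grid
):
    """On the MDP grid binning the action is a function of the state bin."""
    p, _, vi = solved_l05
    rec = run_controller(vi.policy, p, small_grid, n_steps=2000, seed=1)
    s = discretize(rec.trajectory.angles, rec.trajectory.speeds, small_grid)
    a = SymbolSeries(rec.trajectory.actions, 3)
    assert conditional_entropy(a, s) == pytest.approx(0.0, abs=1e-12)


def test_observation_noise_increases_action_entropy(solved_l05, small_grid):
    p, _, vi = solved_l05
    quiet = run_controller(vi.policy, p, small_grid, n_steps=7026, seed=2)
    noisy = run_controller(
        vi.policy,
        p,
        small_grid,
        noise=NoiseParams(sigma_angle_o=0.1, sigma_speed_o=0.2),
        n_steps=7026,
        seed=2,
    )
    def h_a_given_s(rec):
        s = discretize(rec.trajectory.angles, rec.trajectory.speeds)
        return conditional_entropy(SymbolSeries(rec.trajectory.actions, 3), s)
    assert h_a_given_s(noisy) > h_a_given_s(quiet)


# --- the grid of simulations --------------------------------------------------

def test_run_grid_shape_and_determinism(small_grid):
    a = run_grid(lengths=(0.4, 0.8), n_levels=3, grid=small_grid, n_steps=400, base_seed=5)
    b = run_grid(lengths=(0.4, 0.8), n_levels=3, grid=small_grid, n_steps=400, base_seed=5)
    assert len(a) == 6
    assert [(r.length, r.skill_level) for r in a] == [
        (0.4, 0), (0.4, 1), (0.4, 2), (0.8, 0), (0.8, 1), (0.8, 2)
    ]
    for ra, rb in zip(a, b):
        assert np.array_equal(ra.trajectory.angles, rb.trajectory.angles)
        assert ra.utility == rb.utility


def test_skill_ordering_utility_degrades(mini_study):
    """Utility falls with epsilon: strongly negative rank correlation."""
    eps = [r.epsilon for r in mini_study]
    u = [r.utility for r in mini_study]
    rho = stats.spearmanr(eps, u).statistic
    assert rho < -0.7


def test_narrow_corridor_support(mini_study):
    """The optimal controller occupies fewer phase-space cells than the
    most random one, for every length."""
    by_length = {}
    for rec in mini_study:
        by_length.setdefault(rec.length, {})[rec.skill_level] = rec
    for length, levels in by_length.items():
        best, worst = levels[0], levels[max(levels)]
        def support(rec):
            return len(np.unique(discretize(rec.trajectory.angles, rec.trajectory.speeds).symbols))
        assert support(best) < support(worst)
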