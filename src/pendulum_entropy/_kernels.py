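"""Numba kernels for the hot loops: value-iteration sweeps and rollouts.

The kernels operate on flat arrays only; the object-level API lives in
:mod:`pendulum_entropy.controllers`.  Random draws inside the rollout use
numba's ``np.random`` bridge seeded once per call, so a trial is fully
reproducible from its integer seed.
"""

from __future__ import annotations

import numpy as np
from numba import njit

TWO_PI = 2.0 * np.pi


@njit(cache=True)
def vi_sweeps(succ_idx, succ_p, rewards, gamma, tol, max_sweeps):
    """Gauss-Jacobi value-iteration sweeps until the sup-norm change < tol.

    ``Q(s, a) = sum_k p[s,a,k] * (r[j] + gamma * V[j])`` with ``j`` the
    k-th successor bin.  Returns (values, sweeps_run, last_residual).
    """
    n_states, n_actions, n_succ = succ_idx.shape
    values = np.zeros(n_states)
    delta = 0.0
    for sweep in range(max_sweeps):
        new_values = np.empty(n_states)
        delta = 0.0
        for s in range(n_states):
            best = -1.0e300
            for a in range(n_actions):
                q = 0.0
                for k in range(n_succ):
                    j = succ_idx[s, a, k]
                    q += succ_p[s, a, k] * (rewards[j] + gamma * values[j])
                if q > best:
                    best = q
            new_values[s] = best
            d = abs(best - values[s])
            if d > delta:
                delta = d
        values = new_values
        if delta < tol:
            return values, sweep + 1, delta
    return values, max_sweeps, delta


@njit(cache=True)
def greedy_actions(succ_idx, succ_p, rewards, values, gamma):
    """Greedy policy from converged values; ties broken by lowest action code."""
    n_states, n_actions, n_succ = succ_idx.shape
    policy = np.empty(n_states, dtype=np.int64)
    for s in range(n_states):
        best = -1.0e300
        best_a = 0
        for a in range(n_actions):
            q = 0.0
            for k in range(n_succ):
                j = succ_idx[s, a, k]
                q += succ_p[s, a, k] * (rewards[j] + gamma * values[j])
            if q > best:
                best = q
                best_a = a
        policy[s] = best_a
    return policy


@njit(cache=True, inline="always")
def _binomial_disturbance(sigma, trials):
    """Zero-mean scaled-binomial draw with standard deviation ``sigma``."""
    if sigma <= 0.0:
        return 0.0
    b = np.random.binomial(trials, 0.5)
    return (b - trials / 2.0) * 2.0 * sigma / np.sqrt(trials)


@njit(cache=True)
def rollout(
    policy_probs,
    angle_bins,
    speed_bins,
    speed_lo,
    speed_hi,
    length,
    gravity,
    damping,
    control_accel,
    dt,
    semi_implicit,
    sig_angle_t,
    sig_speed_t,
    sig_angle_o,
    sig_speed_o,
    binom_trials,
    n_steps,
    seed,
    start_angle,
    start_speed,
):
    """Closed loop: true state -> noisy observation -> policy -> noisy step.

    Records the TRUE continuous states and the chosen actions.  Action
    codes are 0 (``-u``), 1 (no action), 2 (``+u``).
    """
    np.random.seed(seed)
    angles = np.empty(n_steps)
    speeds = np.empty(n_steps)
    actions = np.empty(n_steps, dtype=np.int64)
    angle_width = TWO_PI / angle_bins
    speed_width = (speed_hi - speed_lo) / speed_bins
    theta = start_angle
    speed = start_speed
    for k in range(n_steps):
        # observe: corrupt, wrap, clamp, bin on the MDP grid
        obs_theta = (theta + _binomial_disturbance(sig_angle_o, binom_trials)) % TWO_PI
        obs_speed = speed + _binomial_disturbance(sig_speed_o, binom_trials)
        a_bin = int(obs_theta / angle_width)
        if a_bin >= angle_bins:
            a_bin = angle_bins - 1
        v_bin = int((obs_speed - speed_lo) / speed_width)
        if v_bin < 0:
            v_bin = 0
        elif v_bin >= speed_bins:
            v_bin = speed_bins - 1
        s_idx = a_bin * speed_bins + v_bin
        # sample the action from the policy row
        u01 = np.random.random()
        action = 0
        acc_p = policy_probs[s_idx, 0]
        while u01 >= acc_p and action < 2:
            action += 1
            acc_p += policy_probs[s_idx, action]
        angles[k] = theta
        speeds[k] = speed
        actions[k] = action
        # deterministic step then transition disturbances
        u = (action - 1) * control_accel
        acc = (u - gravity * np.sin(theta)) / length
        new_speed = (1.0 - damping) * speed + acc * dt
        if semi_implicit:
            theta = theta + new_speed * dt
        else:
            theta = theta + speed * dt
        theta = (theta + _binomial_disturbance(sig_angle_t, binom_trials)) % TWO_PI
        speed = new_speed + _binomial_disturbance(sig_speed_t, binom_trials)
    return angles, speeds, actions
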