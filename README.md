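# pendulum-entropy

State/action entropy analysis of skilled inverted-pendulum balancing.

Two classical accounts of motor skill make opposite predictions about
what mastery looks like in information terms. *Routinization* says
skilled behaviour is stereotyped: given the situation, the expert's
action is nearly certain, so the conditional action entropy H(A|S) is
low. *Perceptual control* says the expert stabilises what they perceive,
not what they do: the states S visited are squeezed into a narrow
corridor of the phase plane (low H(S)), while the actions that keep them
there remain variable (high H(A|S)). A pendulum-balancing task — swing a
pendulum of length *L* upright with two keys applying ±0.27 m s⁻² and
hold it there for two minutes — separates the two accounts cleanly,
because task difficulty is a dial (short pendulums are fast and hard).

This package provides the full computational pipeline for that study,
for researchers in computational motor control:

* `dynamics` — the controlled pendulum, θ̈ = (u − g sin θ)/L, integrated
  semi-implicitly at Δt = 0.017 s;
* `task` — the balancing reward (0 within ±0.27 rad of upright at
  |θ̇| < 0.2 rad s⁻¹, −3×10⁻³ elsewhere) and trial utility
  U = Σₙ r(sₙ);
* `infotheory` — plug-in estimators of H(S), H(A|S), H(S′|A) and
  I(A;S′) on a fixed 1000×200 binning of the phase plane, with S′ the
  state 270 ms after the action;
* `controllers` — a synthetic-trial generator: value iteration on a
  binned MDP of the task, degraded into 26 epsilon-greedy skill levels
  (ε = n/26), deployed under binomial-approximated Gaussian observation
  and/or transition noise;
* `analysis` — per-trial metric tables, Spearman/Pearson
  utility–entropy correlations (pooled and per length), key-press
  episode statistics and phase-space support;
* `io` / `cli` — readers and writers for the deposited trial and
  results CSV dialects, and a `pendulum-entropy` command with
  `simulate` / `analyze` / `correlate` / `report` subcommands.

The numbered scripts under `analysis/` run the study end to end and
write their tables under `results/`.

## Worked example

Simulate the controller study (both noise arms, 26 skill levels × 8
lengths, ~10 s on one CPU) and correlate:

```
$ python analysis/01_simulate_controllers.py --seed 0
[noiseless] wrote 208 trials to results/controller_metrics_noiseless.csv
  best trial: L=0.2 m, eps=0.00, U=-1.209, H(S)=2.47 bits, H(A|S)=0.00 bits
  pooled Spearman: rho(U, H(S)) = -0.954, rho(U, H(A|S)) = +0.470
[obs_noise] wrote 208 trials to results/controller_metrics_obs_noise.csv
  best trial: L=0.2 m, eps=0.00, U=-1.716, H(S)=6.61 bits, H(A|S)=1.25 bits
  pooled Spearman: rho(U, H(S)) = -0.880, rho(U, H(A|S)) = +0.863

$ python analysis/02_correlations.py
[obs_noise] ...
  pooled U ~ H_A_given_S      : rho = +0.863 (p = 4.2e-63), r = +0.941
  pooled U ~ H_S              : rho = -0.880 (p = 1.6e-68), r = -0.941
  mean H(S) - H(S'|A) gap = 1.133 bits (mean I(A;S') = 1.133 bits)
```

Reading the numbers: utility U counts time spent un-balanced (0 is
perfect, −21.078 means never balanced). In both arms, better-performing
controllers occupy a smaller slice of the phase plane — the strongly
negative rho(U, H(S)). Without any disturbance the best trial is also
perfectly stereotyped (H(A|S) = 0 bits): a deterministic policy in a
deterministic world re-issues identical actions in identical states.
Adding observation noise at realistic magnitudes (angle sd 0.1 rad,
speed sd 0.2 rad s⁻¹) flips that signature: the best controller still
balances 80 % of the trial, but now mixes all three keys within each
state cell (H(A|S) = 1.25 bits), and action entropy becomes strongly
*positively* correlated with utility — stable perception by variable
means. The ~1.1-bit gap between H(S) and H(S′|A), equal to the mean
I(A;S′), is the share of state information injected by the actions
themselves (close to log₂3 ≈ 1.6, the information in one key choice).

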