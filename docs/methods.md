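# Methods

## The controlled system

The plant is a point mass *m* = 1 kg on a weightless rod of length *L*,
driven by gravity (*g* = 1 m s⁻²) and a three-valued control: hold the
"left" key (tangential acceleration −*u*), hold the "right" key (+*u*),
or do nothing, with *u* = 0.27 m s⁻². Angles are measured from the
downward rest position and wrapped to [0, 2π); the goal configuration is
upright, θ = π. The continuous dynamics is

    θ̈ = (u − g sin θ) / L,

integrated with a semi-implicit Euler scheme at the recording interval
Δt = 0.017 s:

    θ̇' = (1 − d) θ̇ + θ̈ Δt,      θ' = θ + θ̇' Δt  (wrapped),

with per-step damping d = 5×10⁻⁶. Advancing the angle with the *new*
speed keeps the undriven oscillation within 1 % of constant energy over
a full period at this step size (asserted numerically in the tests);
plain explicit Euler is available behind `PendulumParams(semi_implicit=
False)`. A trial is F = 7026 samples (two minutes), started still and
downward.

The division-by-*L* reading of the angular acceleration is the standard
tangential-force pendulum; it is also the only reading in which the
control and gravity terms share units.

## Reward and utility

A sample is "balanced" when θ lies within the open interval
(π − 0.27, π + 0.27) — membership is evaluated by circular distance, so
wrap-adjacent angles are handled — and |θ̇| < 0.2 rad s⁻¹. Balanced
samples earn reward 0; every other sample earns c = −3×10⁻³. The trial
utility U is the sum over the F recorded samples, so U = c · (number of
out-of-region samples): 0 is perfect and F·c = −21.078 is the floor.
Summing over exactly the recorded samples (rather than F+1 terms) keeps
the floor consistent with the recorded series length.

## Entropy estimation

Per trial we estimate, in bits:

* H(S) — entropy of the binned state distribution,
* H(A|S) — conditional entropy of the key given the binned state,
* H(S′|A) — conditional entropy of the *lagged* state given the action,
* I(A;S′) — mutual information between the action and the lagged state,

where S′ is the state 270 ms after the action was selected
(approximating motor-execution delay). All estimators are plug-in
(maximum-likelihood) on the empirical symbol tables with 0·log 0 ≡ 0 and
log base 2; no bias correction is applied, because the comparisons of
interest are *between trials under an identical binning*, where the
shared offset and the occupancy-dependent bias are part of the measured
signal (see "What the estimator measures" below).

The binning is uniform: 1000 angle bins over [0, 2π) and 200 speed bins
over [−10, 10] rad s⁻¹, out-of-range speeds clamped to the edge bins.
Binned entropies are only comparable under one binning, so every metrics
row carries the binning fingerprint.

Before estimation the series is decimated to every 4th sample (one
sample per 68 ms); the lag is then 4 decimated samples (272 ms). The
decimation rate is a reconstruction choice: the estimators are meant to
treat successive samples as draws from the trial's state distribution,
and at the raw 59 Hz recording rate consecutive samples are so strongly
dependent that slow phase-space sweeps re-visit single cells many times,
inflating the conditional action entropy of unskilled trials. One sample
per ~70 ms keeps 1756 samples per trial — enough for stable estimates —
while bringing consecutive samples close to cell-to-cell independence.
Utility always uses all F raw samples.

### What the estimator measures

With ~1756 samples spread over 10³–10⁴ visited cells, the plug-in
H(A|S) of a *spread-out* trial is driven toward 0 (most cells are
visited once), while a trial concentrated in few cells measures the
genuine within-cell action variability. This finite-sample behaviour is
not a defect here: it is precisely what makes the statistic sensitive to
the combination of state compression and action variability that
distinguishes skilled from unskilled control. It does mean the absolute
bit values are binning- and sample-size-specific.

## The artificial controller family

The synthetic-data generator is an MDP controller family. The phase
plane is binned into a uniform planning grid and the tuple (Ŝ, A, T, r)
is built by propagating every bin-centre state through the deterministic
step for each action; r is the balancing reward at bin centres.

**Successor interpolation.** The per-step drift of this plant is smaller
than a grid cell at any tractable grid (e.g. the speed change from a key
press is u/L·Δt ≈ 0.005 rad s⁻¹), so rounding successors to the nearest
cell makes every slow state absorbing and value iteration finds no
swing-up at all (verified numerically). The transition model therefore
distributes each successor over the four surrounding cells with
bilinear weights — the Kushner–Dupuis Markov-chain approximation — whose
expectation equals the continuous successor. Nearest rounding is kept as
`build_mdp(..., interpolation="nearest")` for degenerate-model
experiments.

**Noise channels.** Transition noise (added to the angle and speed
update equations) and observation noise (added to the state the
controller perceives before binning) are zero-mean scaled binomials:
(B − m/2)·2σ/√m with B ~ Binomial(m, ½), m = 40, giving exact sd σ on a
discrete, bounded support. Transition noise is convolved into the MDP
model (switchable) and injected in the simulator; observation noise only
affects the deployed decision loop — the policy itself is always
computed on the noise-free state space (no partially-observable
machinery).

**Planning.** Value iteration with discount γ = 0.999 (an effective
horizon of ~10³ steps ≈ 17 s, long enough to span swing-up and
recovery), tolerance 10⁻⁶ on the sup-norm change, at most 10⁴ sweeps;
the greedy policy breaks exact ties toward the lowest action code
(left < none < right). Values are identically ≤ 0 because rewards are.

**Skill.** The optimal policy is degraded epsilon-greedily: at skill
level n of N = 26, the controller follows the optimal action with
probability 1 − ε and draws uniformly from the three actions otherwise,
with ε_n = n/N, n = 0…25. The top level is exactly optimal; the bottom
level is 96 % random. (An alternative `spread="unit"` family with
ε = n/(N−1) reaching a fully random controller is available; the n/N
family is the default because a pure-random controller's measured
H(A|S) is dominated by the occupancy effect described above while its
utility sits at the floor, a corner the ε ≤ 25/26 family avoids.)

**Closed loop.** Per sample: true state → observation (noise, wrap,
clamp, bin) → policy lookup → action sample → step (+ transition noise).
The recorded series are the *true* continuous states and the chosen
actions, exactly the content of a human trial file. All randomness flows
from one integer seed through a seed sequence, so every trial is
bit-reproducible.

## Study scale

The full-scale planning grid of the study design is 1000×1000 bins. The
shipped configuration plans on a 64×64 grid over [0, 2π) × [−10, 10]
(kept for the simulation sweep of 26 levels × 8 lengths × 7026 steps,
twice). Besides tractability, the coarse grid serves a modelling role:
its larger bilinear-interpolation diffusion makes the planner hedge
toward the interior of the balanced region, which is what keeps the
deployed policy stable when its observations are corrupted — the same
regularisation-by-stochasticity effect that motivates modelling
transitions as noisy in the first place. On fine grids the
deterministic-model optimum rides the edge of the reward region with
zero margin and collapses under observation noise; grids much coarser
than ~60 bins cannot represent the balancing band at all. The 64×64
choice sits in the middle of the plateau where both arms of the study
behave, and was fixed once for all reported numbers.

## Numerical and degenerate-input choices

* Angle bins are half-open on a uniform [0, 2π) grid; a state exactly on
  a bin edge may fall in either adjacent bin at float precision.
* Speeds outside the binning range are clamped to the edge bins, both in
  the estimators and in the observation channel.
* Episode statistics define a key-press episode as a maximal run of
  identical non-"none" actions; an episode is "inside" the balancing
  region if its start sample is (majority-of-samples classification is
  available behind a flag). Distance travelled uses unwrapped angle
  increments, so a full revolution counts 2π.
* Correlations: Spearman with average ranks for ties, Pearson on raw
  values, two-sided p-values, no multiple-testing correction; groups
  need ≥ 3 rows and a non-constant column (otherwise the coefficient is
  reported as NaN).
* Trial files use the deposited dialect (action codes 0/1/2 for
  none/clockwise/anti-clockwise, angle 0 = upright); the reader
  normalises to the internal downward-zero convention via an explicit
  convention flag, defaulting to upright-zero for `FRI_*` files.

## What the generator does and does not emulate

The controller family reproduces the study conditions — trial length,
sample interval, the 8 lengths, three-valued actions, and state
variability induced by skill and sensor noise. It does not emulate human
reaction latency, action-hold durations, learning within or across
trials, fatigue, or any per-length adaptation of noise levels. Passing
tests on synthetic trials therefore validate the *pipeline* (dynamics,
scoring, estimation, correlation) and the *mechanistic claim* that
observation noise converts skilled deterministic control into the
high-action-entropy / low-state-entropy signature; they do not by
themselves certify the human findings, which require the deposited
trial data (placed under `data/human/`, the same pipeline runs on it).

## Known limitations

* The absolute entropy values depend on the binning and the decimation
  rate; only comparisons under the fixed settings are meaningful.
* The deployed optimal policy is optimal for the discretised, diffused
  model, not for the continuous plant; its closed-loop utility under
  observation noise is metastable (rare falls dominate the variance
  across seeds).
* The correlation magnitudes of the noisy-controller arm vary by ±0.01–
  0.02 across seeds at this scale.
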