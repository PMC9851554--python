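# Controller-study configuration for the `pendulum-entropy simulate` CLI.
# All fields are optional; missing ones fall back to the study defaults.

lengths: [0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9]   # pendulum lengths, m
n_levels: 26        # epsilon-greedy skill levels (eps_n = n / 26)
n_steps: 7026       # samples per trial (2 minutes at 0.017 s)
gamma: 0.999        # value-iteration discount

pendulum:
  length: 0.5       # overridden per trial by `lengths`
  gravity: 1.0      # m s^-2
  damping: 5.0e-6   # per-step speed damping
  control_accel: 0.27   # key acceleration magnitude, m s^-2
  dt: 0.017         # sample interval, s

grid:               # MDP planning grid over [0, 2*pi) x [speed_lo, speed_hi]
  angle_bins: 64
  speed_bins: 64
  speed_lo: -10.0
  speed_hi: 10.0

binning:            # analysis binning for the entropy estimators
  angle_bins: 1000
  speed_bins: 200
  speed_lo: -10.0
  speed_hi: 10.0

noise:              # zero-mean scaled-binomial disturbances
  sigma_angle_o: 0.1    # observation noise on the angle, rad
  sigma_speed_o: 0.2    # observation noise on the speed, rad/s
  sigma_angle_t: 0.0    # transition noise on the angle, rad
  sigma_speed_t: 0.0    # transition noise on the speed, rad/s
  binomial_trials: 40

model_transition_noise: true   # include transition noise in the planning model
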