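# Package-wide defaults: every prior mean/variance and numeric knob used by
# the modelling chain lives here, in one place. All inference operates on
# log-deviations from the prior means below.

neural_mass:
  # Physical prior means. Gains are unit-DC-kernel couplings (a.u.); time
  # constants in ms. h/t/noise log-scalings of 0 reproduce these exactly.
  gain_means: [0.8, 0.6, 1.0, 1.0, 0.3]   # H1..H5 (H1-3 excitatory, H4-5 inhibitory)
  t_e_ms: 5.0
  t_i_ms: 24.0
  noise_amp: 0.02         # input-noise amplitude (power = amp^2 / f^exp)
  noise_exp: 1.0          # pink-noise spectral exponent prior mean
  noise_f_floor_hz: 0.05  # low-frequency cap of the 1/f input spectrum
  noise_input_p: 0.3      # noise weight into the projection population's
                          # inhibitory compartment (same stream as E input)
  ext_gain_mean: 0.03     # extrinsic (between-source) coupling prior mean
  sigmoid: tanh           # firing-rate nonlinearity (slope 1 at the origin)
  dt_s: 0.0005            # default integrator step
  blowup_abs: 1.0e+6

observation_model:
  t_up_ms: 250.0
  tau_decay_ms: 1000.0
  dt_ms: 1.0
  length_ms: 5500.0
  antialias_frac: 0.9     # low-pass cutoff as fraction of output Nyquist

spectral_features:
  window_length_s: 60.0
  window_step_s: 10.0
  dcm_window_length_s: 60.0
  dcm_window_step_s: 50.0
  mar_order: 8
  f_min_hz: 0.25
  f_max_hz: 10.0
  f_step_hz: 0.25
  corr_band_hz: [0.0, 10.0]

inversion:
  prior_var_intrinsic: 0.0625   # 1/16 on H1-5, T_E, T_I log-scalings
  prior_var_extrinsic: 0.125    # 1/8 on extrinsic log-gains
  prior_var_noise: 0.25         # on noise_amp / noise_exp log-scalings
  pinned_var: 1.0e-8            # "switched off" parameters for BMR
  log_precision_prior_mean: 4.0
  log_precision_prior_var: 16.0
  tol_df: 0.01
  max_iterations: 128
  fit_eigenmodes: false

peb:
  beta_prior_var: 0.0625
  log_q_prior_mean: -4.0        # random (between-window) effect log-variance
  log_q_prior_var: 9.0
  pk_tau2_s: 10800.0            # decay constant of the monophasic PK bump
  pk_peak_s: 1800.0             # bump peaks 30 min after onset
  n_dct: 3

forward_mapping:
  delta_band_hz: [1.0, 4.0]
  gamma_band_hz: [30.0, 80.0]
  map_f_min_hz: 1.0
  map_f_max_hz: 100.0
  map_f_step_hz: 1.0
  grid_half_width_sd: 3.0
  grid_points: 41

synthetic_data:
  n_fish: 3
  duration_s: 9000.0
  fs_hz: 20.0
  lfp_fs_hz: 1000.0
  ptz_onset_s: 1800.0
  segment_s: 50.0
  blend_s: 1.0
  measurement_snr: 10.0

pipeline:
  # The default pipeline design is a miniature (one fish, 10 minutes) so a
  # full run finishes on a laptop; override for paper-scale experiments.
  out_dir: runs/latest
  seed: 0
  n_fish: 1
  duration_s: 600.0
  ptz_onset_s: 120.0
  baseline_s: 100.0
  invert_channels: null     # optional channel-name subset for inversion stages
  map_region: Tect_L
  model_observation_kernel: true
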