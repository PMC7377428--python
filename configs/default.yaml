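# Default pipeline configuration for `lbarace run-all --config`.
# Any key may be omitted; values below are the shipped defaults.

seed: 1
n_subjects: 44
out_dir: results
make_figure: true

# simulation counts for model-based statistics
n_sim_per_subject: 10000   # quantile-probability tables
ks_sim_multiplier: 100     # model RT sample size, x subject trial count

population:
  # stimulus drift means: v = base + risk_benefit * [low risk]
  #                         + ev_benefit * [high EV] + stimulus noise
  drift_base_mean: 2.0
  drift_base_sd: 0.4
  risk_benefit_mean: 0.9
  risk_benefit_sd: 0.35
  ev_benefit_mean: 0.5
  ev_benefit_sd: 0.30
  drift_stim_noise_sd: 0.1
  # couples risk preference to utility curvature (concave -> risk averse)
  concavity_risk_coupling: 1.5
  # accumulator geometry and timing
  start_max_mean: 0.8
  start_max_sd: 0.15
  threshold_gap_mean: 0.8    # threshold = start_max + gap
  threshold_gap_sd: 0.15
  nondecision_mean: 0.30     # seconds
  nondecision_sd: 0.05
  drift_sd: 1.0              # fixed scale parameter s
  # satisfaction process
  utility_exponent_mean: 0.7
  utility_exponent_sd: 0.15
  cf_weight_mean: 0.3
  cf_weight_sd: 0.15
  rating_noise_sd: 8.0
  # trait anxiety (independent of all choice parameters)
  stai_mean: 40.0
  stai_sd: 10.0

fitting:
  n_restarts: 10
  max_iter: 1500
  xatol: 1.0e-4
  fatol: 1.0e-6
  drift_sd: 1.0    # fixed, not estimated
  jitter_sd: 0.2
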