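# Strain x hexose presets for the Mig1 localization generator.
#
# Magnitudes (initial amplitude A, pulse rate lambda, plateau L) are free
# parameters chosen to reproduce the qualitative response matrix reported for
# these strains: which conditions show the initial nuclear-accumulation peak,
# which show adapted-phase nucleocytoplasmic shuttling, and which derepress
# the SUC2-promoter reporter.  Absolute localization-index values for any
# condition were never published, so these numbers are declared arbitrary.
#
# Units: times min; rates pulses/hour (pulse_rate) or AU/min (reporter rates);
# localization index dimensionless; expression marker AU.

defaults:
  basal_level: 0.05
  peak_time: 30.0
  decay_tau: 60.0
  pulse_height_mean: 0.4
  pulse_height_sd: 0.12
  pulse_width: 10.0
  pulse_start: 240.0
  noise_sd: 0.05
  jitter_cv: 0.3
  responder_fraction: 1.0
  death_fraction: 0.0
  death_expr_threshold: null
  dose_response_k: null
  expression_marker_median: 100.0
  expression_marker_sigma: 0.15
  reporter:
    repressed_rate: 0.575        # leaky production, steady state 25 AU
    derepressed_rate: 0.575      # overridden per condition
    maturation_delay: 30.0       # Citrine-class chromophore maturation
    degradation_rate: 0.023      # destabilized reporter, ~30 min half-life
    derepression_onset: null     # null = never derepressed
  reporter_noise_sd: 2.0

# Per condition: A = initial_amplitude, rate = pulse_rate (per hour),
# L = plateau_level.  reporter.onset in minutes; reporter.fold multiplies the
# repressed base rate.
conditions:
  wt:
    glucose:  {A: 1.5, rate: 2.0, L: 0.35}
    fructose: {A: 1.4, rate: 2.0, L: 0.30}
    mannose:  {A: 1.5, rate: 2.0, L: 0.35, reporter: {onset: 240.0, fold: 1.5}}
  "hxk1Δ":
    glucose:  {A: 1.5, rate: 2.0, L: 0.35}
    fructose: {A: 1.4, rate: 2.0, L: 0.30}
    mannose:  {A: 1.5, rate: 2.0, L: 0.35, reporter: {onset: 240.0, fold: 2.0}}
  "hxk2Δ":
    glucose:  {A: 1.8, rate: 0.0, L: 0.05, reporter: {onset: 120.0, fold: 8.0}}
    fructose: {A: 1.5, rate: 1.5, L: 0.25, reporter: {onset: 120.0, fold: 1.5}}
    mannose:  {A: 1.6, rate: 0.0, L: 0.05, reporter: {onset: 120.0, fold: 4.0}}
  "hxk1Δhxk2Δ":
    glucose:  {A: 0.6, rate: 0.0, L: 0.05, decay_tau: 30.0,
               reporter: {onset: 30.0, fold: 7.5}}
    fructose: {A: 0.0, rate: 0.0, L: 0.05, reporter: {onset: 120.0, fold: 1.5}}
    mannose:  {A: 0.6, rate: 0.0, L: 0.05, decay_tau: 30.0,
               reporter: {onset: 60.0, fold: 3.0}}
  "+HXK1":
    glucose:  {A: 1.6, rate: 2.0, L: 0.35, expr_median: 1100.0,
               expr_sigma: 0.45, dose_k: 600.0}
    fructose: {A: 1.6, rate: 2.0, L: 0.35, expr_median: 1100.0,
               expr_sigma: 0.45, dose_k: 600.0}
    mannose:  {A: 1.6, rate: 2.0, L: 0.35, expr_median: 1100.0,
               expr_sigma: 0.45, dose_k: 600.0, death_threshold: 1500.0,
               reporter: {onset: 240.0, fold: 1.5}}
  "+HXK2":
    glucose:  {A: 1.8, rate: 2.2, L: 0.40, expr_median: 800.0,
               expr_sigma: 0.45, dose_k: 600.0}
    fructose: {A: 1.8, rate: 2.2, L: 0.40, expr_median: 800.0,
               expr_sigma: 0.45, dose_k: 600.0}
    mannose:  {A: 1.8, rate: 2.2, L: 0.40, expr_median: 800.0,
               expr_sigma: 0.45, dose_k: 600.0, death_threshold: 1000.0,
               reporter: {onset: 240.0, fold: 1.5}}
  "+GLK1":
    glucose:  {A: 1.2, rate: 0.0, L: 0.05, expr_median: 900.0,
               expr_sigma: 0.45, reporter: {onset: 60.0, fold: 8.0}}
    fructose: {A: 0.0, rate: 0.0, L: 0.05, expr_median: 900.0,
               expr_sigma: 0.45, reporter: {onset: 120.0, fold: 1.5}}
    mannose:  {A: 1.2, rate: 0.0, L: 0.05, expr_median: 900.0,
               expr_sigma: 0.45, reporter: {onset: 120.0, fold: 4.0}}
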