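# Status-quo (current healthcare) parameterization.
#
# Values printed in the source literature are entered directly.  Two values
# are calibration outputs of depsim.population_mc.calibrate (fixed seeds,
# coordinate search): course.incidence_scale targets a lifetime incidence of
# 11.4% and course.remission_decay.rate targets a 54% recurrence fraction
# among affected individuals.  services.treatment_effect is back-calculated
# from the printed worked example (12 treated months -> 71.3% cumulative
# remission from a 6.098% monthly base).  services.aftercare_reach has no
# printed value and is an implementer choice (see docs/methods.md).
course:
  yearly_incidence_overall: 0.0114
  incidence_scale: 0.16
  incidence_profile:
    # relative multipliers per age band (years); shape follows German
    # claims-data incidence of diagnosed depression, which rises through
    # midlife; the absolute level is set by incidence_scale (calibrated)
    age_bands: [0, 15, 25, 35, 45, 55, 65, 75]
    multipliers: [0.1, 0.7, 0.9, 1.1, 1.3, 1.3, 1.0, 0.6]
    female_scale: 1.0
    male_scale: 1.0
  remission_milestones: [0.23, 0.32, 0.53]
  remission_monthly_base: 0.06098
  remission_mode: flat
  recurrence_monthly_base: 0.0236
  episode_risk_multiplier: 1.16
  remission_decay:
    form: exponential
    rate: 0.0284
  max_hazard_cap: 1.0
services:
  prevention_reach: 0.05
  prevention_effect: 0.21
  prevention_applies_to_recurrence: false
  treatment_reach: 0.33
  treatment_effect: 0.62
  aftercare_reach: 0.25
  aftercare_effect: 0.36
  waiting_mean: 5.0
  waiting_sd: 1.0
  treatment_max_duration: 24
  aftercare_max_duration: 12
  retreatment_lockout: false
  # established care: ever-treated relapsers keep the monthly help-seeking
  # decision but skip the waiting queue
  retreatment: no_wait
demography:
  life_table: default
  sex_ratio_at_entry: 0.5
  excess_mortality_rr:
    female: 1.6
    male: 1.8
  max_age_months: 1320
simulation:
  n_runs: 1000
  n_lives_per_run: 10000
  base_seed: 20240402
  ci_level: 0.95
  common_random_numbers: true
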