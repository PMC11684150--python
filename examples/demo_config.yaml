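# Demo pipeline configuration: the analysis shape at reduced imputation and
# simulation sizes so `cpfextrap all --config examples/demo_config.yaml`
# completes in a few minutes on one CPU.
cohort:
  n_trial: 212
  n_rwe: 386
  n_trial_unassessed: 12
  n_rwe_unassessed: 73
  trial_dvs_retained: 101
  n_followup: 89
  lead_in_weeks: 4.0
  seed: 2024
m_imputations: 3
families: [weibull, gompertz, gengamma, loglogistic, lognormal]
location_covariates: [age_c, male, cd_duration_c, luminal_active, prior_biologic]
shape_covariates: []
lead_in_weeks: 4.0
horizon_months: 48
engine: microsim
n_sim: 20000
report_months: [0, 8, 24, 48]
extrapolation_family: gompertz
seed: 2024
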