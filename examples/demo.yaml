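# Demo pipeline configuration: a 30+30 toddler cohort with the default
# NT-like and autistic-like agent profiles, compared with age as covariate.
seed: 1
output_dir: popkin_demo
cohort:
  groups:
    NT: {base: nt, n: 30}
    autistic: {base: case, n: 30}
  clinical_score_model:
    fine_motor_t: [8.0, 6.0]
    elc: [6.0, 8.0]
  iq_model:
    NT: [100.0, 15.0]
    autistic: [90.0, 18.0]
covariates: [age_months]
comparisons:
  - [NT, autistic]
correlation_targets: [fine_motor_t]
classifier:
  max_features: 3
  grid: small
alpha: 0.05
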