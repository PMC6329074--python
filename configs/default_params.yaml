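# Default generative parameters: plausible stand-in values for an
# infant-cohort structure (all overridable; the two smoking effects
# beta_smoking_ex/beta_smoking_cur are the true estimands).
n_subjects: 1000
smoking_wave0_coefs:
- - -1.6
  - -0.02
  - -0.4
  - -0.2
- - -0.2
  - -0.03
  - -0.7
  - -0.35
never_transition_coefs:
- - -4.2
  - -0.01
  - -0.3
  - 0.5
  - -0.2
- - -3.2
  - -0.02
  - -0.4
  - 0.6
  - -0.3
ever_transition_coefs:
- -1.7
- -0.005
- -0.25
- 0.4
- 3.5
- -0.2
beta_intercept: 0.3
beta_smoking_ex: 0.1
beta_smoking_cur: 0.15
beta_scage: 0.002
beta_breastfed: -0.1
beta_m_age: -0.005
beta_m_education: -0.1
beta_birthweight: 0.2
beta_sex: 0.05
beta_ses: -0.05
random_intercept_sd: 0.8
residual_sd: 0.6
covariates:
  m_age_mean: 31.0
  m_age_sd: 5.0
  m_education_prev: 0.6
  breastfed_prev: 0.85
  sex_prev: 0.51
  birthweight_mean: 3.4
  birthweight_sd: 0.55
  ses_mean: 0.0
  ses_sd: 1.0
  scage_means:
  - 9.0
  - 33.0
  - 57.0
  - 81.0
  - 105.0
  - 129.0
  scage_sd: 1.0
  dep_intercept0: -1.75
  dep_intercept: -2.2
  dep_b_ses: -0.3
  dep_b_age: -0.02
  dep_b_prev: 2.0
seed: 0
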