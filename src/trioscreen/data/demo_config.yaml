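# Bundled demonstration run: a synthetic claims population with one
# strongly planted adverse triplet (drug00, drug01, drug02).  The planted
# coefficients give a highest-dose (2,2,2) log odds ratio of
# 2*(3*0.4) + 4*(3*0.05) + 8*0.04 = 3.32, so the triplet should surface
# as a signal in essentially every seeded run.
seed: 0
window_days: 30
outcome:
  ade_name: demo_ade
  ade_codes: [ADE]
  risk_factor_map:
    RF0: factor_0
    RF1: factor_1
simulation:
  n_persons: 12000
  n_drugs: 8
  drug_exposure_probs: [0.45, 0.45, 0.45, 0.3, 0.3, 0.3, 0.3, 0.3]
  ads_logmean: 3.0
  ads_logsd: 0.6
  planted_effects:
    - triplet: [0, 1, 2]
      beta: [0.4, 0.4, 0.4, 0.05, 0.05, 0.05, 0.04]
  nuisance_main_effects: [0.0, 0.0, 0.0, 0.1, 0.1, 0.1, 0.1, 0.1]
  risk_factor_prevalences: [0.3, 0.2]
  outcome_prevalence: 0.12
  stratum_sd: 0.5
  seed: 0
policy:
  min_case_count: 40
  top_k: 8
  fdr_level: 0.05
  or_min: 1.3
  required_drug_set: ["drug00|mg"]
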