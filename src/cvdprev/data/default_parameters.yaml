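# Default parameter set for the Myanmar CVD screening/prevention Markov model.
# All probabilities are annual decimals unless noted; costs are US$ (2015-ish
# price year); utilities are per-year weights on [0, 1].
schema_version: 1
percent: false

# Annual probability of moving from the general (<10% 10-year risk) population
# into each WHO total-CVD-risk category, by sex and age band.
risk_incidence:
  M:
    "45-54": {R10: 0.0025, R20: 0.0008, R30: 0.0006, R40: 0.0007}
    "55-64": {R10: 0.0112, R20: 0.0057, R30: 0.0035, R40: 0.0048}
    "65+":   {R10: 0.0181, R20: 0.0001, R30: 0.0049, R40: 0.0037}
  F:
    "45-54": {R10: 0.0019, R20: 0.0012, R30: 0.0001, R40: 0.0005}
    "55-64": {R10: 0.0152, R20: 0.0049, R30: 0.0011, R40: 0.0047}
    "65+":   {R10: 0.0034, R20: 0.0089, R30: 0.0055, R40: 0.0033}

# Annual probability of a first acute CVD event from each risk category
# (10-year band-midpoint risks converted to annual probabilities).
acvd_tp:
  R10: 0.0161
  R20: 0.0284
  R30: 0.0422
  R40: 0.0580

# Annual probability of a recurrent acute event from established (chronic) CVD.
recurrent_acvd_tp:
  "45-54": 0.0661
  "55-64": 0.0684
  "65+":   0.1088

# All-cause non-CVD background mortality, annual, by sex and 5-year band.
background_mortality:
  M:
    "45-49": 0.0072
    "50-54": 0.0113
    "55-59": 0.0169
    "60-64": 0.0261
    "65-69": 0.0383
    "70-74": 0.0582
    "75-79": 0.0861
    "80-84": 0.1313
    "85+":   0.2173
  F:
    "45-49": 0.0040
    "50-54": 0.0060
    "55-59": 0.0087
    "60-64": 0.0139
    "65-69": 0.0221
    "70-74": 0.0617
    "75-79": 0.0617
    "80-84": 0.1021
    "85+":   0.1830

# Per-event probability of dying from the acute event, by cause, sex and
# 10-year band.
cfr_stroke:
  M:
    "40-49": 0.2630
    "50-59": 0.2154
    "60-69": 0.2161
    "70-79": 0.2766
    "80+":   0.3811
  F:
    "40-49": 0.2322
    "50-59": 0.2337
    "60-69": 0.2440
    "70-79": 0.2940
    "80+":   0.3756
cfr_ihd:
  M:
    "40-49": 0.6084
    "50-59": 0.6128
    "60-69": 0.6377
    "70-79": 0.6696
    "80+":   0.7107
  F:
    "40-49": 0.7094
    "50-59": 0.7130
    "60-69": 0.7307
    "70-79": 0.7518
    "80+":   0.7850

# Share of acute events that are strokes (vs acute coronary syndrome); used to
# blend the two case-fatality tables into a composite acute-CVD CFR.
stroke_weight: 0.30

costs:
  screening: 9.13          # per person-year, general population and 10-19.9% risk
  pp_mid: 38.62            # per person-year, primary prevention, 20-29.9% risk
  pp_high: 41.11           # per person-year, primary prevention, >=30% risk
  sp: 41.28                # per person-year, secondary prevention (chronic CVD)
  acvd_event: 449.40       # per incident acute event, all scenarios
  productivity_loss: 4360.00  # per incident acute event, societal perspective only

utilities:
  general: 0.93
  R10: 0.92
  R20: 0.91
  R30: 0.87
  R40: 0.85
  acvd: 0.47
  chronic: 0.64
  cvd_death: 0.0
  noncvd_death: 0.0

# Treated-to-untreated risk multipliers (product of per-drug relative risks).
effects:
  rr_pp_mid: 0.47   # ACEI + CCB + statin (20-29.9% risk)
  rr_pp_high: 0.36  # ACEI + CCB + statin + aspirin (>=30% risk)
  rr_sp: 0.29       # ACEI + beta-blocker + statin + aspirin (chronic CVD)

discount_rate: 0.03

wtp_thresholds:
  gdp1: 1400.2
  gdp3: 4200.6

# Male share of the modelled population, used to aggregate sex-specific runs.
male_fraction: 0.48

# Relative standard errors and distribution families for the PSA.
psa_spec:
  cost_rel_se: 1.0      # gamma
  utility_rel_se: 0.1   # beta
  tp_rel_se: 0.1        # beta
  effect_rel_se: 0.1    # lognormal

config:
  effect_is_multiplier: true     # treated TP = TP * effect (else TP * (1 - effect))
  discount_first_cycle: false    # first cycle weight 1, i.e. d(t) = (1+r)^-t with t0 = 0
  mortality_in_acvd: true        # background mortality applies to acute-event survivors
  productivity_loss_on_death_years: false
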