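# Default synthetic-cohort conditions.
#
# Marginal prevalences follow the headline rates of a large volunteer
# mental-health survey of middle-aged/older UK adults (lifetime depression
# 24%, current hazardous/harmful alcohol use 21%, lifetime GAD 7%, current
# PTSD 6%, unusual experiences 5%, self-harm 4%, hypomania/mania 2%,
# self-reported addiction 6%).  Pairwise tilts (log-odds-ratio scale) and
# covariate offsets encode the *direction* of the reported comorbidity and
# risk-factor patterns; magnitudes are this generator's own defaults.
n: 1000
seed: 0
marginal_prevalence:
  depression: 0.24
  alcohol_hazardous: 0.21
  gad: 0.07
  ptsd_current: 0.06
  unusual_experiences: 0.05
  self_harm: 0.04
  mania: 0.02
  addiction: 0.06
recurrent_share: 0.6
latent_association:
  # [syndrome, syndrome, pairwise log-odds tilt]
  - [depression, gad, 1.7]
  - [depression, mania, 1.5]
  - [depression, ptsd_current, 1.5]
  - [depression, self_harm, 1.8]
  - [depression, unusual_experiences, 0.8]
  - [depression, addiction, 0.8]
  - [depression, alcohol_hazardous, 0.15]
  - [gad, ptsd_current, 1.2]
  - [gad, self_harm, 0.8]
  - [mania, unusual_experiences, 1.0]
  - [ptsd_current, unusual_experiences, 1.0]
  - [ptsd_current, self_harm, 1.0]
  - [self_harm, unusual_experiences, 1.0]
  - [addiction, alcohol_hazardous, 1.2]
covariates:
  female_rate: 0.57
  over65_rate: 0.53
  age_range: [45, 82]
  degree_rate: 0.45
  townsend_probs: [0.25, 0.22, 0.20, 0.18, 0.15]   # volunteer cohorts skew less deprived
  renter_rate: 0.11
  longstanding_illness_rate: 0.28
  neuroticism_binom_p: 0.33
  neuroticism_high_cut: 7
  childhood_adversity_rate: 0.20
  adult_adversity_rate: 0.25
  trauma_exposure_rate: 0.30
  loneliness_rate: 0.18
syndrome_offsets:
  # log-odds shifts of the latent fields per binary covariate feature;
  # directions: depression/anxiety commoner in women, alcohol in men, all
  # syndromes rarer over 65, adversity and neuroticism raise risk.
  male:
    depression: -0.5
    gad: -0.4
    alcohol_hazardous: 0.9
    addiction: 0.4
  over65:
    depression: -0.5
    gad: -0.5
    mania: -0.5
    ptsd_current: -0.5
    unusual_experiences: -0.3
    self_harm: -0.5
    addiction: -0.4
    alcohol_hazardous: -0.1
  childhood_adversity:
    depression: 0.8
    gad: 0.6
    ptsd_current: 1.0
    self_harm: 0.8
    addiction: 0.6
    mania: 0.4
    unusual_experiences: 0.5
  adult_adversity:
    depression: 0.6
    gad: 0.5
    ptsd_current: 0.6
  trauma_exposure:
    ptsd_current: 1.5
  loneliness:
    depression: 0.7
    gad: 0.5
  high_neuroticism:
    depression: 1.0
    gad: 1.0
    mania: 0.3
    self_harm: 0.5
emission_fidelity:
  default: {sensitivity: 0.95, specificity: 0.99}
decline_rate: 0.01
partial_rate: 0.03
screen_engage_given_negative:
  # probability a true-negative engages the section's screen (yielding an
  # engaged-but-unmet pattern, e.g. subthreshold depressive symptoms) rather
  # than screening out; most adults drink, hence the high alcohol value.
  depression: 0.15
  mania: 0.08
  gad: 0.14
  alcohol_hazardous: 0.93
diagnosis_model:
  background:
    Depression: 0.03
    Anxiety or nerves: 0.04
    Mania or bipolar disorder: 0.002
    Schizophrenia: 0.001
    Other psychosis: 0.002
    Anorexia or other eating disorder: 0.012
    Other: 0.05
  given_syndrome:
    depression: {Depression: 0.65}
    gad: {Anxiety or nerves: 0.55}
    mania: {Mania or bipolar disorder: 0.35}
    unusual_experiences: {Schizophrenia: 0.10, Other psychosis: 0.08}
behaviour_model:
  smoked_base: 0.40
  smoked_any_syndrome_extra: 0.15
  cannabis_base: 0.18
  cannabis_any_syndrome_extra: 0.12
  physical_activity_rate: 0.60
  live_alone_base: 0.17
  live_alone_lonely_extra: 0.20
  group_activity_base: 0.55
  group_activity_lonely_penalty: 0.20
  contact_probs: [0.30, 0.40, 0.15, 0.10, 0.05]
  contact_probs_lonely: [0.15, 0.30, 0.20, 0.20, 0.15]
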