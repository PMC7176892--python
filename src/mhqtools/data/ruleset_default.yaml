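# Default operational case definitions ("rules_default").
#
# Thresholds, required counts, durations and item bindings for the likely-
# syndrome classifiers.  DSM-IV operationalisations of the CIDI-SF lifetime
# depression and GAD modules, a one-week hypomania/mania duration rule, the
# standard AUDIT cut-off (>=8) and a 6-item PCL short-form sum with a
# configurable cut-off (default 14, a published short-form convention).
# Marked provisional: thresholds live here so the deployed instrument's exact
# criteria can be transcribed without code changes.
version: rules_default-1.0
provisional: true
depression:
  screen_mood_item: DEP_SCR_MOOD
  screen_anhedonia_item: DEP_SCR_ANH
  core_most_item: DEP_CORE_MOST
  anhedonia_symptom_item: DEP_SYM_ANH
  other_symptom_items: [DEP_SYM_TIRED, DEP_SYM_APPETITE, DEP_SYM_SLEEP,
                        DEP_SYM_CONC, DEP_SYM_WORTH, DEP_SYM_DEATH]
  duration_item: DEP_DUR_WEEKS
  impairment_item: DEP_IMPAIR
  episodes_item: DEP_EPISODES
  min_symptoms: 5
  min_duration_weeks: 2
  require_impairment: true
  recurrent_min_episodes: 2
mania:
  screen_elated_item: MAN_SCR_ELATED
  screen_irritable_item: MAN_SCR_IRRIT
  symptom_items: [MAN_SYM_ACTIVE, MAN_SYM_TALKATIVE, MAN_SYM_SLEEP,
                  MAN_SYM_CONFIDENT, MAN_SYM_THOUGHTS, MAN_SYM_DISTRACT]
  duration_item: MAN_DUR_DAYS
  min_duration_days: 7
  min_symptoms_elated: 3
  min_symptoms_irritable_only: 4
gad:
  screen_item: GAD_SCR
  duration_item: GAD_DUR_MONTHS
  excessive_item: GAD_EXCESS
  control_item: GAD_CONTROL
  symptom_items: [GAD_SYM_RESTLESS, GAD_SYM_TIRED, GAD_SYM_CONC,
                  GAD_SYM_IRRITABLE, GAD_SYM_TENSION, GAD_SYM_SLEEP]
  min_duration_months: 6
  min_symptoms: 3
alcohol:
  items: [AUDIT_1, AUDIT_2, AUDIT_3, AUDIT_4, AUDIT_5,
          AUDIT_6, AUDIT_7, AUDIT_8, AUDIT_9, AUDIT_10]
  cutoff: 8
ptsd:
  items: [PCL_1, PCL_2, PCL_3, PCL_4, PCL_5, PCL_6]
  cutoff: 14
unusual_experiences:
  items: [PSY_VISION, PSY_VOICE, PSY_CONSPIRACY, PSY_SIGNS]
self_harm:
  item: SH_EVER
addiction:
  item: ADD_EVER
diagnoses:
  item: DX_TICKS
  none_code: 0
childhood_trauma:
  # per-item frequency threshold: endorsement at/above this code counts
  item_thresholds: {CTS_1: 2, CTS_2: 2, CTS_3: 2, CTS_4: 2, CTS_5: 2}
adult_adversity:
  items: [AA_NO_CONFIDE, AA_ABUSIVE, AA_MONEY]
trauma_triggers:
  items: [TRIG_COMBAT, TRIG_ACCIDENT, TRIG_ASSAULT,
          TRIG_SEXUAL, TRIG_ILLNESS, TRIG_DEATH]
loneliness:
  lonely_item: LONE_LONELY
  confide_item: AA_NO_CONFIDE
social_isolation:
  live_alone_item: LIVE_ALONE
  contact_item: CONTACT_FREQ
  infrequent_contact_min_code: 3
  group_item: GROUP_ACT
  min_components: 2
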