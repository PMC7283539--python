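# Rule configuration for the T2DM case decision tree and control screen.
#
# The case definition is a disjunction of paths over per-patient evidence;
# a patient is a case when the first listed path whose conditions all hold
# exists. Conditions refer to T2DMEvidence fields; boolean fields require
# equality, count fields take {ge: n}.
case_paths:
  - id: P1
    when: {has_t1dm_dx: false, has_t2dm_dx: true, has_t2dm_med: true}
  - id: P2
    when: {has_t1dm_dx: false, has_t2dm_dx: true, has_t2dm_med: false, has_abnormal_lab: true}
  - id: P3
    when: {has_t1dm_dx: false, has_t2dm_dx: false, has_t2dm_med: true, has_abnormal_lab: true}
  - id: P4
    when: {has_t1dm_dx: true, has_t2dm_dx: true, has_t1dm_med: true, has_t2dm_med: true,
           t2dm_med_precedes_t1dm_med: true}
  - id: P5
    when: {has_t1dm_dx: true, has_t2dm_dx: true, has_t1dm_med: true, has_t2dm_med: false,
           n_t2dm_dx_physician: {ge: 2}}

# standard diagnostic thresholds; config-overridable
lab_criteria:
  fasting_glucose_threshold: 126.0   # mg/dL
  random_glucose_threshold: 200.0    # mg/dL
  hba1c_threshold: 6.5               # percent

control:
  min_inperson_visits: 2
  min_glucose_measures: 1

# encounter events whose code marks an in-person physician visit
inperson_code: "INPERSON"
# entry modes counted as physician-asserted T2DM diagnoses
physician_entry_modes: ["physician", "nlp"]
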