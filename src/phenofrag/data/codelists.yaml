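# Default code lists for the RA and T2DM phenotyping algorithms.
#
# These are illustrative, configuration-level vocabularies: real deployments
# substitute institution-specific ICD / medication / lab dictionaries.
# Patterns are matched case-insensitively; "." is literal and a trailing "*"
# is a prefix wildcard ("714.*" matches "714.0" but not "7140").

ra_dx:
  - system: ICD9CM
    codes: ["714.0", "714.1", "714.2", "714.81"]
  - system: ICD10CM
    codes: ["M05.*", "M06.*"]

ra_exclusion:
  # juvenile idiopathic arthritis and related exclusions for RA controls
  - system: ICD9CM
    codes: ["714.3*"]
  - system: ICD10CM
    codes: ["M08.*"]

sle_dx:
  - system: ICD9CM
    codes: ["710.0"]
  - system: ICD10CM
    codes: ["M32.*"]

pa_dx:
  - system: ICD9CM
    codes: ["696.0"]
  - system: ICD10CM
    codes: ["L40.5*"]

rf_lab:
  - system: LAB
    codes: ["RF"]

t1dm_dx:
  - system: ICD9CM
    codes: ["250.01", "250.03"]
  - system: ICD10CM
    codes: ["E10.*"]

t2dm_dx:
  - system: ICD9CM
    codes: ["250.00", "250.02"]
  - system: ICD10CM
    codes: ["E11.*"]

t1dm_med:
  - system: MED
    codes: ["INSULIN*"]

t2dm_med:
  - system: MED
    codes: ["METFORMIN", "GLIPIZIDE", "GLYBURIDE", "SITAGLIPTIN"]

# any diabetes-related diagnosis disqualifies a T2DM control
dm_related_dx:
  - system: ICD9CM
    codes: ["250.*", "790.29", "648.8*"]
  - system: ICD10CM
    codes: ["E10.*", "E11.*", "R73.*", "O24.*"]

dm_supplies:
  - system: MED
    codes: ["TEST_STRIPS", "LANCETS", "GLUCOMETER", "INSULIN_SYRINGE"]

glucose_lab:
  - system: LAB
    codes: ["GLU_FASTING", "GLU_RANDOM"]

fasting_glucose_lab:
  - system: LAB
    codes: ["GLU_FASTING"]

random_glucose_lab:
  - system: LAB
    codes: ["GLU_RANDOM"]

hba1c_lab:
  - system: LAB
    codes: ["HBA1C"]
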