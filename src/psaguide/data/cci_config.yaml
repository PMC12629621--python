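# Charlson Comorbidity Index configuration: comorbidity weights (original
# 1/2/3/6 tiers), age-decade points, severity hierarchies, and the two
# screening gates (age limit and 10-year survival threshold).
#
# The table is data, not code, so an alternative weight set (e.g. an updated
# Charlson revision) can be substituted without touching the engine.
weights:
  myocardial_infarction: 1
  congestive_heart_failure: 1
  peripheral_vascular_disease: 1
  cerebrovascular_disease: 1
  dementia: 1
  chronic_pulmonary_disease: 1
  connective_tissue_disease: 1
  peptic_ulcer_disease: 1
  mild_liver_disease: 1
  diabetes_uncomplicated: 1
  hemiplegia: 2
  moderate_severe_renal_disease: 2
  diabetes_with_end_organ_damage: 2
  solid_tumor: 2
  leukemia: 2
  lymphoma: 2
  moderate_severe_liver_disease: 3
  metastatic_solid_tumor: 6
  aids: 6

# When both a mild and a severe form of the same organ system are coded,
# only the severe weight counts.
severity_hierarchy:
  - [diabetes_uncomplicated, diabetes_with_end_organ_damage]
  - [mild_liver_disease, moderate_severe_liver_disease]
  - [solid_tumor, metastatic_solid_tumor]

# Age-adjusted CCI convention: +1 point per decade from 50.
age_bands:
  - {min_age: 50, max_age: 59, points: 1}
  - {min_age: 60, max_age: 69, points: 2}
  - {min_age: 70, max_age: 79, points: 3}
  - {min_age: 80, max_age: 200, points: 4}

gate:
  enabled: true
  # "aged >72 years not permitted to proceed"
  age_limit: 72
  # "expected to live at least 10 years" read as P(10-year survival) >= 0.50
  survival_threshold: 0.50
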