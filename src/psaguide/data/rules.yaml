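# Versioned rule file for the deterministic EAU/AUA PSA-testing engine.
#
# This is a codified subset of the two guidelines restricted to the rule
# statements the pipeline's fixture corpus carries, plus documented
# extensions (marked below) needed to cover all five case categories.
# Updating a threshold or interval here requires no code change.
version: 1

shared:
  # PSA elevation threshold: the most commonly applied cutoff, >= 3.0 ng/mL.
  psa_elevated_threshold: 3.0
  # "Moderately elevated" upper bound: up to 10 ng/mL -> confirmatory repeat
  # after a few weeks; above -> refer.
  psa_moderate_upper: 10.0

eau:
  screening_age_min: 50
  # EXTENSION: upper routine band; eligible men above it (71-72, inside the
  # age gate) default to no routine testing with shared decision-making.
  screening_age_max: 70
  # 2-year follow-up interval for a normal PSA in an eligible man.
  routine_interval_months: [24, 24]
  # EXTENSION: risk-adapted earlier start ages (not anchored in the fixture
  # corpus rule statements; standard risk-adapted strategy).
  risk_adapted_start:
    family_history_prostate_ca: 45
    african_ancestry: 45
    brca_carrier: 40
  shared_decision_age: 50

aua:
  screening_age_min: 50
  screening_age_max: 69
  # Regular PSA screening every 2 to 4 years for people aged 50-69.
  routine_interval_months: [24, 48]
  risk_adapted_start:
    family_history_prostate_ca: 45
    african_ancestry: 45
    brca_carrier: 40
  shared_decision_age: 40

special_rules:
  # Active urinary tract infection with an elevated PSA: likely spurious ->
  # treat the infection, then repeat, instead of a confirmatory repeat now.
  uti_defer: true
  # Abnormal DRE warrants urology referral even with a normal PSA.
  abnormal_dre_refer: true
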