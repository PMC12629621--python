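---
source: AUA
section: Early detection of prostate cancer
---

[aua.routine_screening_band] When screening is being undertaken, clinicians
may offer regular PSA screening every 2 to 4 years for people aged 50 to 69
years. Shared decision-making, incorporating the person's values and
preferences, should precede any PSA-based screening decision.

[aua.below_screening_age] Routine PSA screening is not recommended for
average-risk people under 50 years of age; for people at increased risk —
including a family history of prostate cancer, Black ancestry, or germline
BRCA mutation — clinicians may begin the shared decision-making discussion
and offer screening from 40 to 45 years of age.

[aua.beyond_screening_band] For people aged 70 years and older, or with a
life expectancy of less than 10 years, routine PSA screening is not
recommended; screening decisions in this group should be individualised
through shared decision-making.

[aua.psa_confirmatory_repeat] For people with a newly elevated PSA, a
repeat PSA test should be obtained prior to further diagnostic evaluation,
as PSA values fluctuate and a single moderately elevated result may not be
reproducible.

[aua.psa_confirmed_elevated_refer] [aua.psa_markedly_elevated_refer] People
with a confirmed elevated or markedly elevated PSA should be evaluated
further and referred for urological assessment, with risk stratification
guiding the decision on additional testing and biopsy.

[aua.normal_psa_routine_interval] For people on a screening programme whose
PSA remains below the elevation threshold, continuing the regular screening
interval of 2 to 4 years is appropriate; the interval may be individualised
on the basis of the PSA level and the person's preference.

[special.uti_spurious_elevation_defer] PSA elevation in the setting of an
active urinary tract infection is frequently spurious; clinicians should
treat the infection and repeat the PSA after resolution rather than
proceeding with diagnostic evaluation on the basis of the infected value.

[special.abnormal_dre_refer] An abnormal digital rectal examination in a
person with a normal PSA remains an indication for urological referral, as
palpable abnormalities carry an independent risk of clinically significant
prostate cancer.
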