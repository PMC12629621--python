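---
source: EAU
section: Early detection of prostate cancer
---

[eau.offer_baseline_psa] Offer an individualised, risk-adapted strategy for
the early detection of prostate cancer to well-informed men with a good
performance status and a life expectancy of at least ten years. A baseline
serum PSA test should be offered to men from 50 years of age after a
discussion of the potential benefits and harms.

[eau.below_screening_age] Do not subject men to PSA testing without
counselling on the potential risks and benefits, and do not offer routine
early-detection PSA testing to men below the risk-adapted starting age;
early testing may be considered from 45 years of age in men with a family
history of prostate cancer or of African descent, and from 40 years of age
in BRCA2 mutation carriers.

[eau.psa_confirmatory_repeat] [eau.psa_markedly_elevated_refer] The most
commonly applied threshold for PSA is >= 3.0 ng/ml. In case of a moderately
elevated PSA (up to 10 ng/mL), a repeated test after a few weeks should be
considered, under standardised conditions in the same laboratory, to
confirm the increase before any further diagnostic work-up. A markedly
elevated PSA above 10 ng/mL warrants referral for urological assessment.

[eau.psa_confirmed_elevated_refer] Men with a confirmed elevated PSA should
be referred to urology for risk stratification and consideration of further
diagnostic evaluation; repeat population-level testing adds no information
once the elevation is confirmed.

[eau.normal_psa_routine_interval] For men in whom early detection is being
pursued and whose PSA is below the threshold, a risk-adapted strategy based
on the initial PSA level may be used; follow-up intervals of two years may
be considered for those initially at risk, with testing postponed for men
at low baseline risk.

[eau.beyond_screening_band] [gate.life_expectancy] Stop early diagnosis of
prostate cancer based on life expectancy and performance status: men who
have a life expectancy of under ten years are unlikely to benefit from PSA
testing, and routine testing beyond the age band of demonstrated benefit is
not recommended.

[special.uti_spurious_elevation_defer] PSA is organ-specific but not
cancer-specific: urinary tract infection and prostatitis can spuriously
elevate serum PSA. In men with an active urinary infection and an elevated
PSA, treat the infection first and repeat the PSA after resolution rather
than acting on the elevated value.

[special.abnormal_dre_refer] An abnormal digital rectal examination is an
indication for referral and further assessment in its own right, even when
the serum PSA is within the normal range, as a suspicious finding on
palpation is associated with clinically significant disease.
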