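"""Generate a gold-labelled synthetic cohort and grade the pipeline on it.

The generator reproduces the study's category mix (11/9/9/8/7 over five
categories, a 20/24 screening/follow-up split). Gold labels come from the
rule engine, so the mock-backend pipeline must score 100% — any deviation
would indicate a defect in retrieval, prompting, parsing or
reconciliation. A degraded arm simulates an imperfect clinician rater.
"""
from collections import Counter

from psaguide import (
    Arm,
    Category,
    CohortConfig,
    ErrorType,
    aggregate,
    degrade_ratings,
    generate_cohort,
    grade,
)
from psaguide.rag import MockGuidelineBackend, PipelineConfig, run_pipeline

cohort = generate_cohort(CohortConfig(seed=42))
print("category counts:", dict(Counter(g.category.value for _, g in cohort)))

config = PipelineConfig(backend=MockGuidelineBackend())
ratings = [grade(run_pipeline(case, config).dual, gold) for case, gold in cohort]
report = aggregate(ratings)
print(f"mock-pipeline accuracy: {report.accuracy(Arm.llm):.1f}%")

noisy = degrade_ratings(
    cohort,
    {Category.cat4_elevated_psa: {ErrorType.missed_long_interval: 0.5}},
    seed=1,
    arm=Arm.human_closed,
)
noisy_report = aggregate(noisy)
print(f"degraded arm accuracy: {noisy_report.accuracy(Arm.human_closed):.1f}% "
      f"(long-interval errors injected in the elevated-PSA category)")
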