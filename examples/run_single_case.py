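"""Run one outpatient vignette through the full decision-support pipeline.

Builds a 57-year-old with a mildly raised but sub-threshold PSA, runs the
Charlson gate, per-guideline retrieval and the deterministic mock backend,
and prints the reconciled recommendation with its audit trail.
"""
from psaguide import parse_case
from psaguide.rag import MockGuidelineBackend, PipelineConfig, run_pipeline

case = parse_case(
    {
        "case_id": "example-1",
        "age": 57,
        "comorbidities": ["diabetes_uncomplicated"],
        "psa_history": [
            {"value": 1.9, "months_ago": 26},
            {"value": 2.4, "months_ago": 0},
        ],
    }
)

result = run_pipeline(case, PipelineConfig(backend=MockGuidelineBackend()))

print(f"CCI score {result.cci.score} "
      f"(comorbidity {result.cci.comorbidity_points} + age {result.cci.age_points}); "
      f"estimated 10-year survival {result.cci.ten_year_survival:.3f}")
print(f"gate: {'eligible' if result.gate.eligible else result.gate.reasons}")
assert result.dual is not None
for source, rec in (("EAU", result.dual.eau), ("AUA", result.dual.aua)):
    print(f"{source}: {rec.action.value} interval={rec.interval_months} "
          f"rules={list(rec.rationale)}")
final = result.dual.final_actions[0]
print(f"final ({'concordant' if result.dual.concordant else 'discordant'}): "
      f"{final.action.value} interval={final.interval_months}")
# A normal PSA in an eligible 50-69-year-old yields a routine follow-up
# interval; the intersection of the 2-year (EAU) and 2-4-year (AUA)
# intervals is 24 months.
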