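"""Reproduce the published accuracy comparison from the shipped fixture.

Loads the reconstructed error-breakdown fixture (three arms x 220
ratings), aggregates it into the study-style report, and computes the
agreement and significance statistics.
"""
from psaguide import (
    Arm,
    RatingMatrix,
    aggregate,
    compare_accuracy,
    fleiss_kappa,
    load_table1_fixture,
)

ratings = load_table1_fixture()
report = aggregate(ratings)

for arm in Arm:
    print(f"{arm.value:13s} accuracy {report.accuracy(arm):.1f}%  "
          f"errors {report.count(arm, 'overall', 'total_errors')}/220")

llm = [r for r in ratings if r.arm is Arm.llm]
kappa = fleiss_kappa(RatingMatrix.from_ratings(llm))
print(f"LLM-arm Fleiss kappa (44 items x 5 raters): {kappa:.3f}")

for human_arm in (Arm.human_closed, Arm.human_open):
    human = [r for r in ratings if r.arm is human_arm]
    t = compare_accuracy(llm, human, "t")
    z = compare_accuracy(llm, human, "two_proportion")
    print(f"llm vs {human_arm.value}: t={t.statistic:.2f} (p={t.pvalue:.2e}), "
          f"z={z.statistic:.2f} (p={z.pvalue:.2e})")
# The accuracies are the published 95.5 / 62.3 / 74.1 percent; both tests
# put the LLM-vs-clinician differences far below p = .001.
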