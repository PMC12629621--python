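"""Grading taxonomy, aggregation, Fleiss kappa, bootstrap CI, comparisons."""
import itertools

import numpy as np
import pytest

from psaguide import (
    AcceptableAnswer,
    Action,
    Arm,
    Category,
    ErrorType,
    GoldLabel,
    RatingMatrix,
    Source,
    aggregate,
    compare_accuracy,
    fleiss_kappa,
    grade,
    kappa_ci,
)
from psaguide.engine import Recommendation, reconcile
from psaguide.errors import ConsistencyError, DegenerateAgreementError
from psaguide.evaluation import GradedRating, ratings_from_csv, ratings_to_csv


def _rec(source, action, interval=None):
    return Recommendation(
        source=source,
        action=action,
        interval_months=interval,
        rationale=() if action is Action.no_testing else ("rule",),
    )


def _dual(eau_action, aua_action, eau_interval=None, aua_interval=None):
    return reconcile(
        _rec(Source.EAU, eau_action, eau_interval),
        _rec(Source.AUA, aua_action, aua_interval),
    )


def _gold(eau_action, aua_action, eau_interval=None, aua_interval=None,
          category=Category.cat1_screen_recommended):
    return GoldLabel(
        case_id="g",
        acceptable=(
            AcceptableAnswer(source=Source.EAU, action=eau_action, interval_months=eau_interval),
            AcceptableAnswer(source=Source.AUA, action=aua_action, interval_months=aua_interval),
        ),
        category=category,
    )


class TestGrade:
    def test_no_test_when_screening_acceptable_is_failed_to_offer(self):
        gold = _gold(Action.offer_psa_now, Action.routine_interval, aua_interval=(24, 48))
        rating = grade(_dual(Action.no_testing, Action.no_testing), gold)
        assert not rating.correct
        assert rating.error is ErrorType.missed_failed_to_offer

    def test_interval_below_every_acceptable_is_short_interval(self):
        gold = _gold(
            Action.routine_interval, Action.routine_interval,
            eau_interval=(24, 48), aua_interval=(24, 48),
            category=Category.cat3_normal_followup,
        )
        dual = _dual(
            Action.routine_interval, Action.routine_interval,
            eau_interval=(6, 6), aua_interval=(6, 6),
        )
        assert grade(dual, gold).error is ErrorType.unnecessary_short_interval

    def test_interval_above_every_acceptable_is_long_interval(self):
        gold = _gold(
            Action.routine_interval, Action.routine_interval,
            eau_interval=(24, 24), aua_interval=(24, 48),
            category=Category.cat3_normal_followup,
        )
        dual = _dual(
            Action.routine_interval, Action.routine_interval,
            eau_interval=(96, 96), aua_interval=(96, 96),
        )
        assert grade(dual, gold).error is ErrorType.missed_long_interval

    def test_test_offered_when_none_acceptable_is_did_not_require(self):
        gold = _gold(Action.no_testing, Action.no_testing,
                     category=Category.cat2_screen_not_recommended)
        dual = _dual(
            Action.routine_interval, Action.routine_interval,
            eau_interval=(24, 24), aua_interval=(24, 24),
        )
        assert grade(dual, gold).error is ErrorType.unnecessary_did_not_require

    def test_concordance_with_either_guideline_is_correct(self):
        # matches the EAU answer but not the AUA answer -> correct
        gold = _gold(Action.no_testing, Action.routine_interval, aua_interval=(24, 48))
        dual = _dual(Action.no_testing, Action.no_testing)
        assert grade(dual, gold).correct

    def test_gate_refusal_graded_as_no_testing(self):
        gold = _gold(Action.no_testing, Action.no_testing,
                     category=Category.cat2_screen_not_recommended)
        assert grade(None, gold).correct
        gold2 = _gold(Action.offer_psa_now, Action.routine_interval, aua_interval=(24, 48))
        assert grade(None, gold2).error is ErrorType.missed_failed_to_offer

    def test_hallucinated_confirmatory_repeat_is_short_interval(self):
        gold = _gold(
            Action.routine_interval, Action.routine_interval,
            eau_interval=(24, 24), aua_interval=(24, 48),
            category=Category.cat3_normal_followup,
        )
        dual = _dual(Action.confirmatory_repeat_weeks, Action.confirmatory_repeat_weeks)
        rating = grade(dual, gold)
        assert not rating.correct
        assert rating.error is ErrorType.unnecessary_short_interval

    def test_taxonomy_exhaustive_over_action_pairs(self):
        """Every (response action, gold action) pair yields exactly one
        subtype when incorrect — no fall-through."""
        intervals = {Action.routine_interval: (24, 24)}
        for resp, acc in itertools.product(Action, Action):
            gold = _gold(acc, acc, eau_interval=intervals.get(acc),
                         aua_interval=intervals.get(acc))
            dual = _dual(resp, resp, eau_interval=intervals.get(resp),
                         aua_interval=intervals.get(resp))
            rating = grade(dual, gold)
            if resp == acc:
                assert rating.correct
            else:
                assert rating.error is not ErrorType.none


class TestAggregate:
    def test_table_overall_accuracies(self, table1):
        report = aggregate(table1)
        assert report.accuracy(Arm.llm) == pytest.approx(210 / 220 * 100)
        assert report.accuracy(Arm.human_closed) == pytest.approx(137 / 220 * 100)
        assert report.accuracy(Arm.human_open) == pytest.approx(163 / 220 * 100)
        assert report.count(Arm.human_closed, "overall", "total_errors") == 83

    def test_conservation_subtypes_to_subtotals_to_total(self, table1):
        report = aggregate(table1)
        t = report.table
        assert (
            t["short_interval"] + t["did_not_require"] == t["unnecessary_subtotal"]
        ).all()
        assert (t["long_interval"] + t["failed_to_offer"] == t["missed_subtotal"]).all()
        assert (t["unnecessary_subtotal"] + t["missed_subtotal"] == t["total_errors"]).all()
        err_rate = 100.0 * t["total_errors"] / t["n_ratings"]
        assert np.allclose(t["accuracy_pct"] + err_rate, 100.0)

    def test_empty_category_absent_without_division_error(self):
        ratings = [
            GradedRating(case_id="a", arm=Arm.llm, rater_id="r1", correct=True,
                         error=ErrorType.none, category=Category.cat1_screen_recommended)
        ] * 2
        report = aggregate(list(ratings))
        assert report.accuracy(Arm.llm) == 100.0

    def test_mixed_denominators_within_category_raise(self):
        ratings = [
            GradedRating(case_id="a", arm=Arm.llm, rater_id="r1", correct=True,
                         error=ErrorType.none, category=Category.cat1_screen_recommended),
            GradedRating(case_id="a", arm=Arm.human_closed, rater_id="r1", correct=True,
                         error=ErrorType.none, category=Category.cat1_screen_recommended),
            GradedRating(case_id="b", arm=Arm.human_closed, rater_id="r1", correct=True,
                         error=ErrorType.none, category=Category.cat1_screen_recommended),
        ]
        with pytest.raises(ConsistencyError):
            aggregate(ratings)


class TestFleissKappa:
    def test_unanimous_items_two_categories_kappa_one(self):
        labels = np.array([["c"] * 5] * 42 + [["i"] * 5] * 2, dtype=object)
        matrix = RatingMatrix(labels, [f"i{k}" for k in range(44)],
                              [f"r{j}" for j in range(5)])
        assert fleiss_kappa(matrix) == pytest.approx(1.0)

    def test_two_by_two_matches_direct_formula(self):
        # item 1 unanimous, item 2 split: P-bar=0.5, Pe=0.625 -> kappa=-1/3
        labels = np.array([["correct", "correct"], ["correct", "incorrect"]], dtype=object)
        matrix = RatingMatrix(labels, ["i1", "i2"], ["r1", "r2"])
        assert fleiss_kappa(matrix) == pytest.approx(-1 / 3)

    def test_single_category_everywhere_is_undefined(self):
        labels = np.full((4, 3), "correct", dtype=object)
        matrix = RatingMatrix(labels, list("abcd"), ["r1", "r2", "r3"])
        with pytest.raises(DegenerateAgreementError):
            fleiss_kappa(matrix)

    def test_bounded_on_random_matrices(self):
        rng = np.random.default_rng(12345)
        for _ in range(20):
            labels = rng.choice(["a", "b", "c"], size=(10, 4)).astype(object)
            if len({str(v) for v in labels.ravel()}) < 2:
                continue
            assert -1.0 <= fleiss_kappa(
                RatingMatrix(labels, [f"i{k}" for k in range(10)],
                             [f"r{j}" for j in range(4)])
            ) <= 1.0

    def test_minimum_shape_enforced(self):
        labels = np.array([["a", "b"]], dtype=object)
        with pytest.raises(ValueError):
            fleiss_kappa(RatingMatrix(labels, ["i1"], ["r1", "r2"]))


class TestKappaCI:
    def _random_matrix(self, seed=7, n_items=44, n_raters=5):
        rng = np.random.default_rng(seed)
        labels = rng.choice(["correct", "incorrect"], size=(n_items, n_raters)).astype(object)
        return RatingMatrix(labels, [f"i{k}" for k in range(n_items)],
                            [f"r{j}" for j in range(n_raters)])

    def test_deterministic_under_fixed_seed(self):
        matrix = self._random_matrix()
        assert kappa_ci(matrix, n_boot=200, seed=3) == kappa_ci(matrix, n_boot=200, seed=3)

    def test_interval_contains_point_estimate(self):
        matrix = self._random_matrix()
        lo, hi = kappa_ci(matrix, n_boot=1000, seed=1)
        assert lo <= fleiss_kappa(matrix) <= hi

    def test_unanimous_matrix_upper_bound_is_one(self):
        labels = np.array([["c"] * 5] * 10 + [["i"] * 5] * 2, dtype=object)
        matrix = RatingMatrix(labels, [f"i{k}" for k in range(12)],
                              [f"r{j}" for j in range(5)])
        lo, hi = kappa_ci(matrix, n_boot=200, seed=0)
        assert hi == pytest.approx(1.0)

    def test_n_boot_floor(self):
        with pytest.raises(ValueError):
            kappa_ci(self._random_matrix(), n_boot=10)


class TestCompareAccuracy:
    @staticmethod
    def _arm(n_correct, n_total, arm=Arm.llm):
        return [
            GradedRating(
                case_id=f"c{i}", arm=arm, rater_id="r1",
                correct=i < n_correct,
                error=ErrorType.none if i < n_correct else ErrorType.missed_failed_to_offer,
                category=Category.cat1_screen_recommended,
            )
            for i in range(n_total)
        ]

    def test_identical_arms_p_one(self):
        a = self._arm(5, 5)
        for method in ("t", "two_proportion"):
            assert compare_accuracy(a, a, method).pvalue == 1.0

    def test_hand_computed_two_sample_t(self):
        # 9/10 vs 5/10 correct; pooled-variance t = 0.4/sqrt((3.4/18)*0.2)
        a, b = self._arm(9, 10), self._arm(5, 10, Arm.human_closed)
        result = compare_accuracy(a, b, "t")
        assert result.statistic == pytest.approx(2.05798, abs=1e-4)

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            compare_accuracy(self._arm(1, 2), self._arm(1, 2), "wilcoxon")


def test_ratings_csv_round_trip(tmp_path, table1):
    path = tmp_path / "ratings.csv"
    ratings_to_csv(table1, path)
    assert ratings_from_csv(path) == table1
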