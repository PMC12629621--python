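"""Evaluation harness: grading, error taxonomy, agreement and comparisons.

Recommendations are graded against gold labels in a binomial scheme: a
response is **correct** if it is concordant with *either* guideline's
acceptable answer (action equal; intervals overlapping where both carry
one). Incorrect responses receive exactly one of four error subtypes,

* unnecessary tests — ``unnecessary_short_interval`` (test sooner than any
  acceptable interval) or ``unnecessary_did_not_require`` (test offered
  when none was acceptable);
* missed tests — ``missed_long_interval`` (test later than any acceptable
  interval) or ``missed_failed_to_offer`` (no test offered when one was
  acceptable).

Aggregation produces the study-style report (per arm × category subtype
counts, subtotals, totals, accuracy on cases × raters denominators).
Agreement uses Fleiss κ (statsmodels under the hood, with an explicit
undefined-agreement error when chance agreement is 1) with a nonparametric
item-bootstrap CI; accuracy comparisons offer both the two-sample t test
on 0/1 outcomes and a two-proportion z test.

``load_table1_fixture`` reconstructs the study's published error-breakdown
table as rating records: marginal counts per arm × category are exact; the
rater/case layout within a category is an arbitrary but fixed
(lexicographic) fill, so inter-rater agreement on the *human* fixture arms
is not meaningful — only the marginals are guaranteed.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator
from scipy import stats as sps
from statsmodels.stats.inter_rater import fleiss_kappa as _sm_fleiss_kappa
from statsmodels.stats.proportion import proportions_ztest

from .cases import CaseScenario, Category
from .cci import GateConfig, GateDecision
from .engine import (
    Action,
    DualRecommendation,
    Recommendation,
    RuleConfig,
    Source,
    recommend_dual,
)
from .errors import ConsistencyError, DegenerateAgreementError, PsaGuideError


class Arm(str, Enum):
    llm = "llm"
    human_closed = "human_closed"
    human_open = "human_open"


class ErrorType(str, Enum):
    none = "none"
    unnecessary_short_interval = "unnecessary_short_interval"
    unnecessary_did_not_require = "unnecessary_did_not_require"
    missed_long_interval = "missed_long_interval"
    missed_failed_to_offer = "missed_failed_to_offer"


UNNECESSARY = (ErrorType.unnecessary_short_interval, ErrorType.unnecessary_did_not_require)
MISSED = (ErrorType.missed_long_interval, ErrorType.missed_failed_to_offer)

#: Actions that constitute offering a PSA test (referral is not a test).
TEST_ACTIONS = frozenset(
    {Action.offer_psa_now, Action.routine_interval, Action.confirmatory_repeat_weeks,
     Action.defer_treat_uti_then_repeat}
)


class AcceptableAnswer(BaseModel):
    model_config = ConfigDict(frozen=True)

    source: Source
    action: Action
    interval_months: Optional[tuple[int, int]] = None


class GoldLabel(BaseModel):
    model_config = ConfigDict(frozen=True)

    case_id: str
    acceptable: tuple[AcceptableAnswer, ...] = Field(min_length=1)
    category: Category

    @model_validator(mode="after")
    def _one_per_source(self) -> "GoldLabel":
        sources = [a.source for a in self.acceptable]
        if len(sources) != len(set(sources)):
            raise ValueError("at most one acceptable answer per source")
        return self


class GradedRating(BaseModel):
    model_config = ConfigDict(frozen=True)

    case_id: str
    arm: Arm
    rater_id: str
    correct: bool
    error: ErrorType
    category: Category

    @model_validator(mode="after")
    def _consistent(self) -> "GradedRating":
        if self.correct != (self.error is ErrorType.none):
            raise ValueError("correct must hold iff error is 'none'")
        return self


def gold_from_engine(
    case: CaseScenario,
    gate: GateDecision,
    rules: Optional[RuleConfig] = None,
    category: Optional[Category] = None,
) -> GoldLabel:
    """Gold label derived by running the rule engine on the case."""
    dual = recommend_dual(case, gate, rules)
    category = category or case.category
    if category is None:
        raise PsaGuideError(f"case {case.case_id} has no category for its gold label")
    return GoldLabel(
        case_id=case.case_id,
        acceptable=(
            AcceptableAnswer(source=Source.EAU, action=dual.eau.action,
                             interval_months=dual.eau.interval_months),
            AcceptableAnswer(source=Source.AUA, action=dual.aua.action,
                             interval_months=dual.aua.interval_months),
        ),
        category=category,
    )


def implied_window(action: Action, interval: Optional[tuple[int, int]]) -> Optional[tuple[float, float]]:
    """Months-to-next-test window implied by an action, or None for no test.

    ``offer_psa_now`` tests immediately; a confirmatory repeat happens after
    a few weeks (~1-2 months); the treat-UTI-then-repeat path a little later
    (~2-3 months); an interval recommendation carries its own window.
    Referral and no-testing imply no PSA test.
    """
    if action is Action.routine_interval:
        assert interval is not None
        return (float(interval[0]), float(interval[1]))
    if action is Action.offer_psa_now:
        return (0.0, 0.0)
    if action is Action.confirmatory_repeat_weeks:
        return (1.0, 2.0)
    if action is Action.defer_treat_uti_then_repeat:
        return (2.0, 3.0)
    return None


def _matches(final: Recommendation, acc: AcceptableAnswer) -> bool:
    if final.action != acc.action:
        return False
    if final.action is Action.routine_interval:
        assert final.interval_months is not None and acc.interval_months is not None
        a, b = final.interval_months, acc.interval_months
        return a[0] <= b[1] and b[0] <= a[1]
    return True


def grade(
    dual: Optional[DualRecommendation],
    gold: GoldLabel,
    arm: Arm = Arm.llm,
    rater_id: str = "run1",
) -> GradedRating:
    """Grade a dual recommendation (or a gate refusal, ``dual=None``).

    Correct iff any presented final action matches any acceptable answer.
    Otherwise exactly one error subtype is assigned by comparing the
    response's implied test window with the acceptable windows (see the
    module docstring for the taxonomy).
    """
    if dual is None:
        finals: tuple[Recommendation, ...] = (
            Recommendation(source=Source.COMBINED, action=Action.no_testing,
                           rationale=("gate.ineligible",)),
        )
    else:
        finals = dual.final_actions
    if any(_matches(f, a) for f in finals for a in gold.acceptable):
        return GradedRating(case_id=gold.case_id, arm=arm, rater_id=rater_id,
                            correct=True, error=ErrorType.none, category=gold.category)

    acc_windows = [
        w for a in gold.acceptable
        if (w := implied_window(a.action, a.interval_months)) is not None
    ]
    resp_windows = [
        w for f in finals
        if (w := implied_window(f.action, f.interval_months)) is not None
    ]
    if not resp_windows:
        # response offers no PSA test
        error = ErrorType.missed_failed_to_offer if acc_windows else ErrorType.unnecessary_did_not_require
    elif not acc_windows:
        error = ErrorType.unnecessary_did_not_require
    else:
        lo, hi = resp_windows[0]
        acc_lo = min(w[0] for w in acc_windows)
        acc_hi = max(w[1] for w in acc_windows)
        if hi < acc_lo:
            error = ErrorType.unnecessary_short_interval
        elif lo > acc_hi:
            error = ErrorType.missed_long_interval
        else:  # overlapping window but mismatched action: classify by direction
            error = (ErrorType.unnecessary_short_interval if lo <= acc_lo
                     else ErrorType.missed_long_interval)
    return GradedRating(case_id=gold.case_id, arm=arm, rater_id=rater_id,
                        correct=False, error=error, category=gold.category)


# ---------------------------------------------------------------------------
# Aggregation

@dataclass(frozen=True)
class EvaluationReport:
    """Study-style error breakdown with per-row conservation guarantees."""

    table: pd.DataFrame  # index (arm, category + 'overall'); count columns + accuracy

    def accuracy(self, arm: Arm | str, category: str = "overall") -> float:
        """Accuracy in percent for one arm (overall row by default)."""
        return float(self.table.loc[(str(getattr(arm, "value", arm)), category), "accuracy_pct"])

    def count(self, arm: Arm | str, category: str, column: str) -> int:
        return int(self.table.loc[(str(getattr(arm, "value", arm)), category), column])


_SUBTYPE_COLS = {
    ErrorType.unnecessary_short_interval: "short_interval",
    ErrorType.unnecessary_did_not_require: "did_not_require",
    ErrorType.missed_long_interval: "long_interval",
    ErrorType.missed_failed_to_offer: "failed_to_offer",
}


def aggregate(ratings: Sequence[GradedRating]) -> EvaluationReport:
    """Per arm × category error-subtype counts, subtotals and accuracies.

    Denominators are ratings (cases × raters). Raises
    :class:`ConsistencyError` if arms disagree on a category's denominator.
    """
    if not ratings:
        raise ValueError("aggregate requires at least one rating")
    rows = []
    df = pd.DataFrame(
        {
            "arm": [r.arm.value for r in ratings],
            "category": [r.category.value for r in ratings],
            "error": [r.error for r in ratings],
        }
    )
    cat_ns: dict[str, set[int]] = {}
    for (arm, cat), grp in df.groupby(["arm", "category"], sort=True):
        counts = {col: int((grp["error"] == et).sum()) for et, col in _SUBTYPE_COLS.items()}
        rows.append(_report_row(arm, cat, counts, len(grp)))
        cat_ns.setdefault(cat, set()).add(len(grp))
    for cat, ns in cat_ns.items():
        if len(ns) > 1:
            raise ConsistencyError(
                f"mixed denominators within category {cat!r}: {sorted(ns)}"
            )
    for arm, grp in df.groupby("arm", sort=True):
        counts = {col: int((grp["error"] == et).sum()) for et, col in _SUBTYPE_COLS.items()}
        rows.append(_report_row(arm, "overall", counts, len(grp)))
    table = pd.DataFrame(rows).set_index(["arm", "category"]).sort_index()
    return EvaluationReport(table=table)


def _report_row(arm: str, category: str, counts: dict[str, int], n: int) -> dict:
    unnecessary = counts["short_interval"] + counts["did_not_require"]
    missed = counts["long_interval"] + counts["failed_to_offer"]
    total = unnecessary + missed
    return {
        "arm": arm,
        "category": category,
        **counts,
        "unnecessary_subtotal": unnecessary,
        "missed_subtotal": missed,
        "total_errors": total,
        "n_ratings": n,
        "accuracy_pct": 100.0 * (1.0 - total / n) if n else float("nan"),
    }


# ---------------------------------------------------------------------------
# Agreement

class RatingMatrix:
    """Items × raters table of categorical ratings (every cell filled)."""

    def __init__(self, labels: np.ndarray, items: Sequence[str], raters: Sequence[str]):
        labels = np.asarray(labels, dtype=object)
        if labels.ndim != 2:
            raise ValueError("rating matrix must be 2-dimensional")
        if labels.shape != (len(items), len(raters)):
            raise ValueError("label array shape must be (n_items, n_raters)")
        self.labels = labels
        self.items = list(items)
        self.raters = list(raters)
        self.categories = sorted({str(v) for v in labels.ravel()})

    @property
    def n_items(self) -> int:
        return len(self.items)

    @property
    def n_raters(self) -> int:
        return len(self.raters)

    @property
    def n_categories(self) -> int:
        return len(self.categories)

    def counts(self) -> np.ndarray:
        """Items × categories count table (each row sums to n_raters)."""
        idx = {c: j for j, c in enumerate(self.categories)}
        out = np.zeros((self.n_items, self.n_categories), dtype=int)
        for i in range(self.n_items):
            for v in self.labels[i]:
                out[i, idx[str(v)]] += 1
        return out

    @classmethod
    def from_ratings(cls, ratings: Sequence[GradedRating]) -> "RatingMatrix":
        """Binary correct/incorrect matrix, items = cases, columns = raters."""
        cases = sorted({r.case_id for r in ratings})
        raters = sorted({r.rater_id for r in ratings})
        cell: dict[tuple[str, str], str] = {}
        for r in ratings:
            cell[(r.case_id, r.rater_id)] = "correct" if r.correct else "incorrect"
        labels = np.empty((len(cases), len(raters)), dtype=object)
        for i, c in enumerate(cases):
            for j, rt in enumerate(raters):
                if (c, rt) not in cell:
                    raise ValueError(f"rating matrix has an empty cell: {(c, rt)}")
                labels[i, j] = cell[(c, rt)]
        return cls(labels, cases, raters)


def fleiss_kappa(matrix: RatingMatrix) -> float:
    """Fleiss κ with category proportions pooled over items.

    Undefined (raises :class:`DegenerateAgreementError`) when every rating
    across all items is the same single category, i.e. expected chance
    agreement is 1 and κ is 0/0.
    """
    if matrix.n_raters < 2:
        raise ValueError("fleiss_kappa requires at least 2 raters")
    if matrix.n_items < 2:
        raise ValueError("fleiss_kappa requires at least 2 items")
    counts = matrix.counts()
    p = counts.sum(axis=0) / counts.sum()
    p_e = float((p**2).sum())
    if math.isclose(p_e, 1.0):
        raise DegenerateAgreementError(
            "all ratings fall in a single category; chance agreement is 1 and kappa undefined"
        )
    return float(_sm_fleiss_kappa(counts, method="fleiss"))


def kappa_ci(
    matrix: RatingMatrix,
    n_boot: int = 1000,
    seed: int = 0,
    level: float = 0.95,
) -> tuple[float, float]:
    """Percentile bootstrap CI for Fleiss κ, resampling items with replacement.

    Degenerate resamples (undefined κ) are skipped; more than 50% degenerate
    raises. Reproducible under a fixed seed.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    rng = np.random.default_rng(seed)
    values = []
    degenerate = 0
    for _ in range(n_boot):
        idx = rng.integers(0, matrix.n_items, size=matrix.n_items)
        resampled = RatingMatrix(
            matrix.labels[idx],
            [f"i{j}" for j in range(matrix.n_items)],
            matrix.raters,
        )
        try:
            values.append(fleiss_kappa(resampled))
        except DegenerateAgreementError:
            degenerate += 1
    if degenerate > n_boot / 2:
        raise DegenerateAgreementError(
            f"{degenerate}/{n_boot} bootstrap resamples had undefined kappa"
        )
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(values, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# Accuracy comparison

@dataclass(frozen=True)
class ComparisonResult:
    method: str
    statistic: float
    pvalue: float


def compare_accuracy(
    arm_a: Sequence[GradedRating],
    arm_b: Sequence[GradedRating],
    method: str = "two_proportion",
) -> ComparisonResult:
    """Two-sided comparison of two arms' correctness rates.

    ``method="t"`` is the two-sample Student t test on the 0/1 outcomes
    (the study's choice); ``method="two_proportion"`` (default) is the
    z test on the two proportions. Identical degenerate arms return p=1.
    """
    a = np.array([1.0 if r.correct else 0.0 for r in arm_a])
    b = np.array([1.0 if r.correct else 0.0 for r in arm_b])
    if method == "t":
        if a.std() == 0 and b.std() == 0 and a.mean() == b.mean():
            return ComparisonResult(method="t", statistic=0.0, pvalue=1.0)
        t, p = sps.ttest_ind(a, b, equal_var=True)
        return ComparisonResult(method="t", statistic=float(t), pvalue=float(p))
    if method == "two_proportion":
        if a.mean() == b.mean() and a.std() == 0 and b.std() == 0:
            return ComparisonResult(method="two_proportion", statistic=0.0, pvalue=1.0)
        z, p = proportions_ztest(
            count=[int(a.sum()), int(b.sum())], nobs=[len(a), len(b)]
        )
        return ComparisonResult(method="two_proportion", statistic=float(z), pvalue=float(p))
    raise ValueError(f"unknown method {method!r}; use 't' or 'two_proportion'")


# ---------------------------------------------------------------------------
# Published-table fixture

N_RATERS = 5

#: Cases per category (×5 raters gives the published denominators 55/45/45/40/35).
CATEGORY_CASES = {
    Category.cat1_screen_recommended: 11,
    Category.cat2_screen_not_recommended: 9,
    Category.cat3_normal_followup: 9,
    Category.cat4_elevated_psa: 8,
    Category.cat5_other: 7,
}

#: Error-subtype counts per arm × category, as published. The "(0)" on the
#: 3-count long-interval cell in category 1 is a typographical percentage;
#: counts are the internally consistent quantity and the only one stored.
_TABLE1_COUNTS: dict[Arm, dict[Category, dict[ErrorType, int]]] = {
    Arm.llm: {
        Category.cat1_screen_recommended: {ErrorType.missed_failed_to_offer: 5},
        Category.cat3_normal_followup: {ErrorType.unnecessary_short_interval: 5},
    },
    Arm.human_closed: {
        Category.cat1_screen_recommended: {
            ErrorType.missed_long_interval: 3,
            ErrorType.missed_failed_to_offer: 10,
        },
        Category.cat2_screen_not_recommended: {
            ErrorType.unnecessary_did_not_require: 14,
            ErrorType.missed_long_interval: 3,
        },
        Category.cat3_normal_followup: {
            ErrorType.unnecessary_short_interval: 8,
            ErrorType.unnecessary_did_not_require: 8,
            ErrorType.missed_failed_to_offer: 3,
        },
        Category.cat4_elevated_psa: {
            ErrorType.missed_long_interval: 20,
            ErrorType.missed_failed_to_offer: 1,
        },
        Category.cat5_other: {
            ErrorType.unnecessary_short_interval: 3,
            ErrorType.unnecessary_did_not_require: 10,
        },
    },
    Arm.human_open: {
        Category.cat1_screen_recommended: {
            ErrorType.missed_long_interval: 1,
            ErrorType.missed_failed_to_offer: 10,
        },
        Category.cat2_screen_not_recommended: {
            ErrorType.unnecessary_did_not_require: 10,
        },
        Category.cat3_normal_followup: {
            ErrorType.unnecessary_short_interval: 7,
            ErrorType.unnecessary_did_not_require: 7,
            ErrorType.missed_long_interval: 1,
        },
        Category.cat4_elevated_psa: {
            ErrorType.unnecessary_short_interval: 1,
            ErrorType.missed_long_interval: 12,
        },
        Category.cat5_other: {
            ErrorType.unnecessary_short_interval: 2,
            ErrorType.unnecessary_did_not_require: 6,
        },
    },
}

_SUBTYPE_FILL_ORDER = (
    ErrorType.unnecessary_short_interval,
    ErrorType.unnecessary_did_not_require,
    ErrorType.missed_long_interval,
    ErrorType.missed_failed_to_offer,
)


def load_table1_fixture() -> list[GradedRating]:
    """Reconstruct the published error-breakdown table as rating records.

    Three arms × 220 ratings (44 cases × 5 raters) whose per-category
    subtype counts match the published table exactly. Within a category,
    errors fill (case, rater) cells lexicographically, case-major — an
    arbitrary but fixed layout. This puts the LLM arm's 5+5 errors on one
    case each ("all 5 instances" unanimity), so its rating matrix is
    unanimous per item; the human arms' within-category layout is NOT the
    study's (unpublished), so κ on those arms is not meaningful.
    """
    ratings: list[GradedRating] = []
    for arm in Arm:
        arm_counts = _TABLE1_COUNTS.get(arm, {})
        for category, n_cases in CATEGORY_CASES.items():
            cells = [
                (f"t1-{category.value.split('_')[0]}-{i:02d}", f"r{j + 1}")
                for i in range(n_cases)
                for j in range(N_RATERS)
            ]
            errors: list[ErrorType] = []
            for subtype in _SUBTYPE_FILL_ORDER:
                errors.extend([subtype] * arm_counts.get(category, {}).get(subtype, 0))
            errors.extend([ErrorType.none] * (len(cells) - len(errors)))
            for (case_id, rater_id), error in zip(cells, errors):
                ratings.append(
                    GradedRating(
                        case_id=case_id,
                        arm=arm,
                        rater_id=rater_id,
                        correct=error is ErrorType.none,
                        error=error,
                        category=category,
                    )
                )
    return ratings


# ---------------------------------------------------------------------------
# CSV I/O

_CSV_COLUMNS = ["case_id", "arm", "rater_id", "category", "correct", "error"]


def ratings_to_csv(ratings: Sequence[GradedRating], path) -> None:
    pd.DataFrame(
        [
            {
                "case_id": r.case_id,
                "arm": r.arm.value,
                "rater_id": r.rater_id,
                "category": r.category.value,
                "correct": r.correct,
                "error": r.error.value,
            }
            for r in ratings
        ],
        columns=_CSV_COLUMNS,
    ).to_csv(path, index=False)


def ratings_from_csv(path) -> list[GradedRating]:
    df = pd.read_csv(path)
    return [
        GradedRating(
            case_id=str(row.case_id),
            arm=Arm(row.arm),
            rater_id=str(row.rater_id),
            correct=bool(row.correct),
            error=ErrorType(row.error),
            category=Category(row.category),
        )
        for row in df.itertuples()
    ]
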