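"""Set-based imaging-appropriateness metrics and the study statistics.

All case-level metrics operate on evaluation records carrying the ground-truth
Topic ``y``, predicted Topic list ``y_pred``, the guideline-appropriate study
set ``K`` and the predicted study set ``K_pred`` (see
:class:`radalign.pipelines.CaseEvaluation`; any object with those attributes
works).

Conventions:

* Imaging accuracy of a single case is |K_pred ∩ K| / |K_pred| — the fraction
  of recommended studies that are guideline-appropriate.  An empty K_pred
  (unparsed model output) scores 0 rather than being dropped, so parsing
  failures cannot inflate accuracy.
* A *false positive* case recommends imaging although the guideline set is
  exactly {None}; a *false negative* recommends only {None} although imaging
  is warranted.  Both rates are reported over all evaluated cases by default;
  a ``conditional`` denominator restricts to the cases where the condition on
  the ground truth holds (no-imaging cases for FPR, imaging-warranted cases
  for FNR).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

DEFAULT_SENTINEL = "None"


# ---------------------------------------------------------------------------
# case-level and aggregate metrics


def imaging_accuracy(K_pred: Iterable[str], K: Iterable[str]) -> float:
    """Per-case imaging accuracy |K_pred ∩ K| / |K_pred|; empty K_pred -> 0."""
    K_pred, K = frozenset(K_pred), frozenset(K)
    if not K:
        raise ValueError("ground-truth study set K must be non-empty")
    if not K_pred:
        return 0.0
    return len(K_pred & K) / len(K_pred)


def _check_nonempty(evals) -> list:
    evals = list(evals)
    if not evals:
        raise ValueError("no evaluations given")
    return evals


def topic_accuracy(evals) -> float:
    """Mean exact-match indicator: correct iff the true Topic is among y_pred."""
    evals = _check_nonempty(evals)
    return float(np.mean([1.0 if e.y in e.y_pred else 0.0 for e in evals]))


def mean_imaging_accuracy(evals) -> float:
    """Mean of per-case imaging accuracies."""
    evals = _check_nonempty(evals)
    return float(np.mean([imaging_accuracy(e.K_pred, e.K) for e in evals]))


def _is_false_positive(e, sentinel: str) -> bool:
    return frozenset(e.K) == {sentinel} and sentinel not in frozenset(e.K_pred) and bool(e.K_pred)


def _is_false_negative(e, sentinel: str) -> bool:
    return sentinel not in frozenset(e.K) and frozenset(e.K_pred) == {sentinel}


def unnecessary_rate(
    evals, denominator: str = "all", sentinel: str = DEFAULT_SENTINEL
) -> float:
    """Rate of unnecessary imaging (false positive rate).

    A case counts when the guideline set is exactly {sentinel} yet the
    prediction recommends imaging.  ``denominator="all"`` divides by all
    evaluated cases; ``"conditional"`` by the cases whose guideline set is
    {sentinel} (0 when none exist).
    """
    evals = _check_nonempty(evals)
    hits = sum(_is_false_positive(e, sentinel) for e in evals)
    if denominator == "all":
        return hits / len(evals)
    if denominator == "conditional":
        base = sum(frozenset(e.K) == {sentinel} for e in evals)
        return hits / base if base else 0.0
    raise ValueError(f"unknown denominator mode {denominator!r}")


def missed_rate(
    evals, denominator: str = "all", sentinel: str = DEFAULT_SENTINEL
) -> float:
    """Rate of missed imaging (false negative rate); mirror of
    :func:`unnecessary_rate` for imaging-warranted cases answered {sentinel}."""
    evals = _check_nonempty(evals)
    hits = sum(_is_false_negative(e, sentinel) for e in evals)
    if denominator == "all":
        return hits / len(evals)
    if denominator == "conditional":
        base = sum(sentinel not in frozenset(e.K) for e in evals)
        return hits / base if base else 0.0
    raise ValueError(f"unknown denominator mode {denominator!r}")


def f1_counts(evals, sentinel: str = DEFAULT_SENTINEL) -> tuple[int, int, int]:
    """(TP, FP, FN) counts over cases.

    TP: a clinically indicated study was ordered (K_pred ∩ K contains a
    non-sentinel study).  FP / FN: per the two rate definitions.
    """
    evals = _check_nonempty(evals)
    tp = sum(
        bool((frozenset(e.K_pred) & frozenset(e.K)) - {sentinel}) for e in evals
    )
    fp = sum(_is_false_positive(e, sentinel) for e in evals)
    fn = sum(_is_false_negative(e, sentinel) for e in evals)
    return tp, fp, fn


def f1_score(evals, sentinel: str = DEFAULT_SENTINEL) -> float:
    """F1 = 2·TP / (2·TP + FP + FN) over the evaluation set."""
    tp, fp, fn = f1_counts(evals, sentinel)
    denom = 2 * tp + fp + fn
    if denom == 0:
        raise ValueError("F1 undefined: TP + FP + FN = 0")
    return 2 * tp / denom


def dice_sorensen(A: Iterable[str], B: Iterable[str]) -> float:
    """Dice–Sørensen coefficient 2|A∩B| / (|A|+|B|); symmetric, 1 iff A = B."""
    A, B = frozenset(A), frozenset(B)
    if not A and not B:
        raise ValueError("DSC undefined for two empty sets")
    return 2 * len(A & B) / (len(A) + len(B))


@dataclass
class PairwiseDSC:
    """Per-case set agreement between two decision makers."""

    per_case: list[float]
    mean: float
    ci95: tuple[float, float]


def pairwise_dsc(
    orders1: Sequence[Iterable[str]], orders2: Sequence[Iterable[str]]
) -> PairwiseDSC:
    """Per-case DSC between two decision makers' ordered study sets,
    with the mean and a 95% CI over cases."""
    if len(orders1) != len(orders2):
        raise ValueError("decision makers must cover the same case index set")
    values = [dice_sorensen(a, b) for a, b in zip(orders1, orders2)]
    mean, lo, hi = mean_ci(values)
    return PairwiseDSC(per_case=values, mean=mean, ci95=(lo, hi))


def mean_ci(values: Sequence[float], level: float = 0.95) -> tuple[float, float, float]:
    """Mean and Student-t confidence interval (n−1 df) of a sample."""
    values = np.asarray(values, dtype=float)
    n = values.size
    if n < 2:
        raise ValueError("need at least 2 values for a confidence interval")
    if np.ptp(values) == 0.0:  # constant sample: zero-width interval
        v = float(values[0])
        return v, v, v
    mean = float(values.mean())
    sem = float(values.std(ddof=1)) / np.sqrt(n)
    tcrit = stats.t.ppf(0.5 + level / 2, df=n - 1)
    return mean, mean - tcrit * sem, mean + tcrit * sem


# ---------------------------------------------------------------------------
# statistical comparisons


@dataclass
class TestResult:
    statistic: float
    p_value: float
    method: str
    detail: dict = field(default_factory=dict)


def t_test(
    group1: Sequence[float], group2: Sequence[float], tails: int = 2,
    alternative: str = "greater",
) -> TestResult:
    """Two-sample homoscedastic (pooled-variance) t-test.

    ``tails=2`` ignores ``alternative``; ``tails=1`` tests the direction the
    caller supplies ("greater": mean(group1) > mean(group2), or "less").
    """
    g1 = np.asarray(group1, dtype=float)
    g2 = np.asarray(group2, dtype=float)
    if g1.size < 2 or g2.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if g1.std(ddof=1) == 0.0 and g2.std(ddof=1) == 0.0:
        if g1.mean() != g2.mean():
            raise ValueError("degenerate variance: both groups constant with unequal means")
        return TestResult(0.0, 1.0, "two-sample homoscedastic t")
    if tails == 2:
        alt = "two-sided"
    elif tails == 1:
        if alternative not in ("greater", "less"):
            raise ValueError("alternative must be 'greater' or 'less'")
        alt = alternative
    else:
        raise ValueError("tails must be 1 or 2")
    res = stats.ttest_ind(g1, g2, equal_var=True, alternative=alt)
    return TestResult(float(res.statistic), float(res.pvalue), "two-sample homoscedastic t")


def paired_t(
    sample1: Sequence[float], sample2: Sequence[float], tails: int = 2,
    alternative: str = "greater",
) -> TestResult:
    """Two-sample paired t-test on matched observations."""
    s1 = np.asarray(sample1, dtype=float)
    s2 = np.asarray(sample2, dtype=float)
    if s1.size != s2.size:
        raise ValueError("paired samples must have equal length")
    if s1.size < 2:
        raise ValueError("need at least 2 pairs")
    diff = s1 - s2
    if diff.std(ddof=1) == 0.0:
        if diff.mean() != 0.0:
            raise ValueError("degenerate variance: constant nonzero differences")
        return TestResult(0.0, 1.0, "paired t")
    alt = "two-sided" if tails == 2 else alternative
    res = stats.ttest_rel(s1, s2, alternative=alt)
    return TestResult(float(res.statistic), float(res.pvalue), "paired t")


def mcnemar(
    outcomes1: Sequence[int], outcomes2: Sequence[int], exact_threshold: int = 25
) -> TestResult:
    """McNemar test on paired binary outcomes.

    Uses the exact binomial test on the discordant pairs when there are fewer
    than ``exact_threshold`` of them, otherwise the χ² statistic with
    continuity correction.
    """
    o1 = np.asarray(outcomes1, dtype=int)
    o2 = np.asarray(outcomes2, dtype=int)
    if o1.size != o2.size:
        raise ValueError("paired outcomes must have equal length")
    if not (set(np.unique(o1)) <= {0, 1} and set(np.unique(o2)) <= {0, 1}):
        raise ValueError("outcomes must be binary (0/1)")
    b = int(np.sum((o1 == 1) & (o2 == 0)))
    c = int(np.sum((o1 == 0) & (o2 == 1)))
    n_disc = b + c
    if n_disc == 0:
        return TestResult(0.0, 1.0, "mcnemar-exact", {"b": b, "c": c})
    if n_disc < exact_threshold:
        p = float(stats.binomtest(b, n_disc, 0.5).pvalue)
        return TestResult(float(b), min(p, 1.0), "mcnemar-exact", {"b": b, "c": c})
    chi2 = (abs(b - c) - 1) ** 2 / n_disc
    p = float(stats.chi2.sf(chi2, df=1))
    return TestResult(float(chi2), p, "mcnemar-chi2-cc", {"b": b, "c": c})


# ---------------------------------------------------------------------------
# aggregate report


@dataclass
class MetricReport:
    """The full metric suite for one pipeline run (all seeds pooled)."""

    n_cases: int
    n_seeds: int
    topic_accuracy: float
    imaging_accuracy: float
    fpr: float
    fnr: float
    fpr_conditional: float
    fnr_conditional: float
    f1: float
    tp: int
    fp: int
    fn: int
    unparsed_fraction: float
    per_seed_topic_accuracy: dict[int, float]
    per_seed_imaging_accuracy: dict[int, float]
    topic_accuracy_ci95: tuple[float, float] | None
    imaging_accuracy_ci95: tuple[float, float] | None


def metric_report(evals, sentinel: str = DEFAULT_SENTINEL) -> MetricReport:
    """Compute the whole metric suite, pooling over seeds and also reporting
    per-seed means with 95% CIs over seeds (when >= 2 seeds ran)."""
    evals = _check_nonempty(evals)
    seeds = sorted({e.seed for e in evals})
    per_seed_topic = {
        s: topic_accuracy([e for e in evals if e.seed == s]) for s in seeds
    }
    per_seed_imaging = {
        s: mean_imaging_accuracy([e for e in evals if e.seed == s]) for s in seeds
    }
    tp, fp, fn = f1_counts(evals, sentinel)
    denom = 2 * tp + fp + fn
    topic_ci = imaging_ci = None
    if len(seeds) >= 2:
        _, lo, hi = mean_ci(list(per_seed_topic.values()))
        topic_ci = (lo, hi)
        _, lo, hi = mean_ci(list(per_seed_imaging.values()))
        imaging_ci = (lo, hi)
    return MetricReport(
        n_cases=len({e.case_id for e in evals}),
        n_seeds=len(seeds),
        topic_accuracy=topic_accuracy(evals),
        imaging_accuracy=mean_imaging_accuracy(evals),
        fpr=unnecessary_rate(evals, "all", sentinel),
        fnr=missed_rate(evals, "all", sentinel),
        fpr_conditional=unnecessary_rate(evals, "conditional", sentinel),
        fnr_conditional=missed_rate(evals, "conditional", sentinel),
        f1=(2 * tp / denom) if denom else float("nan"),
        tp=tp, fp=fp, fn=fn,
        unparsed_fraction=float(np.mean([1.0 if e.unparsed else 0.0 for e in evals])),
        per_seed_topic_accuracy=per_seed_topic,
        per_seed_imaging_accuracy=per_seed_imaging,
        topic_accuracy_ci95=topic_ci,
        imaging_accuracy_ci95=imaging_ci,
    )
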