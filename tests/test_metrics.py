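import math

import numpy as np
import pytest
from scipy import stats

from radalign.metrics import (
    dice_sorensen,
    f1_counts,
    f1_score,
    imaging_accuracy,
    mcnemar,
    mean_ci,
    missed_rate,
    paired_t,
    pairwise_dsc,
    t_test,
    topic_accuracy,
    unnecessary_rate,
)
from radalign.pipelines import CaseEvaluation


def _ev(y="T", y_pred=("T",), K=("A",), K_pred=("A",), seed=0, case_id="c"):
    return CaseEvaluation(
        case_id=case_id, y=y, y_pred=list(y_pred), K=frozenset(K),
        K_pred=frozenset(K_pred), seed=seed, pipeline="evidence_baseline",
        unparsed=not K_pred and not y_pred,
    )


class TestImagingAccuracy:
    @pytest.mark.parametrize(
        "K_pred,K,expected",
        [
            ({"A"}, {"A"}, 1.0),
            ({"A", "B"}, {"A"}, 0.5),  # |∩|=1, |K_pred|=2
            ({"B"}, {"A"}, 0.0),
            (set(), {"A"}, 0.0),  # unparsed convention
            ({"A"}, {"A", "B"}, 1.0),  # K_pred ⊆ K
        ],
    )
    def test_worked_examples(self, K_pred, K, expected):
        assert imaging_accuracy(K_pred, K) == expected

    def test_empty_ground_truth_rejected(self):
        with pytest.raises(ValueError):
            imaging_accuracy({"A"}, set())


class TestTopicAccuracy:
    def test_counting(self):
        evals = [_ev(y_pred=("T",))] * 3 + [_ev(y_pred=("X",))]
        assert topic_accuracy(evals) == 0.75

    def test_m_greater_one_membership(self):
        assert topic_accuracy([_ev(y_pred=("X", "T"))]) == 1.0

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            topic_accuracy([])


class TestRates:
    def test_no_sentinel_cases_fpr_zero(self):
        assert unnecessary_rate([_ev()]) == 0.0

    def test_fpr_counting_all_denominator(self):
        evals = [_ev(K=("None",), K_pred=("A",), case_id=str(i)) for i in range(2)]
        evals += [_ev(case_id=str(i + 2)) for i in range(8)]
        assert unnecessary_rate(evals, "all") == 0.2

    def test_fnr_conditional_denominator(self):
        evals = [_ev(K=("A",), K_pred=("None",), case_id=str(i)) for i in range(4)]
        evals += [_ev(K=("None",), K_pred=("None",), case_id="n")]
        assert missed_rate(evals, "conditional") == 1.0
        assert missed_rate(evals, "all") == 0.8

    def test_fnr_counting(self):
        evals = [_ev(case_id=str(i)) for i in range(7)]
        evals += [_ev(K=("A",), K_pred=("None",), case_id="m")]
        assert missed_rate(evals, "all") == 0.125

    def test_perfect_predictions(self):
        evals = [_ev(), _ev(K=("None",), K_pred=("None",), case_id="n")]
        assert unnecessary_rate(evals) == 0.0
        assert missed_rate(evals) == 0.0


class TestF1:
    def test_perfect(self):
        assert f1_score([_ev()]) == 1.0

    def test_formula_vs_counting_oracle(self):
        evals = (
            [_ev(case_id=f"tp{i}") for i in range(3)]
            + [_ev(K=("None",), K_pred=("A",), case_id="fp")]
            + [_ev(K=("A",), K_pred=("None",), case_id="fn")]
        )
        assert f1_counts(evals) == (3, 1, 1)
        assert f1_score(evals) == pytest.approx(2 * 3 / (2 * 3 + 1 + 1))  # 0.75

    def test_zero_tp(self):
        evals = [
            _ev(K=("None",), K_pred=("A",), case_id="fp"),
            _ev(K=("A",), K_pred=("None",), case_id="fn"),
        ]
        assert f1_score(evals) == 0.0

    def test_undefined_denominator(self):
        with pytest.raises(ValueError):
            f1_score([_ev(K=("None",), K_pred=("None",))])

    def test_order_invariance(self):
        evals = [_ev(case_id=f"tp{i}") for i in range(3)] + [
            _ev(K=("None",), K_pred=("A",), case_id="fp")
        ]
        assert f1_score(evals) == f1_score(list(reversed(evals)))


class TestDice:
    @pytest.mark.parametrize(
        "A,B,expected",
        [({"A"}, {"A"}, 1.0), ({"A"}, {"B"}, 0.0), ({"A", "B"}, {"B", "C"}, 0.5)],
    )
    def test_worked_examples(self, A, B, expected):
        assert dice_sorensen(A, B) == expected

    def test_symmetry_and_identity(self):
        rng = np.random.default_rng(0)
        universe = list("ABCDEFG")
        for _ in range(50):
            A = frozenset(rng.choice(universe, size=rng.integers(1, 5), replace=False))
            B = frozenset(rng.choice(universe, size=rng.integers(1, 5), replace=False))
            assert dice_sorensen(A, B) == dice_sorensen(B, A)
            assert (dice_sorensen(A, B) == 1.0) == (A == B)

    def test_both_empty_rejected(self):
        with pytest.raises(ValueError):
            dice_sorensen(set(), set())

    def test_pairwise_over_cases(self):
        orders1 = [{"A"}, {"A", "B"}, {"C"}]
        orders2 = [{"A"}, {"B", "C"}, {"D"}]
        res = pairwise_dsc(orders1, orders2)
        assert res.per_case == [1.0, 0.5, 0.0]
        assert res.mean == pytest.approx(0.5)
        assert res.ci95[0] <= res.mean <= res.ci95[1]

    def test_mismatched_case_sets_rejected(self):
        with pytest.raises(ValueError):
            pairwise_dsc([{"A"}], [{"A"}, {"B"}])


class TestMeanCI:
    def test_constant_values_zero_width(self):
        assert mean_ci([0.4, 0.4, 0.4]) == (0.4, 0.4, 0.4)

    def test_two_point_symmetric(self):
        mean, lo, hi = mean_ci([0.0, 1.0])
        assert mean == 0.5
        assert hi - mean == pytest.approx(mean - lo)

    def test_coverage_simulation(self):
        # 95% t-interval should cover the true mean ~95% of the time
        rng = np.random.default_rng(123)
        covered = 0
        reps = 1000
        for _ in range(reps):
            _, lo, hi = mean_ci(rng.normal(size=30))
            covered += lo <= 0.0 <= hi
        rate = covered / reps
        sigma = math.sqrt(0.95 * 0.05 / reps)
        assert abs(rate - 0.95) < 3 * sigma

    def test_single_value_rejected(self):
        with pytest.raises(ValueError):
            mean_ci([1.0])


class TestComparisons:
    def test_identical_groups_two_tailed_p_one(self):
        res = t_test([0.5, 0.5, 0.5], [0.5, 0.5, 0.5], tails=2)
        assert res.p_value == pytest.approx(1.0)
        res2 = t_test([0.1, 0.9, 0.4], [0.1, 0.9, 0.4], tails=2)
        assert res2.p_value == pytest.approx(1.0)

    def test_one_tailed_direction(self):
        g_hi, g_lo = [0.9, 0.85, 0.92, 0.88], [0.5, 0.45, 0.55, 0.52]
        assert t_test(g_hi, g_lo, tails=1, alternative="greater").p_value < 0.01
        assert t_test(g_hi, g_lo, tails=1, alternative="less").p_value > 0.99

    def test_degenerate_variance_unequal_means(self):
        with pytest.raises(ValueError, match="degenerate"):
            t_test([1.0, 1.0], [0.0, 0.0])

    def test_mcnemar_symmetric_discordance(self):
        # discordant counts (5, 5) -> exact binomial p = 1
        o1 = [1] * 5 + [0] * 5 + [1, 0]
        o2 = [0] * 5 + [1] * 5 + [1, 0]
        res = mcnemar(o1, o2)
        assert res.method == "mcnemar-exact"
        assert res.p_value == pytest.approx(1.0)

    def test_mcnemar_matches_statsmodels(self):
        from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar

        rng = np.random.default_rng(7)
        o1 = rng.integers(0, 2, size=60)
        o2 = rng.integers(0, 2, size=60)
        res = mcnemar(o1, o2)
        b = int(np.sum((o1 == 1) & (o2 == 0)))
        c = int(np.sum((o1 == 0) & (o2 == 1)))
        table = [[0, b], [c, 0]]
        exact = (b + c) < 25
        sm_res = sm_mcnemar(table, exact=exact, correction=True)
        assert res.p_value == pytest.approx(float(sm_res.pvalue))

    def test_paired_t_detects_shift(self):
        rng = np.random.default_rng(5)
        base = rng.normal(size=30)
        shifted = base + 0.8 + rng.normal(scale=0.1, size=30)
        res = paired_t(shifted, base, tails=1, alternative="greater")
        assert res.p_value < 1e-6

    @pytest.mark.parametrize("test_name", ["t", "mcnemar", "paired"])
    def test_type_i_error_calibration(self, test_name):
        """Under the null, each test should reject at ~alpha = 0.05."""
        rng = np.random.default_rng({"t": 11, "mcnemar": 12, "paired": 13}[test_name])
        reps, rejections = 2000, 0
        for _ in range(reps):
            if test_name == "t":
                p = t_test(rng.normal(size=20), rng.normal(size=20), tails=2).p_value
            elif test_name == "paired":
                p = paired_t(rng.normal(size=20), rng.normal(size=20), tails=2).p_value
            else:
                p = mcnemar(rng.integers(0, 2, 60), rng.integers(0, 2, 60)).p_value
            rejections += p < 0.05
        rate = rejections / reps
        sigma = math.sqrt(0.05 * 0.95 / reps)
        # exact McNemar is discrete and conservative: one-sided slack below
        if test_name == "mcnemar":
            assert rate <= 0.05 + 3 * sigma
        else:
            assert abs(rate - 0.05) < 3 * sigma
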