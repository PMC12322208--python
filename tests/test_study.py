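import math
import warnings

import numpy as np
import pytest

from radalign.study import (
    ParticipantResponse,
    agreement_outcome,
    fit_guidance_model,
    guidance_randomization,
)
from radalign.synthetic import SimulationSpec, make_prospective_grid


def _grid(n_s=8, n_q=6, seed=0, beta1=0.1):
    spec = SimulationSpec(
        n_participants=n_s, n_physicians=min(2, n_s - 1), n_questions=n_q, beta1=beta1
    )
    responses, truth = make_prospective_grid(spec, seed=seed)
    return responses, truth


def cgm_oracle(responses):
    """Independent normal-equations OLS + hand-built CGM sandwich.

    Rebuilds the design matrix, solves the normal equations explicitly, and
    assembles V_s + V_q - V_{s∩q} with the G/(G-1)·(N-1)/(N-K) corrections,
    entirely separately from the implementation under test.
    """
    parts = sorted({r.participant for r in responses})
    quests = sorted({r.question for r in responses})
    n = len(responses)
    cols = 5 + len(quests) - 1
    X = np.zeros((n, cols))
    y = np.zeros(n)
    s_g = np.zeros(n, dtype=int)
    q_g = np.zeros(n, dtype=int)
    for i, r in enumerate(responses):
        y[i] = r.outcome
        X[i, 0] = 1
        X[i, 1] = r.with_llm_guidance
        X[i, 2] = r.role == "physician"
        X[i, 3] = r.ai_experience
        X[i, 4] = r.ai_sentiment
        qi = quests.index(r.question)
        if qi > 0:
            X[i, 5 + qi - 1] = 1
        s_g[i] = parts.index(r.participant)
        q_g[i] = qi
    keep = [j for j in range(cols) if j == 0 or np.ptp(X[:, j]) > 0]
    X = X[:, keep]
    k = X.shape[1]
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    u = y - X @ beta
    bread = np.linalg.inv(X.T @ X)

    def one_way(groups):
        G = len(np.unique(groups))
        meat = np.zeros((k, k))
        for g in np.unique(groups):
            sel = groups == g
            score = X[sel].T @ u[sel]
            meat += np.outer(score, score)
        corr = (G / (G - 1)) * ((n - 1) / (n - k))
        return corr * bread @ meat @ bread

    inter = s_g * (q_g.max() + 1) + q_g
    V = one_way(s_g) + one_way(q_g) - one_way(inter)
    return beta, V, keep


class TestFitGuidanceModel:
    def test_matches_cgm_oracle(self):
        responses, _ = _grid(n_s=8, n_q=6, seed=21)
        res = fit_guidance_model(responses)
        beta, V, keep = cgm_oracle(responses)
        assert res.beta1 == pytest.approx(beta[1], rel=1e-9)
        assert res.beta0 == pytest.approx(beta[0], rel=1e-9)
        assert res.se_beta1 == pytest.approx(math.sqrt(V[1, 1]), rel=1e-9)

    def test_singleton_intersection_matches_hc_sandwich(self):
        # with one record per (s, q) the intersection clustering is singleton
        # clusters: its component must equal an HC sandwich with the same
        # small-sample correction, recomputed here directly
        responses, _ = _grid(n_s=4, n_q=4, seed=22)
        beta, V, keep = cgm_oracle(responses)
        res = fit_guidance_model(responses)
        assert res.se_beta1 == pytest.approx(math.sqrt(V[1, 1]), rel=1e-9)

    def test_point_estimates_match_statsmodels(self):
        import statsmodels.api as sm

        responses, _ = _grid(n_s=10, n_q=8, seed=23)
        res = fit_guidance_model(responses)
        beta, V, keep = cgm_oracle(responses)
        # cross-check the one-way participant-cluster component against
        # statsmodels' cluster-robust covariance
        parts = sorted({r.participant for r in responses})
        quests = sorted({r.question for r in responses})
        n = len(responses)
        X = np.zeros((n, 5 + len(quests) - 1))
        y = np.zeros(n)
        groups = np.zeros(n, dtype=int)
        for i, r in enumerate(responses):
            y[i] = r.outcome
            X[i, 0] = 1
            X[i, 1] = r.with_llm_guidance
            X[i, 2] = r.role == "physician"
            X[i, 3] = r.ai_experience
            X[i, 4] = r.ai_sentiment
            qi = quests.index(r.question)
            if qi > 0:
                X[i, 5 + qi - 1] = 1
            groups[i] = parts.index(r.participant)
        X = X[:, keep]
        sm_res = sm.OLS(y, X).fit(cov_type="cluster", cov_kwds={"groups": groups})
        assert res.beta1 == pytest.approx(sm_res.params[1], rel=1e-9)

    def test_beta1_recovery(self):
        spec = SimulationSpec(n_participants=30, n_questions=50, beta1=0.08)
        estimates = []
        for seed in range(8):
            responses, _ = make_prospective_grid(spec, seed=seed)
            estimates.append(fit_guidance_model(responses).beta1)
        mc_se = np.std(estimates, ddof=1) / math.sqrt(len(estimates))
        assert abs(np.mean(estimates) - 0.08) < 2 * mc_se + 0.01

    def test_constant_outcome_degenerate(self):
        responses, _ = _grid(n_s=4, n_q=4, seed=3)
        responses = [
            ParticipantResponse(
                participant=r.participant, question=r.question, outcome=1,
                with_llm_guidance=r.with_llm_guidance, role=r.role,
                ai_experience=r.ai_experience, ai_sentiment=r.ai_sentiment,
            )
            for r in responses
        ]
        with pytest.warns(UserWarning, match="degenerate"):
            res = fit_guidance_model(responses)
        assert res.beta1 == pytest.approx(0.0, abs=1e-10)
        assert res.degenerate

    def test_collinear_guidance_rejected(self):
        # guidance constant within questions and spanning the question dummies
        responses = []
        for s in range(4):
            for q in range(4):
                responses.append(
                    ParticipantResponse(
                        participant=f"s{s}", question=f"q{q}",
                        outcome=(s + q) % 2, with_llm_guidance=int(q < 2),
                        ai_experience=float(s), ai_sentiment=float(s % 2),
                    )
                )
        with pytest.raises(ValueError, match="collinear"):
            fit_guidance_model(responses)

    def test_too_few_clusters_rejected(self):
        responses = [
            ParticipantResponse(participant="s0", question=f"q{i}", outcome=i % 2,
                                with_llm_guidance=i % 2)
            for i in range(6)
        ]
        with pytest.raises(ValueError, match="clusters"):
            fit_guidance_model(responses)

    def test_order_invariance(self):
        responses, _ = _grid(n_s=6, n_q=5, seed=31)
        res1 = fit_guidance_model(responses)
        rng = np.random.default_rng(0)
        shuffled = list(responses)
        rng.shuffle(shuffled)
        res2 = fit_guidance_model(shuffled)
        assert res1.beta1 == pytest.approx(res2.beta1, rel=1e-12)
        assert res1.se_beta1 == pytest.approx(res2.se_beta1, rel=1e-9)

    def test_duplicate_cell_rejected(self):
        r = ParticipantResponse(participant="s", question="q", outcome=1,
                                with_llm_guidance=0)
        r2 = ParticipantResponse(participant="s2", question="q", outcome=0,
                                 with_llm_guidance=1)
        with pytest.raises(ValueError, match="duplicate"):
            fit_guidance_model([r, r, r2])


class TestAgreementOutcome:
    def _responses(self, answers):
        return [
            ParticipantResponse(
                participant="s0", question=f"q{i}", outcome=0,
                with_llm_guidance=i % 2, answer=a,
            )
            for i, a in enumerate(answers)
        ]

    def test_always_follows(self):
        recs = {f"q{i}": "CT head" for i in range(4)}
        out = agreement_outcome(self._responses(["CT head"] * 4), recs)
        assert [r.outcome for r in out] == [1, 1, 1, 1]

    def test_never_follows(self):
        recs = {f"q{i}": "CT head" for i in range(4)}
        out = agreement_outcome(self._responses(["US abdomen"] * 4), recs)
        assert [r.outcome for r in out] == [0, 0, 0, 0]

    def test_mixed_hand_counted(self):
        answers = ["CT head", "us abdomen", "None", "no imaging", "MRI spine",
                   "CT head.", "V/Q scan", "xray", "None", "CT head"]
        recs = {f"q{i}": r for i, r in enumerate(
            ["CT head", "US abdomen", "No Imaging", "None", "CT head",
             "ct head", "V/Q scan", "MRI", "CT head", "CT head"])}
        out = agreement_outcome(self._responses(answers), recs)
        # hand count: agree at 0 (exact), 1 (case), 2/3 (sentinel aliases),
        # 5 (punctuation), 6 (exact), 9 (exact) -> 7 agreements
        assert [r.outcome for r in out] == [1, 1, 1, 1, 0, 1, 1, 0, 0, 1]

    def test_missing_recommendation_raises(self):
        with pytest.raises(KeyError):
            agreement_outcome(self._responses(["CT head"]), {})


class TestGuidanceRandomization:
    def test_exact_half_guided(self):
        questions = [f"q{i}" for i in range(50)]
        assignment = guidance_randomization(["a", "b"], questions, 0.5, seed=4)
        assert all(len(qs) == 25 for qs in assignment.values())

    def test_seed_repeatability(self):
        questions = [f"q{i}" for i in range(10)]
        a = guidance_randomization(["p"], questions, 0.5, seed=9)
        b = guidance_randomization(["p"], questions, 0.5, seed=9)
        assert a == b

    def test_non_integral_fraction_floors(self):
        assignment = guidance_randomization(["p"], ["q0", "q1", "q2"], 0.5, seed=0)
        assert len(assignment["p"]) == 1

    def test_marginal_rate_per_question(self):
        # over many participants each question should be guided ~50% of the time
        questions = [f"q{i}" for i in range(10)]
        participants = [f"p{i}" for i in range(1000)]
        assignment = guidance_randomization(participants, questions, 0.5, seed=5)
        sigma = math.sqrt(0.5 * 0.5 / 1000)
        for q in questions:
            rate = sum(q in assignment[p] for p in participants) / 1000
            assert abs(rate - 0.5) < 3 * sigma + 1e-9
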