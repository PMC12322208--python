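"""Prospective-study statistics: guidance effect under two-way clustered SEs.

The prospective design shows each participant a grid of simulated cases
(questions); for a random half of the questions the participant also sees the
pipeline's imaging recommendation.  The guidance effect on a binary outcome
y_{s,q} (correctness, agreement with the recommendation, FPR, FNR) is
estimated with a linear probability model

    y_{s,q} = b0 + b1 * guidance_{s,q} + theta_q + chi_s + e_{s,q}

where theta_q are question fixed effects (explicit dummies; ~50 questions
keeps this tractable) and chi_s are participant covariates (physician vs
student, AI experience, AI sentiment).  Inference on b1 uses two-way
cluster-robust standard errors by participant and by question, combined by
inclusion-exclusion (Cameron–Gelbach–Miller):

    V = V_participant + V_question - V_intersection

each one-way sandwich carrying a G/(G-1) * (N-1)/(N-K) small-sample
correction, with t inference on min(G_s, G_q) - 1 degrees of freedom.  If the
combined matrix is not positive semi-definite, negative eigenvalues are
truncated to zero (and the truncation is recorded on the result).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from ._text import normalize
from .kb import SENTINEL, SENTINEL_ALIASES

ROLES = ("student", "physician")


@dataclass
class ParticipantResponse:
    """One participant's response to one study question."""

    participant: str
    question: str
    outcome: int  # binary outcome y_{s,q}
    with_llm_guidance: int  # whether guidance was shown for this (s, q)
    role: str = "student"
    ai_experience: float = 0.0
    ai_sentiment: float = 0.0
    answer: str | None = None  # study the participant ordered (for agreement)

    def __post_init__(self) -> None:
        if self.outcome not in (0, 1):
            raise ValueError("outcome must be binary")
        if self.with_llm_guidance not in (0, 1):
            raise ValueError("with_llm_guidance must be binary")
        if self.role not in ROLES:
            raise ValueError(f"role must be one of {ROLES}")


@dataclass
class RegressionResult:
    """Estimated guidance effect with two-way cluster-robust inference."""

    beta0: float
    beta1: float
    se_beta1: float
    ci95: tuple[float, float]
    p_value: float
    df: int
    n_obs: int
    n_params: int
    n_question_effects: int
    cluster_counts: dict[str, int]
    residual_std: float
    eigenvalue_truncated: bool = False
    degenerate: bool = False
    params: dict[str, float] = field(default_factory=dict)


def _design(responses: Sequence[ParticipantResponse]):
    """Build (y, X, names, participant index, question index)."""
    questions = sorted({r.question for r in responses})
    participants = sorted({r.participant for r in responses})
    q_index = {q: i for i, q in enumerate(questions)}
    s_index = {s: i for i, s in enumerate(participants)}
    seen: set[tuple[str, str]] = set()
    for r in responses:
        key = (r.participant, r.question)
        if key in seen:
            raise ValueError(f"duplicate response for participant/question {key}")
        seen.add(key)

    n = len(responses)
    names = ["intercept", "with_llm_guidance", "role_physician", "ai_experience", "ai_sentiment"]
    # question dummies, first question omitted as the reference category
    names += [f"q[{q}]" for q in questions[1:]]
    X = np.zeros((n, len(names)))
    y = np.zeros(n)
    s_ids = np.zeros(n, dtype=int)
    q_ids = np.zeros(n, dtype=int)
    for i, r in enumerate(responses):
        y[i] = r.outcome
        X[i, 0] = 1.0
        X[i, 1] = r.with_llm_guidance
        X[i, 2] = 1.0 if r.role == "physician" else 0.0
        X[i, 3] = r.ai_experience
        X[i, 4] = r.ai_sentiment
        qi = q_index[r.question]
        if qi > 0:
            X[i, 5 + qi - 1] = 1.0
        s_ids[i] = s_index[r.participant]
        q_ids[i] = q_index[r.question]
    return y, X, names, s_ids, q_ids


def _drop_constant_columns(X: np.ndarray, names: list[str]):
    """Drop covariate columns with no variation (e.g. all-student samples)."""
    keep = [0]
    for j in range(1, X.shape[1]):
        if np.ptp(X[:, j]) > 0:
            keep.append(j)
    return X[:, keep], [names[j] for j in keep], keep


def _cluster_meat(X: np.ndarray, resid: np.ndarray, groups: np.ndarray) -> np.ndarray:
    k = X.shape[1]
    meat = np.zeros((k, k))
    for g in np.unique(groups):
        idx = groups == g
        s = X[idx].T @ resid[idx]
        meat += np.outer(s, s)
    return meat


def _one_way_v(X, resid, groups, bread, n, k) -> np.ndarray:
    g = len(np.unique(groups))
    corr = (g / (g - 1)) * ((n - 1) / (n - k)) if g > 1 else 1.0
    return corr * bread @ _cluster_meat(X, resid, groups) @ bread


def fit_guidance_model(
    responses: Sequence[ParticipantResponse],
    outcome_field: str = "outcome",
) -> RegressionResult:
    """Fit the linear probability model and return the guidance effect.

    ``outcome_field`` selects which binary attribute of the responses is the
    dependent variable (``"outcome"`` by default; e.g. set to an agreement
    field produced by :func:`agreement_outcome`).

    Raises on a singular design (naming the collinear column), and on fewer
    than 2 clusters in either dimension.  A constant outcome yields beta1 = 0
    with a degenerate-variance warning rather than an error.
    """
    responses = list(responses)
    if not responses:
        raise ValueError("no responses given")
    if outcome_field != "outcome":
        responses = [
            ParticipantResponse(
                participant=r.participant, question=r.question,
                outcome=int(getattr(r, outcome_field)),
                with_llm_guidance=r.with_llm_guidance, role=r.role,
                ai_experience=r.ai_experience, ai_sentiment=r.ai_sentiment,
            )
            for r in responses
        ]
    y, X, names, s_ids, q_ids = _design(responses)
    n_s, n_q = len(np.unique(s_ids)), len(np.unique(q_ids))
    if n_s < 2 or n_q < 2:
        raise ValueError(
            f"need >= 2 clusters in each dimension (participants={n_s}, questions={n_q})"
        )
    X, names, _ = _drop_constant_columns(X, names)
    if "with_llm_guidance" not in names:
        raise ValueError("guidance indicator has no variation; effect not identified")
    n, k = X.shape

    rank = np.linalg.matrix_rank(X)
    if rank < k:
        # name a column involved in the collinearity: the last one whose
        # removal restores full column rank
        for j in range(k - 1, 0, -1):
            X_wo = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(X_wo) == rank:
                raise ValueError(f"singular design: column {names[j]!r} is collinear")
        raise ValueError("singular design")

    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    resid_std = float(resid.std(ddof=min(k, n - 1)) if n > k else 0.0)

    j_guid = names.index("with_llm_guidance")
    b1 = float(beta[j_guid])
    b0 = float(beta[0])

    if np.allclose(resid, 0.0):
        warnings.warn("degenerate variance: outcome is perfectly fit", stacklevel=2)
        return RegressionResult(
            beta0=b0, beta1=b1, se_beta1=0.0, ci95=(b1, b1), p_value=1.0,
            df=min(n_s, n_q) - 1, n_obs=n, n_params=k,
            n_question_effects=sum(nm.startswith("q[") for nm in names),
            cluster_counts={"participant": n_s, "question": n_q},
            residual_std=0.0, degenerate=True,
            params=dict(zip(names, map(float, beta))),
        )

    XtX_inv = np.linalg.inv(X.T @ X)
    v_s = _one_way_v(X, resid, s_ids, XtX_inv, n, k)
    v_q = _one_way_v(X, resid, q_ids, XtX_inv, n, k)
    inter = s_ids.astype(np.int64) * (q_ids.max() + 1) + q_ids
    v_sq = _one_way_v(X, resid, inter, XtX_inv, n, k)
    V = v_s + v_q - v_sq

    # The inclusion-exclusion combination need not be PSD; with a large
    # fixed-effect block it is routinely indefinite in directions orthogonal
    # to the coefficient of interest, where the indefiniteness is harmless.
    # Repair by eigenvalue truncation only when the variance entry actually
    # used for inference is non-positive, so a well-behaved guidance-effect
    # variance is never perturbed.
    truncated = False
    if V[j_guid, j_guid] <= 0:
        truncated = True
        warnings.warn(
            "two-way cluster variance for the guidance effect non-positive; "
            "negative eigenvalues truncated to 0",
            stacklevel=2,
        )
        eigvals, eigvecs = np.linalg.eigh(V)
        V = (eigvecs * np.clip(eigvals, 0.0, None)) @ eigvecs.T

    se = float(np.sqrt(max(V[j_guid, j_guid], 0.0)))
    df = min(n_s, n_q) - 1
    if se == 0.0:
        p = 1.0
        ci = (b1, b1)
    else:
        tstat = b1 / se
        p = float(2 * stats.t.sf(abs(tstat), df=df))
        p = min(max(p, np.finfo(float).tiny), 1.0)
        tcrit = stats.t.ppf(0.975, df=df)
        ci = (b1 - tcrit * se, b1 + tcrit * se)

    return RegressionResult(
        beta0=b0, beta1=b1, se_beta1=se, ci95=ci, p_value=p, df=df,
        n_obs=n, n_params=k,
        n_question_effects=sum(nm.startswith("q[") for nm in names),
        cluster_counts={"participant": n_s, "question": n_q},
        residual_std=resid_std, eigenvalue_truncated=truncated,
        params=dict(zip(names, map(float, beta))),
    )


def _same_study(a: str, b: str) -> bool:
    na, nb = normalize(a), normalize(b)
    fold = lambda s: normalize(SENTINEL) if s in SENTINEL_ALIASES else s
    return fold(na) == fold(nb)


def agreement_outcome(
    responses: Sequence[ParticipantResponse],
    llm_recommendations: Mapping[str, str],
) -> list[ParticipantResponse]:
    """Replace each outcome with agreement between answer and recommendation.

    ``llm_recommendations`` maps question id to the recommended study.  A
    response agrees (1) iff the participant's ordered study equals the
    recommendation under study-name normalization (sentinel aliases folded).
    Every question that appears in ``responses`` must have a recommendation
    and every response an ``answer``.
    """
    out = []
    for r in responses:
        if r.question not in llm_recommendations:
            raise KeyError(f"no LLM recommendation for question {r.question!r}")
        if r.answer is None:
            raise ValueError(
                f"response ({r.participant!r}, {r.question!r}) has no recorded answer"
            )
        agree = int(_same_study(r.answer, llm_recommendations[r.question]))
        out.append(
            ParticipantResponse(
                participant=r.participant, question=r.question, outcome=agree,
                with_llm_guidance=r.with_llm_guidance, role=r.role,
                ai_experience=r.ai_experience, ai_sentiment=r.ai_sentiment,
                answer=r.answer,
            )
        )
    return out


def guidance_randomization(
    participants: Sequence[str],
    questions: Sequence[str],
    fraction: float = 0.5,
    seed: int = 0,
) -> dict[str, frozenset[str]]:
    """Assign each participant a uniform random subset of guided questions.

    Exactly ``floor(fraction * len(questions))`` questions are guided per
    participant; assignments are independent across participants and
    deterministic for a fixed seed.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    n = len(questions)
    n_guided = int(math.floor(fraction * n + 1e-9))
    rng = np.random.default_rng(seed)
    questions = list(questions)
    return {
        p: frozenset(questions[i] for i in rng.choice(n, size=n_guided, replace=False))
        for p in participants
    }
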