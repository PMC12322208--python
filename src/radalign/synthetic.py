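"""Synthetic fixtures with controlled statistical structure.

Everything the rest of the package consumes can be generated here at desk
scale: miniature guideline knowledge bases (including *sibling* topic pairs
that share identical appropriate-study sets and at least one topic whose
guidance warrants no imaging), labeled one-liner cases in clinical
telegraphic style, confusion-driven mock completion backends, and
participant × question prospective-study grids with a known guidance effect.

All generators are pure functions of (spec, seed); fixing the seed reproduces
the artifact bit-for-bit.

Default prospective-grid parameters mirror the study design they emulate:
30 participants (23 students, 7 physicians) × 50 questions, guidance shown
for a random half of the questions per participant, a without-guidance base
correctness rate of 0.158, and a guidance effect of +0.08 on the probability
scale.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np

from .dataset import OneLinerRecord
from .kb import SENTINEL, GuidelineKB, GuidelineTopic, ImagingStudy, TopicVariant, resolve_topic, validate_kb
from .prompting import ScriptedBackend, _stable_seed
from .study import ParticipantResponse, guidance_randomization

_CONDITIONS = [
    "Acute chest pain", "Chronic cough", "Head trauma", "Suspected pulmonary embolism",
    "Acute abdominal pain", "Low back pain", "Suspected stroke", "Hematuria",
    "Acute shortness of breath", "Syncope", "Blunt abdominal trauma", "Headache",
    "Knee pain after fall", "Right upper quadrant pain", "Flank pain",
    "Palpable breast mass", "First trimester bleeding", "Acute scrotal pain",
    "Suspected appendicitis", "Febrile seizure",
]

_MODALITIES = [
    "CT", "MRI", "Radiography", "US", "CTA", "MRA", "Fluoroscopy", "Nuclear scan",
]
_REGIONS = [
    "head", "chest", "abdomen", "pelvis", "spine", "knee", "shoulder", "neck",
    "pulmonary arteries", "kidneys",
]

_RISKS = ["HTN", "IDDM", "HLD", "COPD", "CAD", "CKD", "afib", "20 pack-year smoking hx"]


@dataclass
class ConfusionModel:
    """Row-stochastic map from true topics to emitted topics.

    ``rows[t]`` is the distribution over emitted topic names when the true
    topic is ``t``; ``unparsed_rate`` is the probability of emitting
    non-matching text instead.  ``sibling_map`` records topic pairs that are
    known to share identical study sets in the target KB.
    """

    rows: dict[str, dict[str, float]]
    sibling_map: dict[str, str] = field(default_factory=dict)
    unparsed_rate: float = 0.0

    def validate(self, kb: GuidelineKB | None = None) -> None:
        for t, row in self.rows.items():
            total = sum(row.values())
            if abs(total - 1.0) > 1e-9 or any(p < 0 for p in row.values()):
                raise ValueError(f"row for topic {t!r} is not a probability vector")
        if not 0.0 <= self.unparsed_rate <= 1.0:
            raise ValueError("unparsed_rate must be in [0, 1]")
        if kb is not None:
            for a, b in self.sibling_map.items():
                if resolve_topic(kb, a) != resolve_topic(kb, b):
                    raise ValueError(f"declared siblings {a!r}/{b!r} do not share study sets")

    @classmethod
    def identity(cls, kb: GuidelineKB) -> "ConfusionModel":
        return cls(rows={t: {t: 1.0} for t in kb.topic_names})

    @classmethod
    def sibling_confusion(
        cls, kb: GuidelineKB, sibling_map: dict[str, str], p: float,
        unparsed_rate: float = 0.0,
    ) -> "ConfusionModel":
        """Send each sibling topic to its partner with probability ``p``."""
        rows = {}
        for t in kb.topic_names:
            if t in sibling_map:
                rows[t] = {t: 1.0 - p, sibling_map[t]: p}
            else:
                rows[t] = {t: 1.0}
        model = cls(rows=rows, sibling_map=dict(sibling_map), unparsed_rate=unparsed_rate)
        model.validate(kb)
        return model


@dataclass
class SimulationSpec:
    """Problem sizes and generating parameters for the synthetic fixtures."""

    n_topics: int = 6
    n_studies: int = 8
    n_sibling_pairs: int = 1
    n_cases_per_topic: int = 10
    # prospective-study grid
    n_participants: int = 30
    n_physicians: int = 7
    n_questions: int = 50
    guided_fraction: float = 0.5
    beta0: float = 0.158
    beta1: float = 0.08
    question_effect_sd: float = 0.05
    role_effect: float = 0.02
    experience_effect: float = 0.01
    sentiment_effect: float = 0.01

    def __post_init__(self) -> None:
        if min(self.n_topics, self.n_studies, self.n_cases_per_topic,
               self.n_participants, self.n_questions) <= 0:
            raise ValueError("all counts must be positive")
        if self.n_sibling_pairs < 0:
            raise ValueError("n_sibling_pairs must be >= 0")
        if not 0.0 <= self.guided_fraction <= 1.0:
            raise ValueError("guided_fraction must be in [0, 1]")


def _topic_name(i: int) -> str:
    if i < len(_CONDITIONS):
        return _CONDITIONS[i]
    return f"Synthetic condition {i:03d}"


def make_kb(spec: SimulationSpec, seed: int = 0) -> GuidelineKB:
    """Generate a valid miniature knowledge base.

    The vocabulary holds ``n_studies`` real studies plus the no-imaging
    sentinel.  The first ``2 * n_sibling_pairs`` topics form sibling pairs
    sharing identical canonical study sets; the last topic resolves to the
    sentinel (so no-imaging cases exist).  Non-canonical extra variants are
    added to some topics so canonical-variant isolation is actually exercised.
    """
    if spec.n_studies < 2:
        raise ValueError("n_studies must be >= 2")
    if 2 * spec.n_sibling_pairs + 1 > spec.n_topics:
        raise ValueError(
            f"cannot fit {spec.n_sibling_pairs} sibling pairs plus a no-imaging "
            f"topic into {spec.n_topics} topics"
        )
    rng = np.random.default_rng(seed)
    studies = [ImagingStudy(SENTINEL, is_no_imaging=True)]
    for i in range(spec.n_studies):
        name = f"{_MODALITIES[i % len(_MODALITIES)]} {_REGIONS[(i // len(_MODALITIES)) % len(_REGIONS)]}"
        if i >= len(_MODALITIES) * len(_REGIONS):
            name = f"{name} protocol {i}"
        studies.append(ImagingStudy(name=name, is_no_imaging=False))
    real_names = [s.name for s in studies if not s.is_no_imaging]

    def draw_set() -> frozenset[str]:
        size = int(rng.integers(1, min(3, len(real_names)) + 1))
        return frozenset(str(s) for s in rng.choice(real_names, size=size, replace=False))

    topics: list[GuidelineTopic] = []
    panels = [f"Panel {chr(ord('A') + i % 11)}" for i in range(spec.n_topics)]
    pending_sibling_set: frozenset[str] | None = None
    for i in range(spec.n_topics):
        name = _topic_name(i)
        if i == spec.n_topics - 1:
            canon_set: frozenset[str] = frozenset({SENTINEL})
        elif i < 2 * spec.n_sibling_pairs:
            if i % 2 == 0:
                pending_sibling_set = draw_set()
            canon_set = pending_sibling_set
        else:
            canon_set = draw_set()
        variants = [TopicVariant(description=f"{name}. Initial imaging.",
                                 studies=canon_set, canonical=True)]
        if rng.random() < 0.5:
            variants.append(
                TopicVariant(
                    description=f"{name}. Pregnant patient. Initial imaging.",
                    studies=draw_set(), canonical=False,
                )
            )
        order = rng.permutation(len(variants))
        topics.append(
            GuidelineTopic(name=name, panel=panels[i], variants=[variants[j] for j in order])
        )

    kb = GuidelineKB(version_date="synthetic-2024-06", topics=topics, study_vocabulary=studies)
    violations = validate_kb(kb)
    if violations:  # should be unreachable; guards generator regressions
        raise AssertionError(f"generated KB invalid: {violations}")
    return kb


def sibling_pairs(spec: SimulationSpec) -> dict[str, str]:
    """The symmetric sibling map implied by make_kb's layout for this spec."""
    pairs: dict[str, str] = {}
    for p in range(spec.n_sibling_pairs):
        a, b = _topic_name(2 * p), _topic_name(2 * p + 1)
        pairs[a] = b
        pairs[b] = a
    return pairs


def make_cases(
    kb: GuidelineKB, n_per_topic: int = 10, seed: int = 0, subset: str = "Synthetic"
) -> list[OneLinerRecord]:
    """Generate labeled one-liner records in clinical telegraphic style.

    ``n_per_topic * n_topics`` records are drawn with labels uniform over the
    KB's topics.  Each text embeds the presentation ("concerning for <topic>")
    so that scripted/confusion backends can recover the true label from the
    rendered prompt alone.
    """
    rng = np.random.default_rng(seed)
    names = kb.topic_names
    total = n_per_topic * len(names)
    records = []
    for i in range(total):
        label = names[int(rng.integers(len(names)))]
        age = int(rng.integers(18, 90))
        sex = "M" if rng.random() < 0.5 else "F"
        risks = ", ".join(rng.choice(_RISKS, size=2, replace=False))
        duration = int(rng.integers(1, 14))
        text = (
            f"{age} {sex} with {risks} p/w {duration} d hx of symptoms "
            f"concerning for {label.lower()}"
        )
        records.append(OneLinerRecord(id=f"case-{i:05d}", text=text, subset=subset, label=label))
    return records


_CONCERN_RE = re.compile(r"concerning for ([^\n]*)")


def _true_topic_from_prompt(prompt: str, kb: GuidelineKB) -> str | None:
    """Recover the embedded true topic from a rendered prompt.

    Matches KB topic names against the "concerning for ..." clause, preferring
    the longest topic name found anywhere in the prompt as a fallback.
    """
    # ICL prompts embed example one-liners too; the query case follows the
    # last "Patient one-liner:" marker, so scope the search there when present
    marker = "Patient one-liner:"
    scope = prompt[prompt.rindex(marker):] if marker in prompt else prompt
    m = _CONCERN_RE.search(scope)
    hay = (m.group(1) if m else scope).lower()
    best = None
    for name in kb.topic_names:
        if name.lower() in hay and (best is None or len(name) > len(best)):
            best = name
    return best


def make_confusion_backend(
    kb: GuidelineKB, confusion: ConfusionModel, seed: int = 0
) -> ScriptedBackend:
    """A mock completion backend driven by a confusion model.

    For a topic-prediction prompt whose case has true topic ``t``, the backend
    emits ``"Answer: <topic drawn from rows[t]>"``, or non-matching text with
    probability ``unparsed_rate``.  Output is deterministic per (prompt, call
    seed): the same prompt under the same seed always yields the same text.
    """
    confusion.validate(kb)

    def respond(prompt: str, call_seed: int) -> str:
        rng = np.random.default_rng(_stable_seed(f"{seed}|{call_seed}|{prompt}", call_seed))
        true_topic = _true_topic_from_prompt(prompt, kb)
        if true_topic is None or true_topic not in confusion.rows:
            return "I cannot determine this."
        if rng.random() < confusion.unparsed_rate:
            return "I cannot determine this."
        row = confusion.rows[true_topic]
        names = sorted(row)
        probs = np.array([row[n] for n in names])
        emitted = names[int(rng.choice(len(names), p=probs / probs.sum()))]
        return f"After reviewing the case, the most relevant topic follows.\nAnswer: {emitted}"

    return ScriptedBackend(script={}, fallback=respond)


def make_prospective_grid(
    spec: SimulationSpec, seed: int = 0
) -> tuple[list[ParticipantResponse], dict]:
    """Simulate a participant × question response grid with known effects.

    Outcomes are Bernoulli with success probability
    ``clip(beta0 + beta1 * guidance + theta_q + covariate effects, 0, 1)``,
    clipping (not a logit link) to match the linear probability model that is
    fit to the grid.  Guidance is assigned per participant via
    :func:`guidance_randomization`.  Returns the grid and the true generating
    parameters (including the drawn question effects and the clip count).
    """
    rng = np.random.default_rng(seed)
    participants = [f"s{i:03d}" for i in range(spec.n_participants)]
    questions = [f"q{i:03d}" for i in range(spec.n_questions)]
    roles = {
        p: ("physician" if i < spec.n_physicians else "student")
        for i, p in enumerate(participants)
    }
    ai_exp = {p: int(rng.integers(0, 5)) for p in participants}
    ai_sent = {p: int(rng.integers(0, 5)) for p in participants}
    theta = rng.normal(0.0, spec.question_effect_sd, size=spec.n_questions)
    theta -= theta.mean()  # identifiable: effects sum to zero

    guided = guidance_randomization(
        participants, questions, spec.guided_fraction, seed=int(rng.integers(2**31))
    )

    responses = []
    n_clipped = 0
    for p in participants:
        for j, q in enumerate(questions):
            g = 1 if q in guided[p] else 0
            prob = (
                spec.beta0
                + spec.beta1 * g
                + theta[j]
                + spec.role_effect * (roles[p] == "physician")
                + spec.experience_effect * ai_exp[p]
                + spec.sentiment_effect * ai_sent[p]
            )
            clipped = min(max(prob, 0.0), 1.0)
            if clipped != prob:
                n_clipped += 1
            responses.append(
                ParticipantResponse(
                    participant=p, question=q,
                    outcome=int(rng.random() < clipped),
                    with_llm_guidance=g, role=roles[p],
                    ai_experience=float(ai_exp[p]), ai_sentiment=float(ai_sent[p]),
                )
            )
    if n_clipped:
        warnings.warn(
            f"{n_clipped} success probabilities clipped into [0, 1]", stacklevel=2
        )
    truth = {
        "beta0": spec.beta0,
        "beta1": spec.beta1,
        "theta": dict(zip(questions, map(float, theta))),
        "n_clipped": n_clipped,
        "guided": {p: sorted(qs) for p, qs in guided.items()},
    }
    return responses, truth
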