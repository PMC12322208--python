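"""Prompt construction, the completion-backend contract, and answer parsing.

The pipelines support two tasks — predicting the most relevant guideline
Topic(s) for a one-liner, and recommending an imaging study directly — and
four inference strategies: plain (baseline) prompting, chain-of-thought (COT)
in four reasoning styles, in-context learning (ICL) with retrieved labeled
examples, and retrieval-augmented generation (RAG) with retrieved guideline
text.

Model output is free text; parsing extracts the segment after the final
``Answer:`` marker (or the last non-empty line when the marker is absent),
splits candidate items, and normalizes each against the knowledge base.
Items that match nothing are dropped — they will be scored wrong downstream —
and a response in which nothing matches is recorded as unparsed.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Protocol, Sequence, runtime_checkable

import numpy as np

from .kb import GuidelineKB, normalize_study_name, normalize_topic_name
from .retrieval import DocumentChunk

ANSWER_MARKER = "Answer:"

TASKS = ("topic_prediction", "imaging_prediction")
STRATEGIES = ("baseline", "cot", "icl", "rag")
COT_STYLES = ("default", "differential", "bayesian", "analytic")

#: Instruction block per chain-of-thought reasoning style.
COT_INSTRUCTIONS = {
    "default": "Think through the case step by step before giving your final answer.",
    "differential": (
        "Reason through a differential diagnosis for this patient, narrowing it "
        "down step by step, before giving your final answer."
    ),
    "bayesian": (
        "Reason as a Bayesian: start from prior probabilities over the candidate "
        "topics and update them with each clinical finding before giving your "
        "final answer."
    ),
    "analytic": (
        "Reason through the pathophysiology of the underlying disease process "
        "before giving your final answer."
    ),
}

TOPIC_TASK_TEMPLATE = (
    "You are a clinical decision-support assistant. Given the patient one-liner "
    "below, return the {{m_phrase}} from the guideline topic list.\n"
    "{{reasoning}}{{context}}"
    "Patient one-liner: {{one_liner}}\n"
    'Respond with the topic name(s) on the final line after the marker "Answer:".\n'
)

IMAGING_TASK_TEMPLATE = (
    "You are a clinical decision-support assistant. Given the patient one-liner "
    "below, recommend the single most appropriate diagnostic imaging study, or "
    '"None" if no imaging is warranted.\n'
    "{{reasoning}}{{context}}"
    "Patient one-liner: {{one_liner}}\n"
    'Respond with the study name on the final line after the marker "Answer:".\n'
)


@runtime_checkable
class CompletionBackend(Protocol):
    """Text-completion contract: deterministic at temperature 0 for a fixed seed."""

    def generate(self, prompt: str, temperature: float = 0.0, seed: int = 0) -> str:
        ...


@dataclass
class PromptSpec:
    """Configuration of one inference strategy."""

    task: str = "topic_prediction"
    strategy: str = "baseline"
    cot_style: str | None = None
    k_context: int = 0
    m: int = 1

    def __post_init__(self) -> None:
        if self.task not in TASKS:
            raise ValueError(f"unknown task {self.task!r}")
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if self.k_context < 0:
            raise ValueError("k_context must be >= 0")
        if self.strategy == "cot":
            if self.cot_style is None:
                self.cot_style = "default"
            if self.cot_style not in COT_STYLES:
                raise ValueError(f"unknown cot_style {self.cot_style!r}")
        elif self.cot_style is not None:
            raise ValueError("cot_style is only valid with strategy='cot'")


@dataclass
class ParsedPrediction:
    """Canonicalized model output: topics and/or studies, or unparsed."""

    topics: list[str] = field(default_factory=list)
    studies: frozenset[str] = frozenset()
    unparsed: bool = False


def _render(template: str, mapping: dict[str, str]) -> str:
    out = template
    for key, value in mapping.items():
        out = out.replace("{{" + key + "}}", value)
    return out


def load_template(path: str | Path) -> str:
    """Read a prompt template (plain text with ``{{placeholder}}`` slots)."""
    return Path(path).read_text(encoding="utf-8")


def build_prompt(
    one_liner: str,
    spec: PromptSpec,
    kb: GuidelineKB,
    context: Sequence[DocumentChunk] = (),
    template: str | None = None,
) -> str:
    """Deterministically fill the prompt template for one case.

    RAG context chunks are embedded as numbered reference passages; ICL
    context items must carry labels and are embedded as worked examples in
    retrieval order.
    """
    if spec.strategy in ("rag", "icl"):
        if len(context) != spec.k_context or spec.k_context == 0:
            raise ValueError(
                f"strategy {spec.strategy!r} requires exactly k_context="
                f"{spec.k_context} context items, got {len(context)}"
            )

    reasoning = ""
    if spec.strategy == "cot":
        reasoning = COT_INSTRUCTIONS[spec.cot_style] + "\n"

    ctx = ""
    if spec.strategy == "rag":
        passages = [f"[{i + 1}] {c.text}" for i, c in enumerate(context)]
        ctx = "Reference guideline passages:\n" + "\n".join(passages) + "\n"
    elif spec.strategy == "icl":
        lines = []
        for i, c in enumerate(context):
            if c.label is None:
                raise ValueError("ICL context items must carry topic labels")
            lines.append(f"Example {i + 1}: {c.text}\n{ANSWER_MARKER} {c.label}")
        ctx = "Worked examples:\n" + "\n".join(lines) + "\n"

    if template is None:
        template = (
            TOPIC_TASK_TEMPLATE if spec.task == "topic_prediction" else IMAGING_TASK_TEMPLATE
        )
    m_phrase = (
        "single most relevant topic" if spec.m == 1 else f"up to {spec.m} most relevant topics"
    )
    return _render(
        template,
        {
            "one_liner": one_liner,
            "reasoning": reasoning,
            "context": ctx,
            "m": str(spec.m),
            "m_phrase": m_phrase,
        },
    )


_ITEM_SPLIT_RE = re.compile(r"(?:\n|;|\s\d+[.)]\s+)+")
_ITEM_LEAD_RE = re.compile(r"^\s*(?:\d+[.)]|[-*•])\s*")


def _answer_segment(text: str) -> str:
    matches = list(re.finditer(re.escape(ANSWER_MARKER), text, flags=re.IGNORECASE))
    if matches:
        return text[matches[-1].end():]
    lines = [ln for ln in text.splitlines() if ln.strip()]
    return lines[-1] if lines else ""


def _split_items(segment: str) -> list[str]:
    items = []
    for raw in _ITEM_SPLIT_RE.split(segment):
        item = _ITEM_LEAD_RE.sub("", raw).strip(" \t.,-")
        if item:
            items.append(item)
    return items


def parse_topic_response(text: str, kb: GuidelineKB, m: int = 1) -> ParsedPrediction:
    """Extract up to ``m`` canonical Topic names from a model response.

    Items are split on newlines, semicolons, and numbered-list markers,
    normalized via the KB's fuzzy matcher, de-duplicated preserving order, and
    truncated to ``m``.  If nothing matches the response is unparsed.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    topics: list[str] = []
    for item in _split_items(_answer_segment(text)):
        canon = normalize_topic_name(item, kb)
        if canon is not None and canon not in topics:
            topics.append(canon)
        if len(topics) == m:
            break
    if not topics:
        return ParsedPrediction(unparsed=True)
    return ParsedPrediction(topics=topics)


def parse_imaging_response(text: str, kb: GuidelineKB) -> ParsedPrediction:
    """Extract recommended imaging studies from a model response.

    Matched against the study vocabulary with exact normalized matching;
    sentinel aliases ("none", "no imaging") are folded to the sentinel.
    """
    studies: list[str] = []
    for item in _split_items(_answer_segment(text)):
        canon = normalize_study_name(item, kb)
        if canon is not None and canon not in studies:
            studies.append(canon)
    if not studies:
        return ParsedPrediction(unparsed=True)
    return ParsedPrediction(studies=frozenset(studies))


def _stable_seed(prompt: str, seed: int) -> int:
    digest = hashlib.sha256(f"{seed}:{prompt}".encode("utf-8")).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class ScriptedBackend:
    """Deterministic mock backend: scripted answers with an optional fallback.

    ``script`` maps a *prompt key* to a response.  Keys are matched first
    against the full prompt, then against any case id embedded in the prompt
    (substring match), so tests can script per-case answers without rendering
    prompts themselves.  Unscripted prompts go to ``fallback`` (a callable
    ``(prompt, seed) -> text``) when given, else return an empty string.
    Satisfies the :class:`CompletionBackend` determinism contract.
    """

    script: dict[str, str] = field(default_factory=dict)
    fallback: object = None

    def generate(self, prompt: str, temperature: float = 0.0, seed: int = 0) -> str:
        if prompt in self.script:
            return self.script[prompt]
        for key, response in self.script.items():
            if key and key in prompt:
                return response
        if self.fallback is not None:
            return self.fallback(prompt, seed)
        return ""


def mock_backend(
    script: dict[str, str] | None = None,
    fallback_confusion=None,
    seed: int = 0,
) -> ScriptedBackend:
    """Build a deterministic mock completion backend.

    ``fallback_confusion`` may be a ConfusionModel-driven responder from
    :mod:`radalign.synthetic` (anything callable as ``(prompt, seed) -> text``).
    """
    return ScriptedBackend(script=dict(script or {}), fallback=fallback_confusion)


def deterministic_rng(prompt: str, seed: int) -> np.random.Generator:
    """RNG keyed on (prompt, seed): the mock-backend determinism primitive."""
    return np.random.default_rng(_stable_seed(prompt, seed))
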