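"""Baseline and evidence-based inference pipelines, plus the benchmark runner.

Two ways to turn a one-liner into an imaging recommendation:

* **Baseline** — ask the completion backend for an imaging study directly.
* **Evidence-based** — ask the backend only for the most relevant guideline
  Topic(s), then resolve each Topic to its appropriate-study set with a
  deterministic knowledge-base lookup (no model involvement in the final
  step).  The "optimized" flavor is the same pipeline with a tuned prompting
  strategy (e.g. chain-of-thought) in the PromptSpec.

With ``m > 1`` predicted Topics, the predicted study set is the union of the
per-Topic sets with the no-imaging sentinel dropped whenever any real study is
present (a topic that warrants imaging dominates one that does not).

A backend failure or unparseable response is recorded as an unparsed case —
empty predictions scoring 0 — never silently dropped, so parsing failures
cannot inflate accuracy.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

from .dataset import OneLinerRecord
from .kb import GuidelineKB, UnknownTopicError, normalize_topic_name, resolve_topic, sentinel_name
from .prompting import (
    CompletionBackend,
    PromptSpec,
    build_prompt,
    parse_imaging_response,
    parse_topic_response,
)

PIPELINES = ("baseline", "evidence_baseline", "evidence_optimized")


@dataclass
class CaseEvaluation:
    """Everything the metric suite needs about one case under one seed."""

    case_id: str
    y: str  # ground-truth Topic
    y_pred: list[str]  # predicted Topics (empty for baseline pipeline / unparsed)
    K: frozenset[str]  # guideline-appropriate study set for y
    K_pred: frozenset[str]  # predicted study set
    seed: int
    pipeline: str
    unparsed: bool = False


@dataclass
class RunConfig:
    """One benchmark run: pipeline kind, prompting spec, seeds."""

    pipeline: str = "evidence_baseline"
    spec: PromptSpec = field(default_factory=PromptSpec)
    seeds: Sequence[int] = (0, 1, 2, 3, 4)
    drop_sentinel_from_union: bool = True

    def __post_init__(self) -> None:
        if self.pipeline not in PIPELINES:
            raise ValueError(f"unknown pipeline {self.pipeline!r}")
        if not self.seeds:
            raise ValueError("seeds must be non-empty")


def _ground_truth(record: OneLinerRecord, kb: GuidelineKB) -> tuple[str, frozenset[str]]:
    if record.label is None:
        raise ValueError(f"record {record.id!r} has no ground-truth label")
    y = normalize_topic_name(record.label, kb)
    if y is None:
        raise UnknownTopicError(record.label)
    return y, resolve_topic(kb, y)


def union_study_sets(
    topics: Sequence[str], kb: GuidelineKB, drop_sentinel: bool = True
) -> frozenset[str]:
    """Union of the resolved study sets of several Topics (de-duplicated).

    When ``drop_sentinel`` is set and any real study is present, the
    no-imaging sentinel is removed from the union.
    """
    out: set[str] = set()
    for t in topics:
        out |= resolve_topic(kb, t)
    sent = sentinel_name(kb)
    if drop_sentinel and out - {sent}:
        out.discard(sent)
    return frozenset(out)


def run_evidence_pipeline(
    record: OneLinerRecord,
    backend: CompletionBackend,
    kb: GuidelineKB,
    spec: PromptSpec,
    seed: int = 0,
    context=(),
    pipeline: str = "evidence_baseline",
    drop_sentinel_from_union: bool = True,
) -> CaseEvaluation:
    """Topic prediction followed by deterministic guideline lookup."""
    if spec.task != "topic_prediction":
        raise ValueError("evidence pipeline requires spec.task='topic_prediction'")
    y, K = _ground_truth(record, kb)
    prompt = build_prompt(record.text, spec, kb, context)
    try:
        response = backend.generate(prompt, temperature=0.0, seed=seed)
    except Exception:
        response = ""
    parsed = parse_topic_response(response, kb, m=spec.m)
    if parsed.unparsed:
        return CaseEvaluation(
            case_id=record.id, y=y, y_pred=[], K=K, K_pred=frozenset(),
            seed=seed, pipeline=pipeline, unparsed=True,
        )
    K_pred = union_study_sets(parsed.topics, kb, drop_sentinel_from_union)
    return CaseEvaluation(
        case_id=record.id, y=y, y_pred=list(parsed.topics), K=K, K_pred=K_pred,
        seed=seed, pipeline=pipeline,
    )


def run_baseline_pipeline(
    record: OneLinerRecord,
    backend: CompletionBackend,
    kb: GuidelineKB,
    spec: PromptSpec,
    seed: int = 0,
    context=(),
) -> CaseEvaluation:
    """Direct imaging-study recommendation without consulting the guidelines."""
    if spec.task != "imaging_prediction":
        raise ValueError("baseline pipeline requires spec.task='imaging_prediction'")
    y, K = _ground_truth(record, kb)
    prompt = build_prompt(record.text, spec, kb, context)
    try:
        response = backend.generate(prompt, temperature=0.0, seed=seed)
    except Exception:
        response = ""
    parsed = parse_imaging_response(response, kb)
    return CaseEvaluation(
        case_id=record.id, y=y, y_pred=[], K=K,
        K_pred=parsed.studies if not parsed.unparsed else frozenset(),
        seed=seed, pipeline="baseline", unparsed=parsed.unparsed,
    )


def run_benchmark(
    dataset: Sequence[OneLinerRecord],
    config: RunConfig,
    backend: CompletionBackend,
    kb: GuidelineKB,
    context=(),
) -> list[CaseEvaluation]:
    """Evaluate every included case under every seed.

    Returns ``len(included) * len(seeds)`` evaluations, deterministic given
    the backend's determinism contract.  Excluded records are skipped.
    """
    included = [r for r in dataset if r.included]
    if not included:
        raise ValueError("no included cases in dataset")
    evals: list[CaseEvaluation] = []
    for seed in config.seeds:
        for record in included:
            if config.pipeline == "baseline":
                evals.append(
                    run_baseline_pipeline(record, backend, kb, config.spec, seed, context)
                )
            else:
                evals.append(
                    run_evidence_pipeline(
                        record, backend, kb, config.spec, seed, context,
                        pipeline=config.pipeline,
                        drop_sentinel_from_union=config.drop_sentinel_from_union,
                    )
                )
    return evals


def write_evaluations(evals: Sequence[CaseEvaluation], path: str | Path) -> None:
    """Serialize evaluations as JSONL (sets stored as sorted lists)."""
    with Path(path).open("w", encoding="utf-8") as fh:
        for e in evals:
            doc = asdict(e)
            doc["K"] = sorted(e.K)
            doc["K_pred"] = sorted(e.K_pred)
            fh.write(json.dumps(doc) + "\n")


def read_evaluations(path: str | Path) -> list[CaseEvaluation]:
    evals = []
    with Path(path).open("r", encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            doc = json.loads(line)
            evals.append(
                CaseEvaluation(
                    case_id=doc["case_id"], y=doc["y"], y_pred=doc["y_pred"],
                    K=frozenset(doc["K"]), K_pred=frozenset(doc["K_pred"]),
                    seed=doc["seed"], pipeline=doc["pipeline"],
                    unparsed=doc.get("unparsed", False),
                )
            )
    return evals
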