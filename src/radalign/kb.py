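"""Guideline knowledge base: Topics, clinical variants, and appropriate-study sets.

The knowledge base mirrors the structure of the ACR Appropriateness Criteria:
clinical Topics (grouped into panels) each describe several clinical variants,
and each variant carries the set of imaging studies deemed appropriate for it.
Because a deterministic Topic -> study-set lookup needs a single answer per
Topic, exactly one variant per Topic is marked *canonical* (a curation
decision stored in the snapshot, validated here, never inferred).

Topics whose guidance warrants no imaging resolve to the sentinel pseudo-study
``"None"`` (``"No Imaging"`` is accepted as an input alias).

The on-disk format is a single JSON document::

    {"version_date": "...",
     "study_vocabulary": ["None", "CT head without IV contrast", ...],
     "topics": [{"name": ..., "panel": ...,
                 "variants": [{"description": ..., "canonical": true,
                               "studies": [...]}, ...]}, ...]}
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from ._text import normalize, token_set_similarity

#: Canonical name of the no-imaging sentinel pseudo-study.
SENTINEL = "None"

#: Accepted spellings that normalize to the sentinel.
SENTINEL_ALIASES = frozenset({"none", "no imaging"})

#: Marker returned by :func:`normalize_topic_name` when nothing matches.
UNMATCHED = None

#: Minimum token-set similarity for a fuzzy topic-name match.
DEFAULT_FUZZY_THRESHOLD = 0.90


class KBError(ValueError):
    """Raised for knowledge-base schema or invariant violations."""


class UnknownTopicError(KeyError):
    """Raised when a topic name is not present in the knowledge base."""


@dataclass(frozen=True)
class ImagingStudy:
    """A diagnostic imaging study drawn from a fixed vocabulary."""

    name: str
    is_no_imaging: bool = False


@dataclass
class TopicVariant:
    """One clinical variant of a Topic with its appropriate-study set."""

    description: str
    studies: frozenset[str]
    canonical: bool = False


@dataclass
class GuidelineTopic:
    """A named clinical-scenario category with its variants."""

    name: str
    panel: str
    variants: list[TopicVariant] = field(default_factory=list)

    @property
    def canonical_variant(self) -> TopicVariant:
        for v in self.variants:
            if v.canonical:
                return v
        raise KBError(f"topic {self.name!r}: no canonical variant")


@dataclass
class GuidelineKB:
    """A versioned snapshot of the Topic -> study-set guideline mapping."""

    version_date: str
    topics: list[GuidelineTopic]
    study_vocabulary: list[ImagingStudy]

    def __post_init__(self) -> None:
        self._by_norm_name = {normalize(t.name): t for t in self.topics}

    @property
    def topic_names(self) -> list[str]:
        return [t.name for t in self.topics]

    @property
    def study_names(self) -> frozenset[str]:
        return frozenset(s.name for s in self.study_vocabulary)

    def topic(self, name: str) -> GuidelineTopic:
        try:
            return self._by_norm_name[normalize(name)]
        except KeyError:
            raise UnknownTopicError(name) from None


def _study_from_json(obj) -> ImagingStudy:
    if isinstance(obj, str):
        return ImagingStudy(name=obj, is_no_imaging=normalize(obj) in SENTINEL_ALIASES)
    return ImagingStudy(
        name=obj["name"],
        is_no_imaging=bool(obj.get("is_no_imaging", normalize(obj["name"]) in SENTINEL_ALIASES)),
    )


def _canonical_study_name(raw: str, vocabulary: dict[str, str]) -> str:
    """Map a study spelling onto the vocabulary, folding sentinel aliases."""
    norm = normalize(raw)
    if norm in SENTINEL_ALIASES:
        norm = normalize(SENTINEL)
    return vocabulary.get(norm, raw)


def load_kb(path: str | Path) -> GuidelineKB:
    """Load and validate a knowledge-base snapshot from a JSON file.

    Raises
    ------
    KBError
        If the document does not conform to the schema or any invariant is
        violated; the message names the offending topic.
    """
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise KBError(f"{path}: not valid JSON: {exc}") from exc
    for key in ("version_date", "topics", "study_vocabulary"):
        if key not in doc:
            raise KBError(f"{path}: missing required key {key!r}")

    vocab = [_study_from_json(s) for s in doc["study_vocabulary"]]
    vocab_by_norm = {normalize(s.name): s.name for s in vocab}

    topics = []
    for tdoc in doc["topics"]:
        try:
            name = tdoc["name"]
            variants = [
                TopicVariant(
                    description=v.get("description", ""),
                    studies=frozenset(
                        _canonical_study_name(s, vocab_by_norm) for s in v["studies"]
                    ),
                    canonical=bool(v.get("canonical", False)),
                )
                for v in tdoc["variants"]
            ]
        except (KeyError, TypeError) as exc:
            raise KBError(
                f"{path}: malformed topic entry {tdoc.get('name', '<unnamed>')!r}: {exc}"
            ) from exc
        topics.append(GuidelineTopic(name=name, panel=tdoc.get("panel", ""), variants=variants))

    kb = GuidelineKB(version_date=doc["version_date"], topics=topics, study_vocabulary=vocab)
    violations = validate_kb(kb)
    if violations:
        raise KBError("; ".join(violations))
    return kb


def save_kb(kb: GuidelineKB, path: str | Path) -> None:
    """Serialize a knowledge base back to its JSON snapshot format."""
    doc = {
        "version_date": kb.version_date,
        "study_vocabulary": [
            {"name": s.name, "is_no_imaging": s.is_no_imaging} for s in kb.study_vocabulary
        ],
        "topics": [
            {
                "name": t.name,
                "panel": t.panel,
                "variants": [
                    {
                        "description": v.description,
                        "canonical": v.canonical,
                        "studies": sorted(v.studies),
                    }
                    for v in t.variants
                ],
            }
            for t in kb.topics
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1), encoding="utf-8")


def validate_kb(kb: GuidelineKB) -> list[str]:
    """Check every type invariant; return a list of violation descriptions.

    An empty list means the knowledge base is valid.  Each violation names the
    topic (or vocabulary entry) and the rule broken.
    """
    violations: list[str] = []
    if not kb.topics:
        violations.append("KB: topic count is 0")

    vocab_norms = [normalize(s.name) for s in kb.study_vocabulary]
    if len(set(vocab_norms)) != len(vocab_norms):
        violations.append("vocabulary: study names not unique after normalization")
    for s in kb.study_vocabulary:
        if not s.name:
            violations.append("vocabulary: empty study name")
    n_sentinel = sum(s.is_no_imaging for s in kb.study_vocabulary)
    if n_sentinel != 1:
        violations.append(
            f"vocabulary: exactly one no-imaging sentinel required, found {n_sentinel}"
        )

    topic_norms = [normalize(t.name) for t in kb.topics]
    if len(set(topic_norms)) != len(topic_norms):
        violations.append("topics: names not unique after normalization")

    vocab_set = kb.study_names
    for t in kb.topics:
        if not t.variants:
            violations.append(f"topic {t.name!r}: zero variants")
            continue
        n_canon = sum(v.canonical for v in t.variants)
        if n_canon != 1:
            violations.append(
                f"topic {t.name!r}: exactly one canonical variant required, found {n_canon}"
            )
        for v in t.variants:
            if not v.studies:
                violations.append(
                    f"topic {t.name!r}: variant {v.description!r} has an empty study set"
                )
            missing = v.studies - vocab_set
            if missing:
                violations.append(
                    f"topic {t.name!r}: studies not in vocabulary: {sorted(missing)}"
                )
    return violations


def resolve_topic(kb: GuidelineKB, topic: str) -> frozenset[str]:
    """Deterministically map a canonical Topic name to its appropriate studies.

    Returns the canonical variant's study set; for topics whose guidance
    warrants no imaging this is ``{"None"}``.  The lookup never consults a
    model and is a pure function of the snapshot.

    Raises
    ------
    UnknownTopicError
        If ``topic`` is not in the knowledge base.  Free-text names must be
        run through :func:`normalize_topic_name` first.
    """
    return kb.topic(topic).canonical_variant.studies


def normalize_topic_name(
    raw: str,
    kb: GuidelineKB,
    *,
    fuzzy_threshold: float = DEFAULT_FUZZY_THRESHOLD,
):
    """Map free text onto a canonical Topic name, or ``None`` if unmatched.

    Exact match after case/whitespace/punctuation normalization is preferred.
    Otherwise the best token-set-similarity candidate is accepted iff its
    similarity is at least ``fuzzy_threshold`` (ties broken alphabetically);
    anything below threshold returns the unmatched marker.  Conservative on
    purpose: an off-guideline topic string should be scored wrong downstream,
    not silently mapped to the nearest name.
    """
    norm = normalize(raw)
    if not norm:
        return UNMATCHED
    hit = kb._by_norm_name.get(norm)
    if hit is not None:
        return hit.name
    best_name, best_sim = None, -1.0
    for t in sorted(kb.topics, key=lambda t: t.name):
        sim = token_set_similarity(raw, t.name)
        if sim > best_sim:
            best_name, best_sim = t.name, sim
    if best_sim >= fuzzy_threshold:
        return best_name
    return UNMATCHED


def normalize_study_name(raw: str, kb: GuidelineKB):
    """Map free text onto a vocabulary study name (sentinel aliases folded).

    Exact normalized match only; returns ``None`` when unmatched.
    """
    norm = normalize(raw)
    if norm in SENTINEL_ALIASES:
        norm = normalize(SENTINEL)
    for s in kb.study_vocabulary:
        if normalize(s.name) == norm:
            return s.name
    return UNMATCHED


def sentinel_name(kb: GuidelineKB) -> str:
    """Name of the no-imaging sentinel in this KB's vocabulary."""
    for s in kb.study_vocabulary:
        if s.is_no_imaging:
            return s.name
    raise KBError("KB has no no-imaging sentinel in its vocabulary")
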