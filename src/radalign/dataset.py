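"""One-liner case datasets: records, I/O, first-sentence extraction, summaries.

A *one-liner* is a single-sentence clinical case summary ("62 F with RUQ pain
and fever p/w jaundice").  Records carry a ground-truth guideline Topic label
and an optional exclusion-reason code; excluded records are kept in the file
but dropped from evaluation.  Exclusion reasons are human judgments recorded
as annotations, never auto-classified:

1. the guidelines provide no guidance for the chief complaint;
2. an appropriate study was already performed and/or a diagnosis made;
3. insufficient information about the patient;
4. the text does not refer to a specific patient presentation.
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass, field, asdict
from pathlib import Path

from .kb import GuidelineKB, normalize_topic_name

EXCLUSION_REASONS = (1, 2, 3, 4)

#: Abbreviations whose trailing period never ends a sentence.  Clinical text
#: is abbreviation-dense, so the splitter is guard-listed rather than naive.
ABBREVIATIONS = {
    "dr.", "mr.", "ms.", "mrs.", "y.o.", "vs.", "st.", "jr.", "sr.", "prof.",
}

_BOUNDARY_RE = re.compile(r"[.?!]+\s+(?=[A-Z0-9])")


@dataclass
class OneLinerRecord:
    """A one-sentence patient case with its evaluation bookkeeping."""

    id: str
    text: str
    subset: str
    label: str | None = None
    exclusion_reason: int | None = None

    def __post_init__(self) -> None:
        if not self.text:
            raise ValueError(f"record {self.id!r}: text must be non-empty")
        if self.exclusion_reason is not None and self.exclusion_reason not in EXCLUSION_REASONS:
            raise ValueError(
                f"record {self.id!r}: exclusion_reason must be one of {EXCLUSION_REASONS}"
            )

    @property
    def included(self) -> bool:
        return self.exclusion_reason is None


@dataclass
class DatasetSummary:
    """Counts a dataset report prints: sizes, exclusions, topic coverage."""

    total: int
    n_included: int
    n_excluded: int
    per_subset: dict[str, int]
    excluded_by_reason: dict[int, int]
    n_kb_topics: int
    topics_covered: int
    coverage_pct: float
    per_subset_topics: dict[str, int] = field(default_factory=dict)
    per_subset_coverage_pct: dict[str, float] = field(default_factory=dict)


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round half away from zero (printed-style rounding, not banker's)."""
    factor = 10 ** ndigits
    scaled = x * factor
    import math

    return math.floor(abs(scaled) + 0.5) / factor * (1 if x >= 0 else -1)


def extract_one_liner(case_text: str) -> str:
    """Return the first sentence of a (possibly multi-sentence) case text.

    A boundary is a period/question/exclamation mark followed by whitespace
    and an uppercase letter or digit, unless the preceding word is a known
    abbreviation or a single-letter initial.  If no boundary is found the
    whole (stripped) text is returned, so the result is never empty and the
    function is idempotent.
    """
    if not case_text or not case_text.strip():
        raise ValueError("case_text must be non-empty")
    text = case_text.strip()
    for m in _BOUNDARY_RE.finditer(text):
        head = text[: m.end(0) - len(m.group(0).lstrip("?.!"))]
        # word immediately before the boundary punctuation, including it
        prev = head.rstrip().rsplit(None, 1)[-1].lower() if head.rstrip() else ""
        if prev in ABBREVIATIONS:
            continue
        stem = prev.rstrip(".?!")
        if len(stem) == 1 and stem.isalpha():  # single-letter initial, "J."
            continue
        return text[: m.start(0) + len(m.group(0).rstrip())].rstrip()
    return text


def _record_from_mapping(obj: dict, where: str) -> OneLinerRecord:
    for key in ("id", "text", "subset"):
        if key not in obj or obj[key] in (None, ""):
            raise ValueError(f"{where}: missing required field {key!r}")
    label = obj.get("label")
    if label in ("", None):
        label = None
    reason = obj.get("exclusion_reason")
    if reason in ("", None):
        reason = None
    else:
        reason = int(reason)
    return OneLinerRecord(
        id=str(obj["id"]), text=obj["text"], subset=obj["subset"],
        label=label, exclusion_reason=reason,
    )


def read_dataset(path: str | Path) -> list[OneLinerRecord]:
    """Read records from JSONL (``.jsonl``/``.json``) or CSV.

    Parse errors report the offending line number.
    """
    path = Path(path)
    records: list[OneLinerRecord] = []
    if path.suffix.lower() == ".csv":
        with path.open("r", encoding="utf-8", newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or "text" not in reader.fieldnames:
                raise ValueError(f"{path}: CSV is missing the 'text' column")
            for i, row in enumerate(reader, start=2):
                records.append(_record_from_mapping(row, f"{path}:{i}"))
    else:
        with path.open("r", encoding="utf-8") as fh:
            for i, line in enumerate(fh, start=1):
                line = line.strip()
                if not line:
                    continue
                try:
                    obj = json.loads(line)
                except json.JSONDecodeError as exc:
                    raise ValueError(f"{path}:{i}: invalid JSON: {exc}") from exc
                records.append(_record_from_mapping(obj, f"{path}:{i}"))
    return records


def write_dataset(records: list[OneLinerRecord], path: str | Path) -> None:
    """Write records to JSONL or CSV; ``read_dataset`` round-trips losslessly."""
    path = Path(path)
    fields = ["id", "text", "subset", "label", "exclusion_reason"]
    if path.suffix.lower() == ".csv":
        with path.open("w", encoding="utf-8", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=fields)
            writer.writeheader()
            for r in records:
                row = asdict(r)
                row = {k: ("" if row[k] is None else row[k]) for k in fields}
                writer.writerow(row)
    else:
        with path.open("w", encoding="utf-8") as fh:
            for r in records:
                fh.write(json.dumps(asdict(r)) + "\n")


def apply_exclusions(
    records: list[OneLinerRecord], annotations: dict[str, int]
) -> list[OneLinerRecord]:
    """Set ``exclusion_reason`` from an id -> reason-code annotation map.

    Unannotated records are untouched.  Unknown ids or invalid codes raise.
    Returns new record objects; the input list is not mutated.
    """
    known = {r.id for r in records}
    unknown = set(annotations) - known
    if unknown:
        raise KeyError(f"annotations reference unknown record ids: {sorted(unknown)}")
    for code in annotations.values():
        if code not in EXCLUSION_REASONS:
            raise ValueError(f"invalid exclusion reason {code!r}")
    return [
        OneLinerRecord(
            id=r.id, text=r.text, subset=r.subset, label=r.label,
            exclusion_reason=annotations.get(r.id, r.exclusion_reason),
        )
        for r in records
    ]


def summarize(records: list[OneLinerRecord], kb: GuidelineKB | None = None) -> DatasetSummary:
    """Tally subset sizes, the exclusion breakdown, and topic coverage.

    Coverage counts the KB topics with nonzero support among *included*
    records; percentages are over the KB topic count, rounded to one decimal
    half away from zero.  Totals are conserved: subset sizes sum to the
    included count, reason-code counts to the excluded count.
    """
    included = [r for r in records if r.included]
    excluded = [r for r in records if not r.included]

    per_subset: dict[str, int] = {}
    for r in included:
        per_subset[r.subset] = per_subset.get(r.subset, 0) + 1
    excluded_by_reason = {code: 0 for code in EXCLUSION_REASONS}
    for r in excluded:
        excluded_by_reason[r.exclusion_reason] += 1

    n_kb_topics = len(kb.topics) if kb is not None else 0
    covered: set[str] = set()
    per_subset_topics: dict[str, set[str]] = {}
    if kb is not None:
        for r in included:
            if r.label is None:
                continue
            canon = normalize_topic_name(r.label, kb)
            if canon is None:
                raise ValueError(
                    f"record {r.id!r}: label {r.label!r} does not normalize into the KB"
                )
            covered.add(canon)
            per_subset_topics.setdefault(r.subset, set()).add(canon)

    def pct(n: int) -> float:
        return round_half_away(100.0 * n / n_kb_topics, 1) if n_kb_topics else 0.0

    return DatasetSummary(
        total=len(records),
        n_included=len(included),
        n_excluded=len(excluded),
        per_subset=per_subset,
        excluded_by_reason=excluded_by_reason,
        n_kb_topics=n_kb_topics,
        topics_covered=len(covered),
        coverage_pct=pct(len(covered)),
        per_subset_topics={k: len(v) for k, v in per_subset_topics.items()},
        per_subset_coverage_pct={k: pct(len(v)) for k, v in per_subset_topics.items()},
    )
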