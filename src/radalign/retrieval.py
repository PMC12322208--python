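"""Corpus segmentation and document ranking for RAG / ICL context retrieval.

Guideline narrative text is segmented into disjoint, order-preserving chunks
of bounded character length (defaults 1119–2048, matching fixed retrieval
windows that fit a handful of chunks into a model context).  Three retriever
families rank chunks for a query:

* Okapi BM25 over a bag-of-words index,
* cosine similarity over a pluggable text -> vector embedder, and
* a uniform random baseline.

For in-context-learning retrieval the "corpus" is simply labeled example
one-liners; chunks carry an optional label so the same rankers serve both.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from ._text import tokenize

DEFAULT_MIN_CHARS = 1119
DEFAULT_MAX_CHARS = 2048


@dataclass
class DocumentChunk:
    """One retrievable unit of corpus text."""

    id: int
    text: str
    source: str
    flagged: bool = False  # out-of-bounds remainder (e.g. a short tail)
    label: str | None = None  # set for ICL example corpora

    @property
    def char_len(self) -> int:
        return len(self.text)


@dataclass
class RetrievalResult:
    """Ranked chunk ids with aligned, non-increasing scores."""

    ids: list[int]
    scores: list[float]
    k: int
    warnings: list[str] = field(default_factory=list)


_PARA_RE = re.compile(r"\n\s*\n")
_SENT_RE = re.compile(r"(?<=[.?!])\s+")


def _split_units(text: str, max_chars: int) -> list[str]:
    """Paragraph units, with oversize paragraphs split at sentence boundaries
    (hard character split only when a single sentence still exceeds the cap)."""
    units: list[str] = []
    for para in (p for p in _PARA_RE.split(text) if p):
        if len(para) <= max_chars:
            units.append(para)
            continue
        for sent in _SENT_RE.split(para):
            while len(sent) > max_chars:
                units.append(sent[:max_chars])
                sent = sent[max_chars:]
            if sent:
                units.append(sent)
    return units


def segment_corpus(
    texts: Sequence[tuple[str, str]],
    min_chars: int = DEFAULT_MIN_CHARS,
    max_chars: int = DEFAULT_MAX_CHARS,
) -> list[DocumentChunk]:
    """Greedily pack each source text into disjoint chunks of bounded length.

    Units (paragraphs, or sentences of oversize paragraphs) are accumulated in
    order and flushed when adding the next unit would exceed ``max_chars``.
    Concatenating a source's chunk texts reproduces the source text exactly.
    Chunks shorter than ``min_chars`` (short tails or degenerate sources) are
    flagged rather than merged across sources.
    """
    if not (0 < min_chars < max_chars):
        raise ValueError("require 0 < min_chars < max_chars")
    if not texts:
        raise ValueError("corpus is empty")
    chunks: list[DocumentChunk] = []
    for source, text in texts:
        if not text:
            raise ValueError(f"source {source!r} has empty text")
        units = _split_units(text, max_chars)
        # Track offsets so re-concatenation is exact: chunk boundaries are cut
        # from the original string, preserving inter-unit separators.
        pieces: list[str] = []
        pos = 0
        acc_start, acc_end = 0, 0
        for unit in units:
            u_start = text.index(unit, pos)
            u_end = u_start + len(unit)
            pos = u_end
            if acc_end > acc_start and (u_end - acc_start) > max_chars:
                pieces.append(text[acc_start:acc_end])
                acc_start = acc_end
            acc_end = u_end
        pieces.append(text[acc_start:])
        for piece in pieces:
            chunks.append(
                DocumentChunk(
                    id=len(chunks),
                    text=piece,
                    source=source,
                    flagged=not (min_chars <= len(piece) <= max_chars),
                )
            )
    return chunks


def _ranked_result(
    scores: np.ndarray, ids: list[int], k: int, warn: list[str] | None = None
) -> RetrievalResult:
    # stable sort on (-score, id): descending score, ties to the lower id
    order = np.lexsort((ids, -scores))[:k]
    return RetrievalResult(
        ids=[ids[i] for i in order],
        scores=[float(scores[i]) for i in order],
        k=k,
        warnings=warn or [],
    )


def bm25_rank(
    query: str,
    corpus: Sequence[DocumentChunk],
    k: int,
    k1: float = 1.5,
    b: float = 0.75,
) -> RetrievalResult:
    """Rank chunks for a query with Okapi BM25.

    score(d) = sum over query terms of
    idf(t) * tf * (k1 + 1) / (tf + k1 * (1 - b + b * len(d)/avglen)),
    with the non-negative idf form idf(t) = ln(1 + (N - df + 0.5)/(df + 0.5)).
    Ties (including the all-zero case of a query sharing no token with the
    corpus) are broken by lower chunk id.
    """
    if not corpus:
        raise ValueError("corpus is empty")
    if k <= 0:
        raise ValueError("k must be positive")
    docs = [tokenize(c.text) for c in corpus]
    n = len(docs)
    avglen = sum(len(d) for d in docs) / n
    df: dict[str, int] = {}
    for d in docs:
        for t in set(d):
            df[t] = df.get(t, 0) + 1
    scores = np.zeros(n)
    for term in tokenize(query):
        if term not in df:
            continue
        idf = math.log(1.0 + (n - df[term] + 0.5) / (df[term] + 0.5))
        for i, d in enumerate(docs):
            tf = d.count(term)
            if tf == 0:
                continue
            denom = tf + k1 * (1.0 - b + b * len(d) / avglen)
            scores[i] += idf * tf * (k1 + 1.0) / denom
    return _ranked_result(scores, [c.id for c in corpus], k)


def embedding_rank(
    query: str,
    corpus: Sequence[DocumentChunk],
    embedder: Callable[[str], np.ndarray],
    k: int,
) -> RetrievalResult:
    """Rank chunks by cosine similarity between embedded query and chunks.

    Any zero-norm vector (query or chunk) scores that chunk 0 and records a
    warning instead of dividing by zero.
    """
    if not corpus:
        raise ValueError("corpus is empty")
    if k <= 0:
        raise ValueError("k must be positive")
    warn: list[str] = []
    q = np.asarray(embedder(query), dtype=float)
    if not np.all(np.isfinite(q)):
        raise ValueError("embedder returned non-finite query vector")
    qn = np.linalg.norm(q)
    scores = np.zeros(len(corpus))
    for i, c in enumerate(corpus):
        v = np.asarray(embedder(c.text), dtype=float)
        if v.shape != q.shape:
            raise ValueError("embedder returned inconsistent dimensions")
        vn = np.linalg.norm(v)
        if qn == 0.0 or vn == 0.0:
            msg = f"zero-norm embedding for chunk {c.id}; similarity set to 0"
            warn.append(msg)
            warnings.warn(msg, stacklevel=2)
            continue
        scores[i] = float(q @ v) / (qn * vn)
    return _ranked_result(scores, [c.id for c in corpus], k, warn)


def random_rank(
    corpus: Sequence[DocumentChunk], k: int, seed: int
) -> RetrievalResult:
    """Uniform sample of k chunks without replacement; deterministic per seed."""
    if k <= 0:
        raise ValueError("k must be positive")
    if k > len(corpus):
        raise ValueError(f"k={k} exceeds corpus size {len(corpus)}")
    rng = np.random.default_rng(seed)
    picked = rng.choice(len(corpus), size=k, replace=False)
    return RetrievalResult(
        ids=[corpus[i].id for i in picked],
        scores=[0.0] * k,
        k=k,
    )
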