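"""Shared text utilities: normalization, tokenization, fuzzy similarity.

These primitives back both topic-name matching in the knowledge base and the
bag-of-words retriever, so they live in one place and stay deliberately simple:
lowercase, split on non-alphanumerics, no stemming or stop-word removal.
"""

from __future__ import annotations

import re
from difflib import SequenceMatcher

_TOKEN_RE = re.compile(r"[a-z0-9]+")


def normalize(text: str) -> str:
    """Canonical form for name comparison: lowercase tokens joined by spaces.

    Case, surrounding whitespace, and punctuation are all discarded, so
    ``" Suspected  Pulmonary Embolism. "`` and ``"Suspected Pulmonary
    Embolism"`` normalize identically.
    """
    return " ".join(_TOKEN_RE.findall(text.lower()))


def tokenize(text: str) -> list[str]:
    """Lowercase alphanumeric tokens, in order, with repeats."""
    return _TOKEN_RE.findall(text.lower())


def token_set_similarity(a: str, b: str) -> float:
    """Token-set similarity in [0, 1].

    Classic token-set ratio: compare the sorted token intersection against the
    intersection plus each side's remainder, and take the best sequence-match
    ratio of the three pairings.  Robust to word order and to one string being
    a prefix/superset of the other.
    """
    ta, tb = set(tokenize(a)), set(tokenize(b))
    if not ta or not tb:
        return 1.0 if ta == tb else 0.0
    inter = " ".join(sorted(ta & tb))
    sa = (inter + " " + " ".join(sorted(ta - tb))).strip()
    sb = (inter + " " + " ".join(sorted(tb - ta))).strip()
    pairs = [(inter, sa), (inter, sb), (sa, sb)]
    best = 0.0
    for x, y in pairs:
        if not x and not y:
            continue
        best = max(best, SequenceMatcher(None, x, y).ratio())
    return best
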