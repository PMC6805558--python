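"""The ten-feature lexical representation of a premise/hypothesis pair.

Five base similarities are computed on the preprocessed token streams:

* word overlap — overlap coefficient |A∩B| / min(|A|,|B|) on token sets;
* Dice coefficient on the sets of adjacent-token bigrams;
* cosine of the term-frequency vectors;
* Levenshtein similarity, 1 − d(a,b)/max(|a|,|b|) at character level on the
  space-joined token strings;
* Jaccard |A∩B| / |A∪B| on token sets.

These are joined by their maximum and mean, the question length ratio
|PQ| / |HQ| in tokens, the number of distinct tokens tagged noun or verb in
both questions, and the question-type agreement feature (0/1/2).

Empty-input conventions keep every feature total: an empty side scores 0
for every similarity except Levenshtein of two empty strings, which is 1
(identical strings).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, fields
from typing import Sequence

import edlib

from .preprocess import TokenizedText, bigrams
from .qtypes import qtype_match_feature

__all__ = [
    "FeatureVector",
    "FEATURE_NAMES",
    "word_overlap",
    "dice_bigram",
    "cosine_sim",
    "levenshtein_sim",
    "jaccard_sim",
    "common_noun_verb_count",
    "build_feature_vector",
]


@dataclass(frozen=True)
class FeatureVector:
    word_overlap: float
    dice_bigram: float
    cosine: float
    levenshtein: float
    jaccard: float
    max5: float
    avg5: float
    length_ratio: float
    common_nv: int
    qtype_match: int

    def as_list(self) -> list[float]:
        """Values in the fixed serialization order."""
        return [float(getattr(self, f.name)) for f in fields(self)]


FEATURE_NAMES = tuple(f.name for f in fields(FeatureVector))


def word_overlap(a: set[str], b: set[str]) -> float:
    if not a or not b:
        return 0.0
    return len(a & b) / min(len(a), len(b))


def dice_bigram(a: Sequence[tuple[str, str]], b: Sequence[tuple[str, str]]) -> float:
    sa, sb = set(a), set(b)
    if not sa and not sb:
        return 0.0
    denom = len(sa) + len(sb)
    return 2 * len(sa & sb) / denom if denom else 0.0


def cosine_sim(a: Sequence[str], b: Sequence[str]) -> float:
    if not a or not b:
        return 0.0
    ca, cb = Counter(a), Counter(b)
    if ca == cb:
        return 1.0
    dot = sum(ca[t] * cb[t] for t in ca.keys() & cb.keys())
    norm = math.sqrt(sum(v * v for v in ca.values())) * math.sqrt(
        sum(v * v for v in cb.values())
    )
    return dot / norm if norm else 0.0


def levenshtein_sim(a: str, b: str) -> float:
    if not a and not b:
        return 1.0
    if not a or not b:
        return 0.0
    dist = edlib.align(a, b, task="distance")["editDistance"]
    return 1.0 - dist / max(len(a), len(b))


def jaccard_sim(a: set[str], b: set[str]) -> float:
    union = a | b
    if not union:
        return 0.0
    return len(a & b) / len(union)


def common_noun_verb_count(a: TokenizedText, b: TokenizedText) -> int:
    """Distinct tokens tagged NOUN or VERB in both questions."""
    if a.pos is None or b.pos is None:
        raise ValueError("both inputs must carry POS tags")

    def content(t: TokenizedText) -> set[str]:
        assert t.pos is not None
        return {tok for tok, tag in zip(t.tokens, t.pos) if tag in ("NOUN", "VERB")}

    return len(content(a) & content(b))


def build_feature_vector(
    pq: TokenizedText,
    hq: TokenizedText,
    pq_types: set[str] | None = None,
    hq_types: set[str] | None = None,
) -> FeatureVector:
    """Assemble all ten features for a preprocessed, type-detected pair.

    When either side lacks POS tags the noun/verb feature falls back to 0
    rather than failing, so the vector stays usable for corpora without a
    tagging lexicon.
    """
    pa, ha = set(pq.tokens), set(hq.tokens)
    sims = [
        word_overlap(pa, ha),
        dice_bigram(bigrams(pq.tokens), bigrams(hq.tokens)),
        cosine_sim(pq.tokens, hq.tokens),
        levenshtein_sim(pq.joined(), hq.joined()),
        jaccard_sim(pa, ha),
    ]
    if pq.pos is not None and hq.pos is not None:
        common_nv = common_noun_verb_count(pq, hq)
    else:
        common_nv = 0
    return FeatureVector(
        word_overlap=sims[0],
        dice_bigram=sims[1],
        cosine=sims[2],
        levenshtein=sims[3],
        jaccard=sims[4],
        max5=max(sims),
        avg5=sum(sims) / 5.0,
        length_ratio=len(pq.tokens) / max(1, len(hq.tokens)),
        common_nv=common_nv,
        qtype_match=qtype_match_feature(pq_types or set(), hq_types or set()),
    )
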