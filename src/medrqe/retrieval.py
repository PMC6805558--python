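"""Inverted-index retrieval over the QA collection.

Only the questions are indexed, never the answers.  Each document's indexed
text is expanded at build time with the tokens of the focus synonyms and of
the question-type triggers, so a premise that says "cure" can reach a
hypothesis that says "treatments" without query-time expansion.

Two ranking models are computed from the same index:

* TF-IDF: sum over query terms of qtf · tf(t,d) · log2(N / n_t);
* In-expB2, a Divergence-From-Randomness model: for each query term,

      qtf · (F_t + 1) / (n_t · (tfn + 1)) · tfn · log2((N + 1) / (n_e + 0.5))

  with length-normalized frequency tfn = tf · log2(1 + c · avgdl / dl) and
  expected document frequency n_e = N · (1 − (1 − n_t/N)^F_t).

Their result lists are merged CombSUM-style: a document's fused score is
the sum of its scores in the two top-n lists (zero where absent), and the
fused list is reranked by that sum.  Raw scores are summed by default; an
optional min-max pre-normalization per list is available but off.
"""

from __future__ import annotations

import json
import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

from .corpus import QARecord
from .preprocess import preprocess_text
from .qtypes import Taxonomy

__all__ = [
    "InvertedIndex",
    "RetrievalResult",
    "build_index",
    "score_tfidf",
    "score_inexpb2",
    "retrieve",
    "retrieve_fused",
    "save_index",
    "load_index",
]

DEFAULT_N_CANDIDATES = 100


@dataclass
class InvertedIndex:
    postings: dict[str, list[tuple[str, int]]] = field(default_factory=dict)
    doc_lengths: dict[str, int] = field(default_factory=dict)
    c: float = 1.0  # DFR length-normalization constant

    @property
    def n_docs(self) -> int:
        return len(self.doc_lengths)

    @property
    def avgdl(self) -> float:
        if not self.doc_lengths:
            return 0.0
        return sum(self.doc_lengths.values()) / len(self.doc_lengths)

    def doc_freq(self, term: str) -> int:
        return len(self.postings.get(term, ()))

    def coll_freq(self, term: str) -> int:
        return sum(tf for _, tf in self.postings.get(term, ()))

    def term_freq(self, term: str, doc_id: str) -> int:
        for d, tf in self.postings.get(term, ()):
            if d == doc_id:
                return tf
        return 0


@dataclass(frozen=True)
class RetrievalResult:
    ranking: tuple[tuple[str, float], ...]  # (doc id, score), scores non-increasing
    model: str


def build_index(
    records: Sequence[QARecord],
    taxonomy: Taxonomy | None = None,
    stopwords: frozenset[str] | None = None,
    c: float = 1.0,
) -> InvertedIndex:
    """Index question text plus focus-synonym and type-trigger tokens."""
    index = InvertedIndex(c=c)
    for rec in records:
        doc_id = rec.question.identifier
        if doc_id in index.doc_lengths:
            raise ValueError(f"duplicate document id {doc_id!r}")
        parts = [rec.question.text]
        parts.extend(sorted(rec.question.focus_synonyms))
        if taxonomy is not None:
            for qtype in sorted(rec.question.qtypes):
                parts.extend(sorted(taxonomy.triggers.get(qtype, ())))
        tokens = preprocess_text(" . ".join(parts), stopwords).tokens
        index.doc_lengths[doc_id] = len(tokens)
        for term, tf in sorted(Counter(tokens).items()):
            index.postings.setdefault(term, []).append((doc_id, tf))
    for plist in index.postings.values():
        plist.sort(key=lambda item: item[0])
    return index


def score_tfidf(index: InvertedIndex, query: Sequence[str], doc_id: str) -> float:
    """Raw-tf × log2(N/n_t) weighting, additive over query terms."""
    if doc_id not in index.doc_lengths:
        raise KeyError(f"unknown document {doc_id!r}")
    n = index.n_docs
    score = 0.0
    for term, qtf in Counter(query).items():
        n_t = index.doc_freq(term)
        if n_t == 0:
            continue
        tf = index.term_freq(term, doc_id)
        if tf == 0:
            continue
        score += qtf * tf * math.log2(n / n_t)
    return score


def score_inexpb2(index: InvertedIndex, query: Sequence[str], doc_id: str) -> float:
    """In-expB2 DFR weighting (see module docstring for the formula)."""
    if doc_id not in index.doc_lengths:
        raise KeyError(f"unknown document {doc_id!r}")
    n = index.n_docs
    dl = index.doc_lengths[doc_id]
    avgdl = index.avgdl
    score = 0.0
    for term, qtf in Counter(query).items():
        n_t = index.doc_freq(term)
        if n_t == 0:
            continue
        tf = index.term_freq(term, doc_id)
        if tf == 0 or dl == 0:
            continue
        f_t = index.coll_freq(term)
        tfn = tf * math.log2(1.0 + index.c * avgdl / dl)
        n_e = n * (1.0 - (1.0 - n_t / n) ** f_t)
        gain = (f_t + 1.0) / (n_t * (tfn + 1.0))
        info = tfn * math.log2((n + 1.0) / (n_e + 0.5))
        score += qtf * gain * info
    return score


def _candidate_docs(index: InvertedIndex, query: Sequence[str]) -> set[str]:
    docs: set[str] = set()
    for term in set(query):
        docs.update(d for d, _ in index.postings.get(term, ()))
    return docs


def retrieve(
    index: InvertedIndex,
    query: Sequence[str],
    n: int,
    scorer: Callable[[InvertedIndex, Sequence[str], str], float],
    model: str = "",
) -> RetrievalResult:
    """Top-n documents under one scoring model; ties broken by ascending id."""
    if n < 1:
        raise ValueError("n must be >= 1")
    scored = [
        (doc, scorer(index, query, doc)) for doc in _candidate_docs(index, query)
    ]
    scored = [(d, s) for d, s in scored if s > 0.0]
    scored.sort(key=lambda item: (-item[1], item[0]))
    return RetrievalResult(ranking=tuple(scored[:n]), model=model)


def retrieve_fused(
    index: InvertedIndex,
    query: Sequence[str],
    n: int = DEFAULT_N_CANDIDATES,
    normalize: bool = False,
) -> RetrievalResult:
    """CombSUM fusion of the TF-IDF and In-expB2 top-n lists.

    With ``normalize=True`` each list is min-max scaled to [0,1] before
    summation; the default sums raw scores.
    """
    lists = [
        retrieve(index, query, n, score_tfidf, model="tfidf").ranking,
        retrieve(index, query, n, score_inexpb2, model="inexpb2").ranking,
    ]
    if normalize:
        lists = [_minmax(lst) for lst in lists]
    fused: dict[str, float] = {}
    for ranking in lists:
        for doc, score in ranking:
            fused[doc] = fused.get(doc, 0.0) + score
    merged = sorted(fused.items(), key=lambda item: (-item[1], item[0]))
    return RetrievalResult(ranking=tuple(merged[:n]), model="tfidf+inexpb2")


def _minmax(ranking: tuple[tuple[str, float], ...]) -> tuple[tuple[str, float], ...]:
    if not ranking:
        return ranking
    scores = [s for _, s in ranking]
    lo, hi = min(scores), max(scores)
    if hi == lo:
        return tuple((d, 1.0) for d, _ in ranking)
    return tuple((d, (s - lo) / (hi - lo)) for d, s in ranking)


def save_index(index: InvertedIndex, path: str | Path) -> None:
    obj = {
        "c": index.c,
        "doc_lengths": index.doc_lengths,
        "postings": {t: [[d, tf] for d, tf in pl] for t, pl in index.postings.items()},
    }
    Path(path).write_text(json.dumps(obj), "utf-8")


def load_index(path: str | Path) -> InvertedIndex:
    obj = json.loads(Path(path).read_text("utf-8"))
    return InvertedIndex(
        postings={t: [(d, int(tf)) for d, tf in pl] for t, pl in obj["postings"].items()},
        doc_lengths={d: int(v) for d, v in obj["doc_lengths"].items()},
        c=float(obj["c"]),
    )
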