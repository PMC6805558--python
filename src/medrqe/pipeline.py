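"""End-to-end entailment-based question answering.

Given a free-text premise question, the pipeline (1) retrieves the top-N
candidate questions from the expanded index with fused TF-IDF / In-expB2
scores, (2) scores each (premise, candidate) pair with the entailment
classifier and discards non-entailed candidates, (3) max-normalizes the IR
and entailment scores over the full candidate pool and reranks the
survivors by the convex combination α·norm_ir + β·norm_rqe, and (4) maps
the surviving questions to their curated answers.  When no candidate is
entailed, the system degrades to the fused IR ranking and flags the result
as a fallback, so a non-empty collection always yields an answer.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

from .classifier import RQEModel, predict
from .corpus import QARecord, Question
from .preprocess import preprocess_text
from .qtypes import Taxonomy, detect_types
from .retrieval import DEFAULT_N_CANDIDATES, InvertedIndex, retrieve_fused

__all__ = [
    "PipelineConfig",
    "CandidateQuestion",
    "AnswerResult",
    "get_candidates",
    "rerank_hybrid",
    "answer_question",
]


@dataclass(frozen=True)
class PipelineConfig:
    n_candidates: int = DEFAULT_N_CANDIDATES
    alpha: float = 0.5
    beta: float = 0.5
    rerank_weight: float = 8.9
    entailment_threshold: float = 0.5
    top_k: int = 10

    def __post_init__(self) -> None:
        if not 1 <= self.top_k <= self.n_candidates:
            raise ValueError("need n_candidates >= top_k >= 1")
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be non-negative")


@dataclass
class CandidateQuestion:
    doc_id: str
    ir_score: float
    ir_rank: int
    rqe_score: float = 0.0
    entailed: bool = False
    norm_ir: float = 0.0
    norm_rqe: float = 0.0
    hybrid_score: float = 0.0


@dataclass(frozen=True)
class RankedAnswer:
    answer: str
    source: str
    score: float
    question_id: str


@dataclass(frozen=True)
class AnswerResult:
    answers: tuple[RankedAnswer, ...]
    fallback: bool  # True when no candidate was entailed and IR order was used


def get_candidates(
    pq: Question, index: InvertedIndex, config: PipelineConfig
) -> list[CandidateQuestion]:
    """Top-N fused retrieval results for the (already preprocessed) premise."""
    result = retrieve_fused(index, pq.tokens, n=config.n_candidates)
    return [
        CandidateQuestion(doc_id=doc, ir_score=score, ir_rank=rank)
        for rank, (doc, score) in enumerate(result.ranking, start=1)
    ]


def _records_by_id(records: Sequence[QARecord]) -> dict[str, QARecord]:
    return {rec.question.identifier: rec for rec in records}


def rerank_hybrid(
    candidates: Sequence[CandidateQuestion],
    model: RQEModel,
    pq: Question,
    records: Sequence[QARecord],
    config: PipelineConfig,
) -> list[CandidateQuestion]:
    """Entailment-filter and rerank by α·norm_ir + β·norm_rqe.

    Normalization divides each score by its maximum over the full N-candidate
    pool (before filtering); an all-zero pool normalizes to zero.  Output is
    sorted by hybrid score, ties broken by ascending document id, and
    contains only entailed candidates.
    """
    by_id = _records_by_id(records)
    scored: list[CandidateQuestion] = []
    for cand in candidates:
        hq = by_id[cand.doc_id].question
        pred = predict(model, pq, hq)
        scored.append(
            replace(
                cand,
                rqe_score=pred.score,
                entailed=pred.score >= config.entailment_threshold,
            )
        )
    max_ir = max((c.ir_score for c in scored), default=0.0)
    max_rqe = max((c.rqe_score for c in scored), default=0.0)
    for cand in scored:
        cand.norm_ir = cand.ir_score / max_ir if max_ir > 0 else 0.0
        cand.norm_rqe = cand.rqe_score / max_rqe if max_rqe > 0 else 0.0
        cand.hybrid_score = config.alpha * cand.norm_ir + config.beta * cand.norm_rqe
    entailed = [c for c in scored if c.entailed]
    entailed.sort(key=lambda c: (-c.hybrid_score, c.doc_id))
    return entailed


def answer_question(
    pq_text: str,
    index: InvertedIndex,
    model: RQEModel,
    records: Sequence[QARecord],
    config: PipelineConfig | None = None,
    taxonomy: Taxonomy | None = None,
) -> AnswerResult:
    """Answer a free-text premise question with the top-k ranked answers."""
    config = config or PipelineConfig()
    taxonomy = taxonomy or model.featurizer.taxonomy
    pq = Question(identifier="PQ", text=pq_text)
    pq.tokens = preprocess_text(pq_text, model.featurizer.stopwords).tokens
    if taxonomy is not None:
        pq.qtypes = detect_types(pq_text, taxonomy)
    candidates = get_candidates(pq, index, config)
    reranked = rerank_hybrid(candidates, model, pq, records, config)
    fallback = not reranked
    if fallback:
        # nothing entailed: degrade to the fused IR order
        chosen = [(c.doc_id, c.ir_score) for c in candidates]
    else:
        chosen = [(c.doc_id, c.hybrid_score) for c in reranked]
    by_id = _records_by_id(records)
    answers = tuple(
        RankedAnswer(
            answer=by_id[doc].answer,
            source=by_id[doc].source,
            score=score,
            question_id=doc,
        )
        for doc, score in chosen[: config.top_k]
    )
    return AnswerResult(answers=answers, fallback=fallback)
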