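"""Answer-quality metrics in the TREC LiveQA style.

Human judgments grade each returned answer 1–4 (Incorrect, Incorrect but
Related, Correct but Incomplete, Correct and Complete).  The first-answer
measures are

* avgScore(0–3): mean over all questions of (grade − 1), an unanswered
  question contributing 0 — the main ranking measure;
* succ@i+: questions graded ≥ i over all questions;
* prec@i+: questions graded ≥ i over answered questions only.

The top-10 measures treat grades 3 and 4 as correct and compute mean
average precision, with per-question AvgP = (1/K)·Σ_{n=1..K} n/rank_n over
the K correct answers in the top 10, and mean reciprocal rank of the first
correct answer (0 when there is none).

Inter-annotator agreement follows the track's convention: precision is the
fraction of matching ratings, recall is fixed at 100% (there are no
negative labels), so F1 = 2P/(1+P); a partial variant collapses the grades
to Correct {3,4} vs Incorrect {1,2} first.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

__all__ = [
    "QuestionJudgment",
    "JudgedRun",
    "MetricReport",
    "avg_score",
    "succ_prec_at",
    "avgp_at10",
    "map_mrr_at10",
    "compute_report",
    "iaa_f1",
    "relative_improvement",
]

VALID_GRADES = (1, 2, 3, 4)
_CORRECT_GRADES = (3, 4)


@dataclass(frozen=True)
class QuestionJudgment:
    """Judgments for one test question.

    ``first_grade`` is the 1–4 grade of the first returned answer, or None
    when the system returned nothing; ``top10_correct`` flags each returned
    rank (up to 10) as correct (grade 3 or 4) or not.
    """

    first_grade: int | None = None
    top10_correct: tuple[bool, ...] = ()

    def __post_init__(self) -> None:
        if self.first_grade is not None and self.first_grade not in VALID_GRADES:
            raise ValueError(f"grade must be in 1..4, got {self.first_grade}")
        if len(self.top10_correct) > 10:
            raise ValueError("at most 10 per-rank flags")

    @property
    def answered(self) -> bool:
        return self.first_grade is not None


@dataclass
class JudgedRun:
    judgments: list[QuestionJudgment] = field(default_factory=list)

    @classmethod
    def from_grades(
        cls, grades: Sequence[int | None], top10: Sequence[Sequence[bool]] | None = None
    ) -> "JudgedRun":
        top10 = top10 or [[] for _ in grades]
        return cls(
            judgments=[
                QuestionJudgment(first_grade=g, top10_correct=tuple(f))
                for g, f in zip(grades, top10, strict=True)
            ]
        )


@dataclass(frozen=True)
class MetricReport:
    avg_score: float
    succ: dict[int, float]
    prec: dict[int, float]
    map10: float
    mrr10: float


def avg_score(run: JudgedRun) -> float:
    """Mean (grade − 1) over all questions, unanswered counting 0."""
    if not run.judgments:
        raise ValueError("empty run")
    total = sum(j.first_grade - 1 for j in run.judgments if j.answered)
    return total / len(run.judgments)


def succ_prec_at(run: JudgedRun, i: int) -> tuple[float, float]:
    """(succ@i+, prec@i+) for a grade cutoff i in {2,3,4}."""
    if i not in (2, 3, 4):
        raise ValueError(f"cutoff must be 2, 3 or 4, got {i}")
    if not run.judgments:
        raise ValueError("empty run")
    answered = [j for j in run.judgments if j.answered]
    if not answered:
        raise ValueError("prec@i+ undefined: no answered questions")
    hits = sum(1 for j in answered if j.first_grade >= i)
    return hits / len(run.judgments), hits / len(answered)


def avgp_at10(flags: Sequence[bool]) -> float:
    """Average precision of one top-10 list: (1/K)·Σ n/rank_n; 0 if K=0."""
    if len(flags) > 10:
        raise ValueError("at most 10 per-rank flags")
    correct_ranks = [rank for rank, ok in enumerate(flags, start=1) if ok]
    k = len(correct_ranks)
    if k == 0:
        return 0.0
    return sum(n / rank for n, rank in enumerate(correct_ranks, start=1)) / k


def map_mrr_at10(run: JudgedRun) -> tuple[float, float]:
    """(MAP@10, MRR@10) over the run; a question with no correct answer
    contributes 0 to both means."""
    if not run.judgments:
        raise ValueError("empty run")
    aps, rrs = [], []
    for j in run.judgments:
        aps.append(avgp_at10(j.top10_correct))
        first = next(
            (rank for rank, ok in enumerate(j.top10_correct, start=1) if ok), None
        )
        rrs.append(1.0 / first if first else 0.0)
    return sum(aps) / len(aps), sum(rrs) / len(rrs)


def compute_report(run: JudgedRun) -> MetricReport:
    map10, mrr10 = map_mrr_at10(run)
    succ, prec = {}, {}
    for i in (2, 3, 4):
        succ[i], prec[i] = succ_prec_at(run, i)
    return MetricReport(
        avg_score=avg_score(run), succ=succ, prec=prec, map10=map10, mrr10=mrr10
    )


def iaa_f1(
    reference: Sequence[int], other: Sequence[int], partial: bool = False
) -> tuple[float, float]:
    """(precision, F1) agreement between two assessors' grade sequences.

    With ``partial=True`` grades are collapsed to Correct {3,4} vs
    Incorrect {1,2} before comparison.  Recall is fixed at 1, so
    F1 = 2P/(1+P).
    """
    if len(reference) != len(other):
        raise ValueError("grade sequences must have equal length")
    if not reference:
        raise ValueError("empty grade sequences")

    def norm(g: int) -> int:
        if g not in VALID_GRADES:
            raise ValueError(f"grade must be in 1..4, got {g}")
        return int(g in _CORRECT_GRADES) if partial else g

    matches = sum(norm(a) == norm(b) for a, b in zip(reference, other))
    precision = matches / len(reference)
    return precision, 2 * precision / (1 + precision)


def relative_improvement(new: float, baseline: float) -> float:
    """Percentage improvement of ``new`` over ``baseline``."""
    if baseline <= 0:
        raise ValueError("baseline must be positive")
    return 100.0 * (new - baseline) / baseline
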