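"""Logistic-regression question-entailment classifier.

A question pair is represented by the ten lexical features of
:mod:`medrqe.features` and classified as entailment / no-entailment by an
L2-regularized logistic regression.  The positive-class probability serves
as the entailment score downstream: it is bounded in [0,1], which is what
the QA pipeline's max-normalization assumes.

Also provides the rank-fusion score used for similar-question reranking on
community-QA data: ``lr_score + w / ir_rank`` with the empirical weight
w = 8.9.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression

from .corpus import Question, RQEPair
from .features import FEATURE_NAMES, build_feature_vector
from .preprocess import preprocess_text
from .qtypes import Taxonomy, detect_types

__all__ = [
    "RQEModel",
    "Prediction",
    "PairFeaturizer",
    "train_lr",
    "predict",
    "evaluate_accuracy",
    "similarity_rerank_score",
    "save_model",
    "load_model",
]

DEFAULT_RERANK_WEIGHT = 8.9

_MODEL_FORMAT_VERSION = 1


@dataclass(frozen=True)
class Prediction:
    score: float  # positive-class probability
    label: int


class PairFeaturizer:
    """Preprocess + type-detect both questions and build the feature vector.

    The same featurizer instance is shared between training and prediction
    so the preprocessing configuration cannot drift.
    """

    def __init__(
        self,
        taxonomy: Taxonomy | None = None,
        stopwords: frozenset[str] | None = None,
        pos_lexicon: dict[str, str] | None = None,
    ) -> None:
        self.taxonomy = taxonomy
        self.stopwords = stopwords
        self.pos_lexicon = pos_lexicon or {}

    def _prepare(self, q: Question):
        tt = preprocess_text(q.text, self.stopwords)
        if self.pos_lexicon:
            tt.pos = [self.pos_lexicon.get(t, "OTHER") for t in tt.tokens]
        if q.qtypes:
            types = set(q.qtypes)
        elif self.taxonomy is not None:
            types = detect_types(q.text, self.taxonomy)
        else:
            types = set()
        return tt, types

    def features(self, pq: Question, hq: Question) -> list[float]:
        ptt, ptypes = self._prepare(pq)
        htt, htypes = self._prepare(hq)
        return build_feature_vector(ptt, htt, ptypes, htypes).as_list()

    def matrix(self, pairs: Sequence[RQEPair]) -> np.ndarray:
        return np.array(
            [self.features(p.premise, p.hypothesis) for p in pairs], dtype=float
        )


@dataclass
class RQEModel:
    weights: np.ndarray  # shape (10,)
    intercept: float
    featurizer: PairFeaturizer
    seed: int
    threshold: float = 0.5

    def score(self, pq: Question, hq: Question) -> float:
        x = np.asarray(self.featurizer.features(pq, hq))
        z = float(x @ self.weights + self.intercept)
        return float(1.0 / (1.0 + np.exp(-z)))


def train_lr(
    pairs: Sequence[RQEPair],
    seed: int,
    featurizer: PairFeaturizer | None = None,
    C: float = 1.0,
    tol: float = 1e-6,
    max_iter: int = 1000,
) -> RQEModel:
    """Fit the entailment classifier; deterministic under the seed.

    Raises on single-class data; logs a warning but still returns the model
    when the optimizer stops before reaching the tolerance.
    """
    labels = {p.label for p in pairs}
    if labels != {0, 1}:
        raise ValueError(f"training data must contain both classes, got labels {labels}")
    featurizer = featurizer or PairFeaturizer()
    X = featurizer.matrix(pairs)
    y = np.array([p.label for p in pairs])
    # lbfgs with default L2 penalty; strength set through C
    clf = LogisticRegression(
        C=C, tol=tol, max_iter=max_iter, solver="lbfgs", random_state=seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("always", ConvergenceWarning)
        clf.fit(X, y)
    return RQEModel(
        weights=clf.coef_[0].copy(),
        intercept=float(clf.intercept_[0]),
        featurizer=featurizer,
        seed=seed,
    )


def predict(model: RQEModel, pq: Question, hq: Question) -> Prediction:
    score = model.score(pq, hq)
    return Prediction(score=score, label=int(score >= model.threshold))


def evaluate_accuracy(model: RQEModel, pairs: Sequence[RQEPair]) -> float:
    """Percentage of pairs classified correctly."""
    if not pairs:
        raise ValueError("cannot evaluate on an empty pair set")
    correct = sum(
        predict(model, p.premise, p.hypothesis).label == p.label for p in pairs
    )
    return 100.0 * correct / len(pairs)


def similarity_rerank_score(
    lr_score: float, ir_rank: int, w: float = DEFAULT_RERANK_WEIGHT
) -> float:
    """Hybrid similar-question score: ``lr_score + w / ir_rank``."""
    if ir_rank < 1:
        raise ValueError(f"ir_rank must be >= 1, got {ir_rank}")
    return lr_score + w / ir_rank


def save_model(model: RQEModel, path: str | Path) -> None:
    obj = {
        "format_version": _MODEL_FORMAT_VERSION,
        "feature_names": list(FEATURE_NAMES),
        "weights": [float(v) for v in model.weights],
        "intercept": model.intercept,
        "threshold": model.threshold,
        "seed": model.seed,
    }
    Path(path).write_text(json.dumps(obj, indent=1), "utf-8")


def load_model(path: str | Path, featurizer: PairFeaturizer | None = None) -> RQEModel:
    obj = json.loads(Path(path).read_text("utf-8"))
    if obj.get("format_version") != _MODEL_FORMAT_VERSION:
        raise ValueError(f"{path}: unsupported model format {obj.get('format_version')}")
    if obj.get("feature_names") != list(FEATURE_NAMES):
        raise ValueError(f"{path}: feature layout does not match this package version")
    return RQEModel(
        weights=np.asarray(obj["weights"], dtype=float),
        intercept=float(obj["intercept"]),
        featurizer=featurizer or PairFeaturizer(),
        seed=int(obj["seed"]),
        threshold=float(obj.get("threshold", 0.5)),
    )
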