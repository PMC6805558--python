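"""Domain types and I/O for QA collections and question-pair datasets.

A QA collection is a sequence of question–answer records, each carrying the
question text, its curated answer, the source it was harvested from, the
question focus (the main topic entity) with its synonyms, the question
type(s), and optional controlled-vocabulary annotations (concept identifier,
semantic type, semantic group) that are carried as metadata only.

Two on-disk dialects are supported: a tolerant XML reader for
MedQuAD-style documents, and a canonical JSONL dialect (one flat record
per line) used everywhere else.  Question-pair datasets for entailment
training are plain TSV: ``premise<TAB>hypothesis<TAB>label``.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from lxml import etree

__all__ = [
    "Question",
    "QARecord",
    "RQEPair",
    "DatasetSplit",
    "CorpusError",
    "read_medquad_xml",
    "read_jsonl",
    "write_jsonl",
    "read_pair_tsv",
    "write_pair_tsv",
    "split_dataset",
    "collection_stats",
]


class CorpusError(ValueError):
    """Malformed collection or pair file."""


@dataclass
class Question:
    identifier: str
    text: str
    tokens: list[str] = field(default_factory=list)
    qtypes: set[str] = field(default_factory=set)
    focus: str | None = None
    focus_synonyms: set[str] = field(default_factory=set)


@dataclass
class QARecord:
    question: Question
    answer: str
    source: str = ""
    cui: str | None = None
    semantic_type: str | None = None
    semantic_group: str | None = None


@dataclass(frozen=True)
class RQEPair:
    """A labeled premise/hypothesis question pair; label 1 means the premise
    entails the hypothesis (every answer to the hypothesis at least partially
    answers the premise)."""

    premise: Question
    hypothesis: Question
    label: int

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label!r}")


@dataclass
class DatasetSplit:
    train: list[RQEPair]
    dev: list[RQEPair]
    test: list[RQEPair]
    seed: int


# --------------------------------------------------------------------------
# XML dialect
#
#   <Document id="..." source="...">
#     <Focus>...</Focus>
#     <FocusAnnotations>
#       <CUI>...</CUI> <SemanticType>...</SemanticType>
#       <SemanticGroup>...</SemanticGroup>
#       <Synonyms><Synonym>...</Synonym>...</Synonyms>
#     </FocusAnnotations>
#     <QAPairs>
#       <QAPair><Question qid="..." qtype="...">...</Question>
#               <Answer>...</Answer></QAPair>
#     </QAPairs>
#   </Document>
#
# Elements are matched case-insensitively and unknown elements are ignored;
# a file may hold one Document or a list of Documents under any root.
# --------------------------------------------------------------------------


def _localname(el: etree._Element) -> str:
    return etree.QName(el).localname.lower() if isinstance(el.tag, str) else ""


def _find(el: etree._Element, name: str) -> etree._Element | None:
    for child in el:
        if _localname(child) == name:
            return child
    return None


def _findall(el: etree._Element, name: str) -> list[etree._Element]:
    return [c for c in el.iter() if _localname(c) == name]


def _text(el: etree._Element | None) -> str:
    return "".join(el.itertext()).strip() if el is not None else ""


def read_medquad_xml(path: str | Path) -> list[QARecord]:
    """Parse a MedQuAD-style XML file into records, order preserved."""
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise CorpusError(f"{path}: malformed XML: {exc}") from exc
    root = tree.getroot()
    documents = [root] if _localname(root) == "document" else _findall(root, "document")
    records: list[QARecord] = []
    for doc in documents:
        doc_id = doc.get("id") or doc.get("ID") or f"doc{len(records)}"
        source = doc.get("source") or doc.get("Source") or ""
        focus = _text(_find(doc, "focus")) or None
        cui = semtype = semgroup = None
        synonyms: set[str] = set()
        ann = _find(doc, "focusannotations")
        if ann is not None:
            cui = _text(_find(ann, "cui")) or None
            semtype = _text(_find(ann, "semantictype")) or None
            semgroup = _text(_find(ann, "semanticgroup")) or None
        for syn in _findall(doc, "synonym"):
            if _text(syn):
                synonyms.add(_text(syn))
        pairs = _findall(doc, "qapair")
        for i, pair in enumerate(pairs):
            q_el = _find(pair, "question")
            a_el = _find(pair, "answer")
            if q_el is None:
                raise CorpusError(f"{path}: QAPair without a Question element")
            if a_el is None or not _text(a_el):
                raise CorpusError(f"{path}: QAPair without an Answer element")
            qid = q_el.get("qid") or f"{doc_id}-{i + 1}"
            qtype = q_el.get("qtype")
            question = Question(
                identifier=qid,
                text=_text(q_el),
                qtypes={qtype} if qtype else set(),
                focus=focus,
                focus_synonyms=set(synonyms),
            )
            records.append(
                QARecord(
                    question=question,
                    answer=_text(a_el),
                    source=source,
                    cui=cui,
                    semantic_type=semtype,
                    semantic_group=semgroup,
                )
            )
    return records


# --------------------------------------------------------------------------
# JSONL dialect: one flat object per line with keys
#   id, question, answer, source, focus, focus_synonyms, qtypes,
#   cui, semantic_type, semantic_group
# --------------------------------------------------------------------------


def write_jsonl(records: Iterable[QARecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            obj = {
                "id": rec.question.identifier,
                "question": rec.question.text,
                "answer": rec.answer,
                "source": rec.source,
                "focus": rec.question.focus,
                "focus_synonyms": sorted(rec.question.focus_synonyms),
                "qtypes": sorted(rec.question.qtypes),
                "cui": rec.cui,
                "semantic_type": rec.semantic_type,
                "semantic_group": rec.semantic_group,
            }
            fh.write(json.dumps(obj, ensure_ascii=False) + "\n")


def read_jsonl(path: str | Path) -> list[QARecord]:
    records: list[QARecord] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusError(f"{path}:{lineno}: invalid JSON: {exc}") from exc
            for key in ("id", "question", "answer"):
                if key not in obj:
                    raise CorpusError(f"{path}:{lineno}: missing field '{key}'")
            question = Question(
                identifier=str(obj["id"]),
                text=obj["question"],
                qtypes=set(obj.get("qtypes") or []),
                focus=obj.get("focus"),
                focus_synonyms=set(obj.get("focus_synonyms") or []),
            )
            records.append(
                QARecord(
                    question=question,
                    answer=obj["answer"],
                    source=obj.get("source", ""),
                    cui=obj.get("cui"),
                    semantic_type=obj.get("semantic_type"),
                    semantic_group=obj.get("semantic_group"),
                )
            )
    return records


# --------------------------------------------------------------------------
# Pair TSV
# --------------------------------------------------------------------------

_POSITIVE_LABELS = {"1", "entailment", "entails", "true", "yes", "positive"}
_NEGATIVE_LABELS = {
    "0", "no-entailment", "non-entailment", "neutral", "contradiction",
    "false", "no", "negative",
}


def read_pair_tsv(path: str | Path) -> list[RQEPair]:
    """Read ``premise<TAB>hypothesis<TAB>label`` lines.

    Multi-class inference labels are binarized on read: ``entailment`` maps
    to 1, everything else recognized (neutral, contradiction, ...) to 0.
    """
    pairs: list[RQEPair] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 3:
                raise CorpusError(
                    f"{path}:{lineno}: expected 3 tab-separated columns, got {len(parts)}"
                )
            premise, hypothesis, label_token = parts
            token = label_token.strip().lower()
            if token in _POSITIVE_LABELS:
                label = 1
            elif token in _NEGATIVE_LABELS:
                label = 0
            else:
                raise CorpusError(f"{path}:{lineno}: unknown label {label_token!r}")
            pairs.append(
                RQEPair(
                    premise=Question(identifier=f"p{lineno}", text=premise),
                    hypothesis=Question(identifier=f"h{lineno}", text=hypothesis),
                    label=label,
                )
            )
    return pairs


def write_pair_tsv(pairs: Iterable[RQEPair], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for pair in pairs:
            fh.write(f"{pair.premise.text}\t{pair.hypothesis.text}\t{pair.label}\n")


def split_dataset(pairs: Sequence[RQEPair], seed: int) -> DatasetSplit:
    """Shuffle and split 80/10/10.

    Dev and test each get round(0.1·n) pairs (half-up rounding), train the
    remainder; the same seed always yields the same partition.
    """
    n = len(pairs)
    if n < 3:
        raise CorpusError(f"need at least 3 pairs to split, got {n}")
    n_eval = int(0.1 * n + 0.5)  # half-up
    shuffled = list(pairs)
    random.Random(seed).shuffle(shuffled)
    dev = shuffled[:n_eval]
    test = shuffled[n_eval : 2 * n_eval]
    train = shuffled[2 * n_eval :]
    return DatasetSplit(train=train, dev=dev, test=test, seed=seed)


def collection_stats(records: Sequence[QARecord]) -> dict[str, int]:
    """Per-source pair counts plus a ``total`` entry."""
    counts: dict[str, int] = {}
    for rec in records:
        counts[rec.source] = counts.get(rec.source, 0) + 1
    counts["total"] = len(records)
    return counts
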