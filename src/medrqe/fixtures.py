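"""Seeded synthetic QA fixtures.

Real consumer-health QA data cannot be bundled, so this module generates
collections with the same statistical structure the method assumes: topics
(a focus with synonyms), type-templated questions instantiated from the
taxonomy's printed patterns, consumer-style premise variants (focus-synonym
substitution, trigger substitution, a prefixed context sentence, keyboard
typos), and labeled entailment pairs built by the same rule used to
construct the CHQ-FAQ test set — a pair is positive exactly when premise
and hypothesis share the focus and at least one question type, and negative
on a focus or type mismatch.

Focus names are drawn from a packaged list of pronounceable nonsense nouns
rather than real disease names, so no test can accidentally depend on a
real-world lexicon.  All generation is deterministic under the spec seed.
"""

from __future__ import annotations

import random
import zlib
from dataclasses import dataclass
from importlib import resources

from .corpus import QARecord, Question, RQEPair
from .preprocess import tokenize
from .qtypes import INFORMATION, Taxonomy
from .stemming import porter_stem

__all__ = [
    "FixtureSpec",
    "generate_collection",
    "generate_premise_variants",
    "generate_rqe_pairs",
    "fixture_pos_lexicon",
]


@dataclass(frozen=True)
class FixtureSpec:
    n_topics: int = 30
    types_per_topic: int = 4
    synonyms_per_topic: int = 3
    typo_rate: float = 0.05
    context_sentence_rate: float = 0.5
    positive_ratio: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("typo_rate", "context_sentence_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if not 0.0 < self.positive_ratio < 1.0:
            raise ValueError("positive_ratio must be in (0,1)")


# Question patterns per type; FOCUS is replaced by the topic name and
# TRIGGER, where present, by one of the type's trigger phrases.
_TEMPLATES = {
    "Treatment": "What are the treatments for FOCUS?",
    "Prognosis": "What is the outlook for FOCUS?",
    "Frequency": "How many people are affected by FOCUS?",
    "Research": "What research (or clinical trial) is being done for FOCUS?",
    "Contact a medical professional": "When to contact a medical professional about FOCUS?",
    "Susceptibility": "Who is at risk for FOCUS?",
    "Support Groups": "Where to find support for people with FOCUS?",
    "Causes": "What causes FOCUS?",
    "Symptoms": "What are the symptoms of FOCUS?",
    "Prevention": "How to prevent FOCUS?",
    "Diagnosis": "What exams and tests diagnose FOCUS?",
    "Complications": "What are the possible problems linked to FOCUS?",
    "Inheritance": "Is FOCUS inherited?",
    "Genetic changes": "What are the genetic changes related to FOCUS?",
    "Considerations": "What considerations should I know about FOCUS?",
    INFORMATION: "What is FOCUS?",
}

# Consumer-style framing sentences; deliberately free of trigger phrases.
_CONTEXT_SENTENCES = (
    "My mother was told she has FOCUS last month and we are very worried.",
    "I have been reading about FOCUS for weeks without finding a clear answer.",
    "My son will be tested for FOCUS soon and I want to understand it better.",
    "We live far from any large hospital and I am trying to help my father with FOCUS.",
    "A friend of the family mentioned FOCUS and now I cannot stop thinking about it.",
)

_QWERTY_NEIGHBORS = {
    "a": "sq", "b": "vn", "c": "xv", "d": "sf", "e": "wr", "f": "dg",
    "g": "fh", "h": "gj", "i": "uo", "j": "hk", "k": "jl", "l": "k",
    "m": "n", "n": "bm", "o": "ip", "p": "o", "q": "wa", "r": "et",
    "s": "ad", "t": "ry", "u": "yi", "v": "cb", "w": "qe", "x": "zc",
    "y": "tu", "z": "x",
}


def _focus_nouns() -> list[str]:
    text = resources.files("medrqe").joinpath("data", "focus_nouns.txt").read_text("utf-8")
    return [w.strip() for w in text.splitlines() if w.strip()]


def _record_rng(spec: FixtureSpec, record_id: str) -> random.Random:
    # stable per-record stream, independent of generation order
    return random.Random((spec.seed << 32) ^ zlib.crc32(record_id.encode()))


def _template_for(qtype: str, taxonomy: Taxonomy) -> str:
    if qtype in _TEMPLATES:
        return _TEMPLATES[qtype]
    triggers = sorted(taxonomy.triggers.get(qtype, ()))
    trigger = triggers[0] if triggers else qtype.lower()
    return f"What about the {trigger} of FOCUS?"


def generate_collection(spec: FixtureSpec, taxonomy: Taxonomy) -> list[QARecord]:
    """One record per (topic, sampled type); answers encode their gold key."""
    rng = random.Random(spec.seed)
    nouns = _focus_nouns()
    rng.shuffle(nouns)
    needed = spec.n_topics * (1 + spec.synonyms_per_topic)
    if needed > len(nouns):
        raise ValueError(
            f"spec needs {needed} distinct focus nouns, packaged list has {len(nouns)}"
        )
    type_pool = list(taxonomy.group_types("disease"))
    records: list[QARecord] = []
    for i in range(spec.n_topics):
        base = i * (1 + spec.synonyms_per_topic)
        focus = nouns[base]
        synonyms = set(nouns[base + 1 : base + 1 + spec.synonyms_per_topic])
        qtypes = rng.sample(type_pool, min(spec.types_per_topic, len(type_pool)))
        for qtype in qtypes:
            text = _template_for(qtype, taxonomy).replace("FOCUS", focus)
            qid = f"t{i:03d}-{qtype.lower().replace(' ', '-')}"
            question = Question(
                identifier=qid,
                text=text,
                qtypes={qtype},
                focus=focus,
                focus_synonyms=set(synonyms),
            )
            records.append(
                QARecord(
                    question=question,
                    answer=f"Curated answer about the {qtype.lower()} of {focus}. [{focus}|{qtype}]",
                    source="synthetic",
                )
            )
    return records


def _inject_typos(text: str, rate: float, rng: random.Random) -> str:
    """Adjacent-key substitution, at most one character per affected token."""
    if rate <= 0:
        return text
    out_words = []
    for word in text.split(" "):
        letters = [i for i, ch in enumerate(word) if ch.lower() in _QWERTY_NEIGHBORS]
        if letters and rng.random() < rate:
            i = rng.choice(letters)
            repl = rng.choice(_QWERTY_NEIGHBORS[word[i].lower()])
            word = word[:i] + repl + word[i + 1 :]
        out_words.append(word)
    return " ".join(out_words)


def generate_premise_variants(
    record: QARecord,
    spec: FixtureSpec,
    taxonomy: Taxonomy,
    substitute_focus: bool = True,
    substitute_trigger: bool = True,
) -> list[tuple[str, str]]:
    """Consumer-style rewrites of a collection question.

    One variant per (focus term, type trigger) combination: the focus is
    replaced by each of its synonyms (and kept once), the type's template
    trigger by each of the type's trigger phrases; each variant then gets a
    context-sentence prefix with probability ``context_sentence_rate`` and
    keyboard typos at ``typo_rate``.  The first variant of a record with
    zero rates and no listed synonyms is the original question verbatim.
    Returns (premise text, gold record id) tuples.
    """
    rng = _record_rng(spec, record.question.identifier)
    focus = record.question.focus or ""
    qtype = next(iter(record.question.qtypes))
    template = _template_for(qtype, taxonomy)
    template_trigger = None
    for trig in sorted(taxonomy.triggers.get(qtype, ()), key=len, reverse=True):
        if trig in template.lower():
            template_trigger = trig
            break
    focus_terms = [focus]
    if substitute_focus:
        focus_terms += sorted(record.question.focus_synonyms)
    triggers = [template_trigger] if template_trigger else [None]
    if substitute_trigger:
        for trig in sorted(taxonomy.triggers.get(qtype, ())):
            if template_trigger and trig != template_trigger:
                triggers.append(trig)
    variants: list[tuple[str, str]] = []
    for focus_term in focus_terms:
        for trig in triggers:
            text = template
            if trig and template_trigger and trig != template_trigger:
                idx = text.lower().index(template_trigger)
                text = text[:idx] + trig + text[idx + len(template_trigger) :]
            text = text.replace("FOCUS", focus_term)
            if rng.random() < spec.context_sentence_rate:
                prefix = rng.choice(_CONTEXT_SENTENCES).replace("FOCUS", focus_term)
                text = f"{prefix} {text}"
            text = _inject_typos(text, spec.typo_rate, rng)
            variants.append((text, record.question.identifier))
    return variants


def generate_rqe_pairs(
    records: list[QARecord],
    spec: FixtureSpec,
    taxonomy: Taxonomy,
    n_pairs: int | None = None,
) -> list[RQEPair]:
    """Labeled entailment pairs built by the focus/type construction rule.

    Positives pair a premise variant with its own source question (same
    focus, same type).  Negatives pair a variant with a question that
    mismatches on focus (same type, different topic) or on type (same topic,
    different type), split evenly between the two mismatch categories.

    Premise variants used here retain the topic's canonical focus term and
    trigger phrase (context sentences and typos still apply): the
    entailment features are purely lexical, so a synonym- or
    trigger-substituted premise would be indistinguishable from a mismatch.
    Substitution is exercised by the retrieval fixtures instead, where the
    expanded index resolves it.
    """
    foci = {rec.question.focus for rec in records}
    all_types = {t for rec in records for t in rec.question.qtypes}
    if len(foci) < 2 or len(all_types) < 2:
        raise ValueError("need at least 2 topics and 2 question types")
    if n_pairs is None:
        n_pairs = 2 * len(records)
    n_pos = round(n_pairs * spec.positive_ratio)
    n_neg = n_pairs - n_pos
    if n_pos < 1 or n_neg < 1:
        raise ValueError(f"cannot realize balance {spec.positive_ratio} at n={n_pairs}")
    rng = random.Random(spec.seed + 1)

    by_type: dict[str, list[QARecord]] = {}
    by_focus: dict[str, list[QARecord]] = {}
    for rec in records:
        by_focus.setdefault(rec.question.focus or "", []).append(rec)
        for t in rec.question.qtypes:
            by_type.setdefault(t, []).append(rec)

    def variant_of(rec: QARecord) -> str:
        text = rec.question.text
        if rng.random() < spec.context_sentence_rate:
            prefix = rng.choice(_CONTEXT_SENTENCES).replace(
                "FOCUS", rec.question.focus or ""
            )
            text = f"{prefix} {text}"
        return _inject_typos(text, spec.typo_rate, rng)

    def premise_q(rec: QARecord, text: str, n: int) -> Question:
        return Question(
            identifier=f"chq-{n}",
            text=text,
            qtypes=set(rec.question.qtypes),
            focus=rec.question.focus,
            focus_synonyms=set(rec.question.focus_synonyms),
        )

    pairs: list[RQEPair] = []
    for k in range(n_pos):
        rec = rng.choice(records)
        pairs.append(
            RQEPair(
                premise=premise_q(rec, variant_of(rec), k),
                hypothesis=rec.question,
                label=1,
            )
        )
    for k in range(n_neg):
        rec = rng.choice(records)
        qtype = next(iter(rec.question.qtypes))
        if k % 2 == 0:
            # focus mismatch: same type, different topic
            others = [
                r for r in by_type.get(qtype, []) if r.question.focus != rec.question.focus
            ]
        else:
            # type mismatch: same topic, disjoint type set
            others = [
                r
                for r in by_focus.get(rec.question.focus or "", [])
                if not (r.question.qtypes & rec.question.qtypes)
            ]
        if not others:
            others = [r for r in records if r.question.focus != rec.question.focus]
        hyp = rng.choice(others)
        pairs.append(
            RQEPair(
                premise=premise_q(rec, variant_of(rec), n_pos + k),
                hypothesis=hyp.question,
                label=0,
            )
        )
    rng.shuffle(pairs)
    return pairs


_VERB_TRIGGERS = (
    "relieve", "manage", "cure", "prevent", "diagnose", "treat", "affect",
    "find", "contact", "inherit", "cause",
)


def fixture_pos_lexicon(
    taxonomy: Taxonomy, records: list[QARecord]
) -> dict[str, str]:
    """A stem-keyed POS lexicon for the fixture vocabulary.

    Focus terms and their synonyms are nouns; trigger verbs are verbs;
    remaining trigger words are nouns.  Keys are Porter stems because the
    tagger runs on preprocessed tokens.
    """
    lexicon: dict[str, str] = {}
    for phrases in taxonomy.triggers.values():
        for phrase in phrases:
            for tok in tokenize(phrase):
                lexicon.setdefault(porter_stem(tok), "NOUN")
    for verb in _VERB_TRIGGERS:
        lexicon[porter_stem(verb)] = "VERB"
    for rec in records:
        for term in [rec.question.focus or ""] + sorted(rec.question.focus_synonyms):
            for tok in tokenize(term):
                lexicon[porter_stem(tok)] = "NOUN"
    return lexicon
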