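"""Question-type taxonomy and trigger-based type detection.

Consumer-health questions fall into a small taxonomy of information needs:
16 types for questions about diseases (Treatment, Prognosis, Symptoms, ...),
20 types for questions about drugs (Side effects, Dose, Usage, ...) and one
catch-all type, Information, for other medical entities such as procedures
and tests.  Information also serves as the generic "What is X?" type for
diseases, so it is a member of both the disease and the other group.

Each type carries a set of trigger phrases ("prognosis", "life expectancy",
...).  Detection is a dictionary lookup: a type is assigned when one of its
triggers occurs in the question, matched case-insensitively as a whole
phrase on the raw text, with a stemmed-token fallback so that surface
variants ("treatments") still hit their trigger ("treatment").
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from .preprocess import preprocess_text

__all__ = [
    "Taxonomy",
    "load_taxonomy",
    "load_default_taxonomy",
    "detect_types",
    "qtype_match_feature",
    "INFORMATION",
]

INFORMATION = "Information"

_WHAT_IS_RE = re.compile(r"^\s*what\s+(is|are)\b", re.IGNORECASE)


@dataclass(frozen=True)
class Taxonomy:
    """Type names grouped into disease/drug/other, with trigger phrases."""

    groups: dict[str, tuple[str, ...]]  # group name -> ordered type names
    triggers: dict[str, frozenset[str]]  # type name -> lowercase trigger phrases

    @property
    def types(self) -> frozenset[str]:
        return frozenset(t for names in self.groups.values() for t in names)

    def group_types(self, group: str) -> tuple[str, ...]:
        """Type names of a group; Information counts in disease and other."""
        names = self.groups.get(group, ())
        if group == "disease" and INFORMATION not in names:
            names = names + (INFORMATION,)
        return names

    def with_trigger(self, type_name: str, trigger: str) -> "Taxonomy":
        """A copy with one extra trigger phrase for an existing type."""
        if type_name not in self.types:
            raise KeyError(type_name)
        triggers = dict(self.triggers)
        triggers[type_name] = triggers[type_name] | {trigger.lower()}
        return Taxonomy(groups=self.groups, triggers=triggers)


def _parse_taxonomy(text: str, origin: str) -> Taxonomy:
    groups: dict[str, list[str]] = {}
    triggers: dict[str, frozenset[str]] = {}
    for lineno, line in enumerate(text.splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) not in (2, 3):
            raise ValueError(
                f"{origin}:{lineno}: expected 'group<TAB>type[<TAB>triggers]'"
            )
        group, name = parts[0].strip(), parts[1].strip()
        phrases = parts[2] if len(parts) == 3 else ""
        if not group or not name:
            raise ValueError(f"{origin}:{lineno}: empty group or type name")
        groups.setdefault(group, []).append(name)
        triggers[name] = frozenset(
            p.strip().lower() for p in phrases.split(",") if p.strip()
        )
    return Taxonomy(
        groups={g: tuple(names) for g, names in groups.items()},
        triggers=triggers,
    )


def load_taxonomy(path: str | Path) -> Taxonomy:
    """Read a taxonomy file: ``group<TAB>type<TAB>comma-separated triggers``."""
    return _parse_taxonomy(Path(path).read_text("utf-8"), str(path))


def load_default_taxonomy() -> Taxonomy:
    """The packaged default taxonomy (16 disease / 20 drug / 1 other type)."""
    text = resources.files("medrqe").joinpath("data", "taxonomy.tsv").read_text("utf-8")
    tax = _parse_taxonomy(text, "taxonomy.tsv")
    n_disease = len(tax.group_types("disease"))
    n_drug = len(tax.group_types("drug"))
    if n_disease != 16 or n_drug != 20 or INFORMATION not in tax.group_types("other"):
        raise ValueError(
            f"corrupt packaged taxonomy: {n_disease} disease / {n_drug} drug types"
        )
    return tax


def _phrase_in_text(phrase: str, text_lower: str) -> bool:
    return re.search(rf"(?<![a-z0-9]){re.escape(phrase)}(?![a-z0-9])", text_lower) is not None


def detect_types(text: str, taxonomy: Taxonomy) -> set[str]:
    """All question types whose triggers occur in the text.

    Raw-text matching is whole-phrase and case-insensitive; a stemmed
    fallback compares the trigger's stemmed tokens against the question's
    stemmed tokens as a contiguous subsequence.  When nothing matches and
    the question opens with "what is/are", the catch-all Information type
    is returned.
    """
    text_lower = text.lower()
    stems = preprocess_text(text, stopwords=()).tokens
    found: set[str] = set()
    for type_name, phrases in taxonomy.triggers.items():
        for phrase in phrases:
            if _phrase_in_text(phrase, text_lower):
                found.add(type_name)
                break
            phrase_stems = preprocess_text(phrase, stopwords=()).tokens
            if phrase_stems and _contains_run(stems, phrase_stems):
                found.add(type_name)
                break
    if not found and INFORMATION in taxonomy.types and _WHAT_IS_RE.match(text):
        found.add(INFORMATION)
    return found


def _contains_run(tokens: list[str], run: list[str]) -> bool:
    n, k = len(tokens), len(run)
    return any(tokens[i : i + k] == run for i in range(n - k + 1))


def qtype_match_feature(pq_types: set[str], hq_types: set[str]) -> int:
    """Type-agreement feature: 2 perfect match, 1 overlap, 0 disjoint.

    Two empty sets score 0 — absence of a detected type is not evidence of
    agreement.
    """
    if pq_types and pq_types == hq_types:
        return 2
    if pq_types & hq_types:
        return 1
    return 0
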