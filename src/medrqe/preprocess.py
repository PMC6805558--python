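"""Text preprocessing shared by the feature extractor and the retrieval index.

The normalization pipeline is deliberately simple and deterministic:
lowercase, split on runs of non-alphanumeric characters, drop stop words,
then Porter-stem each surviving token.  Both the premise question and the
indexed collection questions go through the identical pipeline, so every
lexical similarity is computed in the same normalized space.

Part-of-speech tagging is a pluggable contract rather than a bundled
statistical tagger: any callable that maps a token to one of ``NOUN``,
``VERB`` or ``OTHER`` may be supplied.  The default implementation is a
lexicon lookup with ``OTHER`` for unknown tokens.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .stemming import porter_stem

__all__ = [
    "TokenizedText",
    "load_default_stopwords",
    "load_stopwords",
    "load_pos_lexicon",
    "tokenize",
    "preprocess_text",
    "bigrams",
    "pos_tag",
    "POS_TAGS",
]

POS_TAGS = ("NOUN", "VERB", "OTHER")

_TOKEN_RE = re.compile(r"[a-z0-9]+")


@dataclass
class TokenizedText:
    """A text together with its preprocessed (stemmed, stopword-free) tokens.

    ``pos``, when set, carries exactly one tag per token, each tag one of
    :data:`POS_TAGS`.
    """

    raw: str
    tokens: list[str] = field(default_factory=list)
    pos: list[str] | None = None

    def joined(self) -> str:
        """Tokens joined by single spaces (the string the edit-distance
        similarity operates on)."""
        return " ".join(self.tokens)


def load_default_stopwords() -> frozenset[str]:
    """The packaged standard English stop-word list."""
    text = resources.files("medrqe").joinpath("data", "stopwords.txt").read_text("utf-8")
    return frozenset(w.strip() for w in text.splitlines() if w.strip())


def load_stopwords(path: str | Path) -> frozenset[str]:
    """Read a stop-word file: one token per line, UTF-8."""
    lines = Path(path).read_text("utf-8").splitlines()
    return frozenset(w.strip() for w in lines if w.strip())


def load_pos_lexicon(path: str | Path) -> dict[str, str]:
    """Read a POS lexicon: ``token<TAB>tag`` per line, tag in :data:`POS_TAGS`."""
    lexicon: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text("utf-8").splitlines(), 1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 2 or parts[1] not in POS_TAGS:
            raise ValueError(f"{path}:{lineno}: expected 'token<TAB>NOUN|VERB|OTHER'")
        lexicon[parts[0]] = parts[1]
    return lexicon


def tokenize(text: str) -> list[str]:
    """Lowercase and split on runs of non-alphanumeric characters."""
    return _TOKEN_RE.findall(text.lower())


def preprocess_text(text: str, stopwords: Iterable[str] | None = None) -> TokenizedText:
    """Tokenize, drop stop words and Porter-stem.

    Stop words are matched on the surface token, before stemming.  With
    ``stopwords=None`` the packaged default list is used; pass an empty set
    to disable removal.
    """
    if stopwords is None:
        stopwords = load_default_stopwords()
    else:
        stopwords = frozenset(stopwords)
    tokens = [porter_stem(t) for t in tokenize(text) if t not in stopwords]
    return TokenizedText(raw=text, tokens=tokens)


def bigrams(tokens: Sequence[str]) -> list[tuple[str, str]]:
    """Adjacent token pairs, in order; empty for fewer than two tokens."""
    return [(tokens[i], tokens[i + 1]) for i in range(len(tokens) - 1)]


def pos_tag(tokens: Sequence[str], lexicon: Mapping[str, str]) -> list[str]:
    """Tag each token by lexicon lookup; unknown tokens get ``OTHER``."""
    return [lexicon.get(t, "OTHER") for t in tokens]
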