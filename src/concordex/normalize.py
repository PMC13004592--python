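"""Text normalization: tokenize, drop numerals, lemmatize, remove stop words.

The normalization chain converts a raw answer or reference text into an
ordered sequence of lowercase lemma tokens suitable for bag-of-words
vectorization.  The four steps run in a fixed order::

    tokenize -> drop_numeric -> lemmatize -> remove_stopwords

Stop-word removal runs *after* lemmatization so that inflected filler words
(e.g. "was" -> "be") are caught by a lemma-form stop-list.  The stop-list is
a pinned file shipped with the package; the lemmatizer is a pinned
rule-based English backend (irregular-form table plus suffix rules) whose
fallback for unknown forms is the identity map, keeping the lemma map total.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from typing import Iterable

from pydantic import BaseModel

__all__ = [
    "ConfigurationError",
    "NormalizationConfig",
    "TokenSequence",
    "tokenize",
    "drop_numeric",
    "lemmatize",
    "remove_stopwords",
    "normalize",
    "load_stoplist",
]


class ConfigurationError(ValueError):
    """Raised for unknown stop-list or lemmatizer identifiers."""


class NormalizationConfig(BaseModel):
    """Configuration of the normalization chain.

    Parameters
    ----------
    stoplist_name:
        Identifier of a pinned stop-word list shipped in the package
        (currently ``"english"``), or ``"none"`` to disable stop-word
        removal.
    lemmatizer_name:
        ``"rules"`` (pinned rule-based English lemmatizer) or
        ``"identity"`` (no lemmatization).
    drop_numeric:
        Whether tokens containing any digit are removed.
    """

    stoplist_name: str = "english"
    lemmatizer_name: str = "rules"
    drop_numeric: bool = True

    model_config = {"frozen": True}


@dataclass(frozen=True)
class TokenSequence:
    """A normalized document: ordered lowercase lemma tokens."""

    tokens: tuple[str, ...]
    source_id: str = ""

    def __len__(self) -> int:
        return len(self.tokens)

    def __iter__(self):
        return iter(self.tokens)


_TOKEN_RE = re.compile(r"[0-9a-z]+")
_DIGIT_RE = re.compile(r"[0-9]")


def tokenize(text: str) -> list[str]:
    """Lowercase and split on any non-alphanumeric boundary.

    Punctuation, whitespace and other formatting characters act as
    separators and are discarded; hyphenated words split into their parts.
    """
    return _TOKEN_RE.findall(text.lower())


def drop_numeric(tokens: Iterable[str]) -> list[str]:
    """Remove every token containing at least one digit character.

    Drops both pure numerals ("50") and alphanumeric forms ("5mg", "b12"),
    so that isolated quantities such as drug dosages cannot dominate the
    term weights.
    """
    return [t for t in tokens if not _DIGIT_RE.search(t)]


# Irregular English forms that suffix rules cannot reach.
_IRREGULAR: dict[str, str] = {
    "am": "be", "is": "be", "are": "be", "was": "be", "were": "be",
    "been": "be", "being": "be",
    "has": "have", "had": "have", "having": "have",
    "does": "do", "did": "do", "done": "do", "doing": "do",
    "goes": "go", "went": "go", "gone": "go",
    "ran": "run", "running": "run",
    "men": "man", "women": "woman", "children": "child",
    "mice": "mouse", "feet": "foot", "teeth": "tooth",
    "made": "make", "said": "say", "taken": "take", "took": "take",
    "given": "give", "gave": "give", "found": "find", "seen": "see",
    "saw": "see", "known": "know", "knew": "know", "grew": "grow",
    "grown": "grow", "left": "leave", "bound": "bind", "built": "build",
}

_VOWELS = set("aeiou")


def _strip_suffix(token: str) -> str:
    """Suffix rules for regular plural and verbal inflections."""
    n = len(token)
    if n >= 5 and token.endswith("ies"):
        return token[:-3] + "y"
    if n >= 5 and token.endswith(("ches", "shes", "sses", "xes", "zes")):
        return token[:-2]
    if n >= 4 and token.endswith("s") and not token.endswith(("ss", "us", "is")):
        return token[:-1]
    for suf in ("ing", "ed"):
        if n >= len(suf) + 3 and token.endswith(suf):
            stem = token[: -len(suf)]
            # undouble a final consonant (planned -> plan, running -> run)
            if (
                len(stem) >= 3
                and stem[-1] == stem[-2]
                and stem[-1] not in _VOWELS
                and stem[-1] not in "lsz"
            ):
                stem = stem[:-1]
            return stem
    return token


def _lemma_rules(token: str) -> str:
    if token in _IRREGULAR:
        return _IRREGULAR[token]
    return _strip_suffix(token)


_LEMMATIZERS = {
    "rules": _lemma_rules,
    "identity": lambda t: t,
}


def lemmatize(tokens: Iterable[str], config: NormalizationConfig | None = None) -> list[str]:
    """Map each token to its lemma; unknown forms map to themselves."""
    config = config or NormalizationConfig()
    try:
        fn = _LEMMATIZERS[config.lemmatizer_name]
    except KeyError:
        raise ConfigurationError(
            f"unknown lemmatizer backend {config.lemmatizer_name!r}; "
            f"available: {sorted(_LEMMATIZERS)}"
        ) from None
    return [fn(t) for t in tokens]


def load_stoplist(name: str) -> frozenset[str]:
    """Load a pinned stop-word list shipped with the package.

    The file format is one token per line, UTF-8, with ``#`` comments and
    blank lines ignored.  ``name="none"`` yields the empty list.
    """
    if name == "none":
        return frozenset()
    ref = resources.files("concordex.data").joinpath(f"stopwords_{name}.txt")
    if not ref.is_file():
        raise ConfigurationError(f"no stop-list named {name!r} is shipped with the package")
    words = set()
    for line in ref.read_text(encoding="utf-8").splitlines():
        word = line.split("#", 1)[0].strip()
        if word:
            words.add(word)
    return frozenset(words)


def remove_stopwords(tokens: Iterable[str], config: NormalizationConfig | None = None) -> list[str]:
    """Drop tokens present in the configured stop-list, preserving order."""
    config = config or NormalizationConfig()
    stoplist = load_stoplist(config.stoplist_name)
    return [t for t in tokens if t not in stoplist]


def normalize(text: str, config: NormalizationConfig | None = None, source_id: str = "") -> TokenSequence:
    """Full normalization chain producing a :class:`TokenSequence`.

    Equivalent to ``remove_stopwords(lemmatize(drop_numeric(tokenize(text))))``
    under the given configuration.
    """
    config = config or NormalizationConfig()
    tokens = tokenize(text)
    if config.drop_numeric:
        tokens = drop_numeric(tokens)
    tokens = lemmatize(tokens, config)
    tokens = remove_stopwords(tokens, config)
    return TokenSequence(tokens=tuple(tokens), source_id=source_id)
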