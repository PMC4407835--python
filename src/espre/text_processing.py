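"""Clinical text → signed bag-of-words term vectors.

The pipeline is: tokenize → greedy leftmost-longest dictionary matching →
NegEx-style negation detection → signed term keys. An asserted concept c is
keyed ``"c"``; a negated one ``"NEG" + c`` (e.g. "No CNS disease" becomes
the single key "NEG23853001"). Raw word tokens outside concept mentions can
optionally be kept as ``"w:" + token`` keys so that narrative phrasing not
covered by the terminology still contributes to matching.

Negation follows the NegEx scheme: a pre-negation trigger phrase ("no",
"denies", "without", ...) negates any concept mention that starts within a
bounded token window after the trigger, unless a scope terminator ("but",
"however", ...) or a pseudo-negation phrase ("not only", ...) intervenes.
Only pre-negation triggers are implemented; the lexicon is a plain-text
config so users can extend it.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator

from .terminology import TerminologyIndex, normalize_tokens

__all__ = [
    "Token",
    "Polarity",
    "ConceptMention",
    "TermVector",
    "TriggerLexicon",
    "tokenize",
    "extract_mentions",
    "detect_negation",
    "to_term_vector",
    "flip_polarity",
    "load_triggers",
    "load_stopwords",
    "default_triggers",
    "default_stopwords",
    "NEG_PREFIX",
    "RAW_PREFIX",
    "DEFAULT_NEGATION_WINDOW",
]

NEG_PREFIX = "NEG"
RAW_PREFIX = "w:"
#: NegEx scope window in tokens (canonical default).
DEFAULT_NEGATION_WINDOW = 5

_ALNUM = frozenset("abcdefghijklmnopqrstuvwxyz0123456789")


@dataclass(frozen=True)
class Token:
    """A normalized token with offsets into the original text."""

    text: str
    start: int
    end: int


class Polarity(enum.Enum):
    ASSERTED = "asserted"
    NEGATED = "negated"


@dataclass(frozen=True)
class ConceptMention:
    """A dictionary hit over a half-open token-index span."""

    concept_id: str
    span: tuple[int, int]
    polarity: Polarity = Polarity.ASSERTED

    @property
    def key(self) -> str:
        if self.polarity is Polarity.NEGATED:
            return NEG_PREFIX + self.concept_id
        return self.concept_id


def tokenize(text: str) -> list[Token]:
    """Split text into lowercase alphanumeric tokens with source offsets.

    A token is a maximal run of [a-zA-Z0-9]; everything else (punctuation,
    symbols, whitespace) separates tokens, so "T-cell ALL (relapsed)"
    yields ["t", "cell", "all", "relapsed"]. ``text[start:end].lower()``
    reconstructs each token.
    """
    tokens: list[Token] = []
    start = None
    for i, ch in enumerate(text):
        if ch.lower() in _ALNUM:
            if start is None:
                start = i
        elif start is not None:
            tokens.append(Token(text[start:i].lower(), start, i))
            start = None
    if start is not None:
        tokens.append(Token(text[start:].lower(), start, len(text)))
    return tokens


def extract_mentions(
    tokens: list[Token], index: TerminologyIndex
) -> list[ConceptMention]:
    """Greedy leftmost-longest dictionary matching over the token stream.

    At each position the longest indexed phrase starting there wins and the
    scan resumes after it, so matched spans never overlap. All mentions are
    initially asserted; polarity is assigned later by negation detection.
    """
    texts = [t.text for t in tokens]
    mentions: list[ConceptMention] = []
    i, n = 0, len(tokens)
    while i < n:
        matched = False
        for length in range(min(index.max_phrase_len, n - i), 0, -1):
            concept_id = index.phrase_map.get(tuple(texts[i : i + length]))
            if concept_id is not None:
                mentions.append(ConceptMention(concept_id, (i, i + length)))
                i += length
                matched = True
                break
        if not matched:
            i += 1
    return mentions


@dataclass(frozen=True)
class TriggerLexicon:
    """Negation trigger phrases, each stored as a normalized token tuple."""

    pre: tuple[tuple[str, ...], ...]
    pseudo: tuple[tuple[str, ...], ...] = ()
    terminators: tuple[tuple[str, ...], ...] = ()

    @classmethod
    def from_phrases(
        cls,
        pre: Iterable[str],
        pseudo: Iterable[str] = (),
        terminators: Iterable[str] = (),
    ) -> "TriggerLexicon":
        def norm(phrases: Iterable[str]) -> tuple[tuple[str, ...], ...]:
            out = []
            for p in phrases:
                key = tuple(normalize_tokens(p))
                if key:
                    out.append(key)
            return tuple(out)

        return cls(norm(pre), norm(pseudo), norm(terminators))


def _phrase_occurrences(
    texts: list[str], phrases: tuple[tuple[str, ...], ...]
) -> list[tuple[int, int]]:
    """All (start, end) token spans where any phrase occurs."""
    spans = []
    for phrase in phrases:
        plen = len(phrase)
        for i in range(len(texts) - plen + 1):
            if tuple(texts[i : i + plen]) == phrase:
                spans.append((i, i + plen))
    return spans


def detect_negation(
    tokens: list[Token],
    mentions: list[ConceptMention],
    triggers: TriggerLexicon,
    window: int = DEFAULT_NEGATION_WINDOW,
) -> list[ConceptMention]:
    """Assign negated polarity to mentions in the scope of a pre-negation
    trigger.

    A mention starting at token m is negated iff some pre-negation trigger
    occurrence ends at e ≤ m with a gap m − e < ``window`` and (a) the
    trigger is not part of a pseudo-negation phrase, and (b) no scope
    terminator or pseudo-negation occurrence starts in [e, m). The concept
    set is never changed — only polarities.
    """
    texts = [t.text for t in tokens]
    pre_spans = _phrase_occurrences(texts, triggers.pre)
    pseudo_spans = _phrase_occurrences(texts, triggers.pseudo)
    term_spans = _phrase_occurrences(texts, triggers.terminators)

    def in_pseudo(span: tuple[int, int]) -> bool:
        return any(ps <= span[0] and span[1] <= pe for ps, pe in pseudo_spans)

    blockers = sorted(
        {s for s, _ in term_spans} | {s for s, _ in pseudo_spans}
    )

    out: list[ConceptMention] = []
    for mention in mentions:
        m = mention.span[0]
        negated = False
        for ts, te in pre_spans:
            if te > m or m - te >= window or in_pseudo((ts, te)):
                continue
            if any(te <= b < m for b in blockers):
                continue
            negated = True
            break
        out.append(
            replace(mention, polarity=Polarity.NEGATED)
            if negated
            else mention
        )
    return out


@dataclass(frozen=True)
class TermVector:
    """Binary signed bag-of-words.

    Keys are concept ids ("23853001"), negated concept ids ("NEG23853001"),
    or raw word tokens ("w:relapsed"). A vector never holds both "c" and
    "NEGc": on construction the asserted key wins (clinical text asserting a
    finding anywhere outweighs a negated mention for matching purposes).
    """

    terms: frozenset[str] = frozenset()

    @staticmethod
    def _resolve(keys: Iterable[str]) -> frozenset[str]:
        keys = set(keys)
        dropped = {
            k
            for k in keys
            if k.startswith(NEG_PREFIX)
            and not k.startswith(RAW_PREFIX)
            and k[len(NEG_PREFIX) :] in keys
        }
        return frozenset(keys - dropped)

    @classmethod
    def from_keys(cls, keys: Iterable[str]) -> "TermVector":
        return cls(cls._resolve(keys))

    def union(self, other: "TermVector") -> "TermVector":
        return TermVector.from_keys(self.terms | other.terms)

    def concept_keys(self) -> frozenset[str]:
        return frozenset(k for k in self.terms if not k.startswith(RAW_PREFIX))

    def __contains__(self, key: str) -> bool:
        return key in self.terms

    def __len__(self) -> int:
        return len(self.terms)

    def __iter__(self) -> Iterator[str]:
        return iter(self.terms)


def to_term_vector(
    mentions: list[ConceptMention],
    tokens: list[Token],
    include_raw_tokens: bool = True,
    stopwords: frozenset[str] | None = None,
) -> TermVector:
    """Collapse mentions (and optionally leftover tokens) into a vector.

    Each asserted mention contributes its concept_id key, each negated one
    the NEG-prefixed key; presence is binary. With ``include_raw_tokens``,
    every non-stopword token outside all mention spans contributes a
    ``w:``-prefixed key.
    """
    if stopwords is None:
        stopwords = default_stopwords()
    keys = {m.key for m in mentions}
    if include_raw_tokens:
        covered = set()
        for m in mentions:
            covered.update(range(*m.span))
        for i, tok in enumerate(tokens):
            if i not in covered and tok.text not in stopwords:
                keys.add(RAW_PREFIX + tok.text)
    return TermVector.from_keys(keys)


def flip_polarity(vector: TermVector) -> TermVector:
    """Swap asserted ↔ negated on every concept key; raw keys unchanged.

    Used to fold exclusion criteria into a trial vector: terms extracted
    from exclusion text are converted into negated format (and vice versa,
    making the operation an involution).
    """
    flipped = set()
    for key in vector.terms:
        if key.startswith(RAW_PREFIX):
            flipped.add(key)
        elif key.startswith(NEG_PREFIX):
            flipped.add(key[len(NEG_PREFIX) :])
        else:
            flipped.add(NEG_PREFIX + key)
    # bypass conflict resolution: a conflict-free input flips conflict-free
    return TermVector(frozenset(flipped))


# ---------------------------------------------------------------------------
# Bundled lexicons


def load_triggers(path: str | Path) -> TriggerLexicon:
    """Parse a trigger lexicon file with [PRE] / [PSEUDO] / [TERM] sections,
    one phrase per line; '#' starts a comment."""
    sections: dict[str, list[str]] = {"PRE": [], "PSEUDO": [], "TERM": []}
    current: list[str] | None = None
    for raw in Path(path).read_text(encoding="utf-8").splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("[") and line.endswith("]"):
            name = line[1:-1].upper()
            if name not in sections:
                raise ValueError(f"unknown trigger section {name!r}")
            current = sections[name]
        elif current is None:
            raise ValueError("phrase before any section header")
        else:
            current.append(line)
    return TriggerLexicon.from_phrases(
        sections["PRE"], sections["PSEUDO"], sections["TERM"]
    )


def load_stopwords(path: str | Path) -> frozenset[str]:
    words = set()
    for raw in Path(path).read_text(encoding="utf-8").splitlines():
        line = raw.split("#", 1)[0].strip().lower()
        if line:
            words.add(line)
    return frozenset(words)


_DEFAULT_TRIGGERS: TriggerLexicon | None = None
_DEFAULT_STOPWORDS: frozenset[str] | None = None


def _data_path(name: str) -> Path:
    return Path(str(resources.files("espre").joinpath("data", name)))


def default_triggers() -> TriggerLexicon:
    global _DEFAULT_TRIGGERS
    if _DEFAULT_TRIGGERS is None:
        _DEFAULT_TRIGGERS = load_triggers(_data_path("negation_triggers.txt"))
    return _DEFAULT_TRIGGERS


def default_stopwords() -> frozenset[str]:
    global _DEFAULT_STOPWORDS
    if _DEFAULT_STOPWORDS is None:
        _DEFAULT_STOPWORDS = load_stopwords(_data_path("stopwords.txt"))
    return _DEFAULT_STOPWORDS
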