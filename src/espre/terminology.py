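"""Controlled-vocabulary loading and phrase/ICD-9 → concept lookup.

A bundled flat-file mini-terminology stands in for the licensed clinical
vocabularies (UMLS/SNOMED-CT/RxNorm) a production deployment would use: the
matching pipeline only needs the phrase→concept and ICD-9→concept mapping
contracts, not the full vocabularies.

Normalization is deliberately aggressive — lowercase, strip everything
outside [a-z0-9], collapse whitespace — so that dictionary lookup operates
at the same granularity as the bag-of-words vectors downstream.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

__all__ = [
    "Concept",
    "TerminologyIndex",
    "Icd9Map",
    "TerminologyError",
    "normalize",
    "normalize_tokens",
    "load_terminology",
    "load_icd9_map",
    "normalize_icd9",
    "map_icd9",
]


class TerminologyError(ValueError):
    """Raised on malformed or inconsistent terminology/map files."""


_NON_ALNUM = re.compile(r"[^a-z0-9]+")


def normalize_tokens(text: str) -> list[str]:
    """Normalized token list: lowercase, [a-z0-9] runs only."""
    return [t for t in _NON_ALNUM.split(text.lower()) if t]


def normalize(text: str) -> str:
    """Canonical phrase form: normalized tokens joined by single spaces."""
    return " ".join(normalize_tokens(text))


@dataclass(frozen=True)
class Concept:
    """One controlled-vocabulary entry.

    The preferred term is always among the synonyms, so lookup of any
    surface form of the concept round-trips to ``concept_id``.
    """

    concept_id: str
    preferred_term: str
    synonyms: tuple[str, ...]
    vocabulary: str = ""

    def __post_init__(self) -> None:
        if not self.concept_id:
            raise TerminologyError("concept_id must be non-empty")
        if not self.synonyms:
            raise TerminologyError(
                f"concept {self.concept_id!r} has no synonyms"
            )


@dataclass
class TerminologyIndex:
    """Phrase → concept dictionary over normalized token sequences.

    ``phrase_map`` keys are tuples of normalized tokens; every phrase maps
    to exactly one concept_id (duplicates are rejected at load time).
    ``max_phrase_len`` bounds the longest-match search window.
    """

    concepts: dict[str, Concept] = field(default_factory=dict)
    phrase_map: dict[tuple[str, ...], str] = field(default_factory=dict)
    max_phrase_len: int = 0

    def add(self, concept: Concept) -> None:
        if concept.concept_id in self.concepts:
            raise TerminologyError(
                f"duplicate concept_id {concept.concept_id!r}"
            )
        self.concepts[concept.concept_id] = concept
        for syn in concept.synonyms:
            key = tuple(normalize_tokens(syn))
            if not key:
                continue
            existing = self.phrase_map.get(key)
            if existing is not None and existing != concept.concept_id:
                raise TerminologyError(
                    f"phrase {' '.join(key)!r} maps to both "
                    f"{existing!r} and {concept.concept_id!r}"
                )
            self.phrase_map[key] = concept.concept_id
            self.max_phrase_len = max(self.max_phrase_len, len(key))

    def lookup(self, phrase: str) -> str | None:
        """Resolve a free-text phrase to a concept_id, or None."""
        return self.phrase_map.get(tuple(normalize_tokens(phrase)))

    def __contains__(self, concept_id: str) -> bool:
        return concept_id in self.concepts

    def __len__(self) -> int:
        return len(self.concepts)


def load_terminology(path: str | Path) -> TerminologyIndex:
    """Load a terminology TSV into a phrase index.

    Format: header row, then ``concept_id<TAB>preferred_term<TAB>
    syn1|syn2|...<TAB>vocabulary``. The preferred term is indexed whether or
    not it is repeated in the synonym column. Load order does not affect the
    resulting index.
    """
    path = Path(path)
    index = TerminologyIndex()
    with path.open(encoding="utf-8") as fh:
        header = fh.readline()
        if not header.strip():
            return index
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 4:
                raise TerminologyError(
                    f"{path.name}:{lineno}: expected 4 tab-separated "
                    f"columns, got {len(parts)}"
                )
            concept_id, preferred, syns, vocab = parts
            synonyms = [s for s in syns.split("|") if s.strip()]
            if normalize(preferred) not in {normalize(s) for s in synonyms}:
                synonyms.insert(0, preferred)
            try:
                index.add(
                    Concept(
                        concept_id=concept_id.strip(),
                        preferred_term=preferred.strip(),
                        synonyms=tuple(synonyms),
                        vocabulary=vocab.strip(),
                    )
                )
            except TerminologyError as exc:
                raise TerminologyError(f"{path.name}:{lineno}: {exc}") from exc
    return index


# ICD-9-CM code shapes: plain 3-digit stems, V-codes (V + 2 digits) and
# E-codes (E + 3 digits), each with up to two decimal digits.
_ICD9_DOTTED = re.compile(
    r"^(?:(\d{3})|V(\d{2})|E(\d{3}))(?:\.(\d{1,2}))?$", re.IGNORECASE
)
_ICD9_PLAIN = re.compile(r"^(?:(\d{3})|V(\d{2})|E(\d{3}))(\d{1,2})?$", re.IGNORECASE)


def normalize_icd9(code: str) -> str:
    """Normalize an ICD-9 code to dotted upper-case form.

    Both the dotted ("204.00") and undotted ("20400") dialects occur in EHR
    extracts; the dot is (re)inserted after the 3-digit stem (after the V/E
    prefix where present). Raises :class:`TerminologyError` on strings that
    match neither dialect.
    """
    code = code.strip()
    m = _ICD9_DOTTED.match(code)
    if m is None:
        m = _ICD9_PLAIN.match(code)
    if m is None:
        raise TerminologyError(f"invalid ICD-9 code {code!r}")
    plain, vcode, ecode, suffix = m.groups()
    if plain is not None:
        stem = plain
    elif vcode is not None:
        stem = f"V{vcode}"
    else:
        stem = f"E{ecode}"
    return f"{stem}.{suffix}" if suffix else stem


@dataclass
class Icd9Map:
    """Flat ICD-9 → concept_id dictionary (dotted-form keys)."""

    entries: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.entries)


def load_icd9_map(
    path: str | Path, terminology: TerminologyIndex | None = None
) -> Icd9Map:
    """Load an ICD-9 → concept TSV (``icd9_code<TAB>concept_id``, header).

    If ``terminology`` is given, every target concept_id must exist in it.
    """
    path = Path(path)
    entries: dict[str, str] = {}
    with path.open(encoding="utf-8") as fh:
        fh.readline()  # header
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 2:
                raise TerminologyError(
                    f"{path.name}:{lineno}: expected 2 columns, got {len(parts)}"
                )
            code, concept_id = parts[0].strip(), parts[1].strip()
            code = normalize_icd9(code)
            if terminology is not None and concept_id not in terminology:
                raise TerminologyError(
                    f"{path.name}:{lineno}: concept {concept_id!r} "
                    "not in terminology"
                )
            entries[code] = concept_id
    return Icd9Map(entries=entries)


def map_icd9(code: str, icd9_map: Icd9Map) -> list[str]:
    """Map an ICD-9 code to concept ids; unknown codes yield [] (non-fatal)."""
    return [icd9_map.entries[c]] if (c := normalize_icd9(code)) in icd9_map.entries else []
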