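"""Parse trial eligibility descriptions into matchable trial profiles.

A trial profile carries the demographic constraints (age bounds, gender)
used by the pre-filter, the enrollment window, and a signed term vector
built from the narrative criteria: inclusion text is processed like any
clinical text (with negation detection, so "No CNS disease" inside an
inclusion section yields a NEG key), exclusion text is processed the same
way and then polarity-flipped, since a term the trial excludes should match
patients in whom it is absent.

Ages are stored as whole-day durations (1 year = 365.25 d, 1 month =
30.44 d, rounded) so the downstream filter can compare them against a
patient's age over the enrollment window without re-parsing units.
"""

from __future__ import annotations

import datetime as dt
import re
from dataclasses import dataclass, field
from pathlib import Path

from .terminology import TerminologyIndex
from .text_processing import (
    DEFAULT_NEGATION_WINDOW,
    TermVector,
    TriggerLexicon,
    default_stopwords,
    default_triggers,
    detect_negation,
    extract_mentions,
    flip_polarity,
    to_term_vector,
    tokenize,
)

__all__ = [
    "CriteriaError",
    "TrialCriteria",
    "AgeBounds",
    "Gender",
    "TrialProfile",
    "split_sections",
    "extract_age_bounds",
    "extract_gender",
    "build_trial_profile",
    "parse_trial_file",
    "DAYS_PER_YEAR",
    "DAYS_PER_MONTH",
]

DAYS_PER_YEAR = 365.25
DAYS_PER_MONTH = 30.44

_NCT_RE = re.compile(r"^NCT\d{8}$")


class CriteriaError(ValueError):
    """Raised when an eligibility description cannot be parsed."""


@dataclass(frozen=True)
class TrialCriteria:
    """Raw trial metadata plus the split criteria text."""

    nct_id: str
    open_date: dt.date
    close_date: dt.date
    inclusion_text: str
    exclusion_text: str = ""

    def __post_init__(self) -> None:
        if not _NCT_RE.match(self.nct_id):
            raise CriteriaError(f"bad trial id {self.nct_id!r}")
        if self.open_date > self.close_date:
            raise CriteriaError(
                f"{self.nct_id}: open_date after close_date"
            )


@dataclass(frozen=True)
class AgeBounds:
    """Inclusive age interval in days; None means unbounded above."""

    min_days: int = 0
    max_days: int | None = None

    def __post_init__(self) -> None:
        if self.min_days < 0:
            raise CriteriaError("negative minimum age")
        if self.max_days is not None and self.min_days > self.max_days:
            raise CriteriaError(
                f"contradictory age bounds: min {self.min_days} d > "
                f"max {self.max_days} d"
            )

    def contains(self, age_days: int) -> bool:
        if age_days < self.min_days:
            return False
        return self.max_days is None or age_days <= self.max_days

    def overlaps(self, lo_days: int, hi_days: int) -> bool:
        """Does [lo, hi] intersect these bounds?"""
        if hi_days < self.min_days:
            return False
        return self.max_days is None or lo_days <= self.max_days


class Gender:
    MALE = "male"
    FEMALE = "female"
    ANY = "any"


@dataclass(frozen=True)
class TrialProfile:
    """Everything matching needs about one trial."""

    nct_id: str
    age: AgeBounds
    gender: str
    open_date: dt.date
    close_date: dt.date
    vector: TermVector = field(default_factory=TermVector)


_INCL_RE = re.compile(r"inclusion\s+criteria\s*:?", re.IGNORECASE)
_EXCL_RE = re.compile(r"exclusion\s+criteria\s*:?", re.IGNORECASE)


def split_sections(text: str) -> tuple[str, str]:
    """Split an eligibility description at its section headers.

    Returns (inclusion_text, exclusion_text); a missing exclusion header
    yields an empty exclusion section, a missing inclusion header is an
    error (the criteria are unusable without one).
    """
    incl = _INCL_RE.search(text)
    if incl is None:
        raise CriteriaError("no 'Inclusion Criteria' header found")
    excl = _EXCL_RE.search(text, incl.end())
    if excl is None:
        return text[incl.end() :].strip(), ""
    return text[incl.end() : excl.start()].strip(), text[excl.end() :].strip()


def _to_days(value: float, unit: str) -> int:
    unit = unit.lower()
    if unit.startswith("year"):
        return round(value * DAYS_PER_YEAR)
    if unit.startswith("month"):
        return round(value * DAYS_PER_MONTH)
    return round(value)


_NUM = r"(\d+(?:\.\d+)?)"
_UNIT = r"(years?|months?|days?)"
_RANGE_RE = re.compile(
    rf"{_NUM}\s*{_UNIT}\s*(?:to|through|-|–)\s*{_NUM}\s*{_UNIT}",
    re.IGNORECASE,
)
_MIN_RES = [
    re.compile(rf"(?:at least|minimum(?: age)?(?: of)?:?|>=|≥)\s*{_NUM}\s*{_UNIT}", re.IGNORECASE),
    re.compile(rf"{_NUM}\s*{_UNIT}\s*(?:and|or)\s*older", re.IGNORECASE),
]
_MIN_STRICT_RES = [
    re.compile(rf"(?:older than|over|>)\s*{_NUM}\s*{_UNIT}", re.IGNORECASE),
]
_MAX_RES = [
    re.compile(rf"(?:at most|up to|maximum(?: age)?(?: of)?:?|<=|≤)\s*{_NUM}\s*{_UNIT}", re.IGNORECASE),
    re.compile(rf"{_NUM}\s*{_UNIT}\s*(?:and|or)\s*younger", re.IGNORECASE),
]
_MAX_STRICT_RES = [
    re.compile(rf"(?:younger than|under|less than|below|<)\s*{_NUM}\s*{_UNIT}", re.IGNORECASE),
]


def extract_age_bounds(text: str) -> AgeBounds:
    """Pull age limits out of criteria text.

    The explicit "X Unit to Y Unit" range form wins outright; otherwise the
    first-occurring lower-bound phrase and first-occurring upper-bound
    phrase are combined. Strict bounds ("younger than 18 years") are stored
    as the adjacent inclusive whole day. Absent language leaves the side
    unbounded. Contradictory bounds raise :class:`CriteriaError`.
    """
    m = _RANGE_RE.search(text)
    if m is not None:
        lo = _to_days(float(m.group(1)), m.group(2))
        hi = _to_days(float(m.group(3)), m.group(4))
        return AgeBounds(min_days=lo, max_days=hi)

    def first(patterns: list[re.Pattern]) -> tuple[int, float, str] | None:
        best = None
        for pat in patterns:
            mm = pat.search(text)
            if mm and (best is None or mm.start() < best[0]):
                best = (mm.start(), float(mm.group(1)), mm.group(2))
        return best

    min_days = 0
    max_days: int | None = None
    lo_incl, lo_strict = first(_MIN_RES), first(_MIN_STRICT_RES)
    if lo_incl is not None and (
        lo_strict is None or lo_incl[0] <= lo_strict[0]
    ):
        min_days = _to_days(lo_incl[1], lo_incl[2])
    elif lo_strict is not None:
        min_days = _to_days(lo_strict[1], lo_strict[2]) + 1
    hi_incl, hi_strict = first(_MAX_RES), first(_MAX_STRICT_RES)
    if hi_incl is not None and (
        hi_strict is None or hi_incl[0] <= hi_strict[0]
    ):
        max_days = _to_days(hi_incl[1], hi_incl[2])
    elif hi_strict is not None:
        max_days = _to_days(hi_strict[1], hi_strict[2]) - 1
    return AgeBounds(min_days=min_days, max_days=max_days)


_FEMALE_RE = re.compile(r"\b(?:females?|women|woman|girls?)\b", re.IGNORECASE)
_MALE_RE = re.compile(r"\b(?:males?|men|man|boys?)\b", re.IGNORECASE)
_BOTH_RE = re.compile(r"\b(?:both|all genders?|any gender)\b", re.IGNORECASE)


def extract_gender(text: str) -> str:
    """Gender constraint: female-only wording → female, male-only → male,
    'both'/mixed/absent → any."""
    if _BOTH_RE.search(text):
        return Gender.ANY
    has_f = _FEMALE_RE.search(text) is not None
    has_m = _MALE_RE.search(text) is not None
    if has_f and not has_m:
        return Gender.FEMALE
    if has_m and not has_f:
        return Gender.MALE
    return Gender.ANY


_BULLET_RE = re.compile(r"^\s*(?:[-*•‣·]+|\d+[.)])\s+", re.MULTILINE)


def strip_bullets(text: str) -> str:
    """Remove leading bullet markers and list numbering from each line."""
    return _BULLET_RE.sub("", text)


def _criteria_vector(
    text: str,
    index: TerminologyIndex,
    triggers: TriggerLexicon,
    window: int,
    include_raw_tokens: bool,
    negate: bool,
    stopwords: frozenset[str],
) -> TermVector:
    tokens = tokenize(strip_bullets(text))
    mentions = extract_mentions(tokens, index)
    if negate:
        mentions = detect_negation(tokens, mentions, triggers, window)
    return to_term_vector(
        mentions, tokens, include_raw_tokens=include_raw_tokens,
        stopwords=stopwords,
    )


def build_trial_profile(
    criteria: TrialCriteria,
    index: TerminologyIndex,
    triggers: TriggerLexicon | None = None,
    *,
    window: int = DEFAULT_NEGATION_WINDOW,
    include_raw_tokens: bool = True,
    negex_in_exclusion: bool = True,
    stopwords: frozenset[str] | None = None,
) -> TrialProfile:
    """Turn parsed criteria into a trial profile.

    The profile vector is the union of the inclusion vector and the
    polarity-flipped exclusion vector. With ``negex_in_exclusion`` (the
    default) negation detection also runs inside the exclusion section
    before flipping, so "no prior chemotherapy" under exclusion composes to
    an asserted prior-chemotherapy requirement (NegEx negates, flip
    re-asserts); set it False to flip raw asserted exclusion terms only.
    Where inclusion and flipped-exclusion keys conflict, the asserted key
    wins (same rule as everywhere vectors merge).
    """
    if triggers is None:
        triggers = default_triggers()
    if stopwords is None:
        stopwords = default_stopwords()
    full_text = "\n".join(
        t for t in (criteria.inclusion_text, criteria.exclusion_text) if t
    )
    incl_vec = _criteria_vector(
        criteria.inclusion_text, index, triggers, window,
        include_raw_tokens, negate=True, stopwords=stopwords,
    )
    excl_vec = _criteria_vector(
        criteria.exclusion_text, index, triggers, window,
        include_raw_tokens, negate=negex_in_exclusion, stopwords=stopwords,
    )
    vector = incl_vec.union(flip_polarity(excl_vec))
    return TrialProfile(
        nct_id=criteria.nct_id,
        age=extract_age_bounds(full_text),
        gender=extract_gender(full_text),
        open_date=criteria.open_date,
        close_date=criteria.close_date,
        vector=vector,
    )


def parse_trial_file(path: str | Path) -> TrialCriteria:
    """Read one trial file: NCT_ID/OPEN_DATE/CLOSE_DATE header lines, a
    blank line, then the eligibility description verbatim."""
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    header: dict[str, str] = {}
    body_start = 0
    for i, line in enumerate(lines):
        if not line.strip():
            body_start = i + 1
            break
        if ":" not in line:
            raise CriteriaError(f"{path.name}: bad header line {line!r}")
        key, _, value = line.partition(":")
        header[key.strip().upper()] = value.strip()
    else:
        raise CriteriaError(f"{path.name}: no blank line after header")
    for required in ("NCT_ID", "OPEN_DATE", "CLOSE_DATE"):
        if required not in header:
            raise CriteriaError(f"{path.name}: missing header {required}")
    description = "\n".join(lines[body_start:])
    inclusion, exclusion = split_sections(description)
    try:
        open_date = dt.date.fromisoformat(header["OPEN_DATE"])
        close_date = dt.date.fromisoformat(header["CLOSE_DATE"])
    except ValueError as exc:
        raise CriteriaError(f"{path.name}: {exc}") from exc
    return TrialCriteria(
        nct_id=header["NCT_ID"],
        open_date=open_date,
        close_date=close_date,
        inclusion_text=inclusion,
        exclusion_text=exclusion,
    )
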