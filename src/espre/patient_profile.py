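"""Patient EHR records → signed term vectors under per-trial temporal cutoffs.

A patient's profile for a trial only reflects information that was available
when the enrollment decision could have been made: entries timestamped after
the trial's closing date are dropped, and for a patient actually enrolled in
the trial only entries written strictly before the enrollment date count.
Structured diagnoses contribute via both their text (dictionary extraction,
negation off — a problem-list label asserts presence) and their ICD-9 code
(flat map); free-text notes run through the full pipeline including
negation and raw-token folding. Presence is binary, so a concept carried by
many visits still counts once.
"""

from __future__ import annotations

import datetime as dt
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from .criteria_parser import TrialProfile
from .terminology import Icd9Map, TerminologyIndex, map_icd9
from .text_processing import (
    DEFAULT_NEGATION_WINDOW,
    TermVector,
    TriggerLexicon,
    default_stopwords,
    default_triggers,
    detect_negation,
    extract_mentions,
    to_term_vector,
    tokenize,
)

__all__ = [
    "DataEntry",
    "PatientRecord",
    "PatientProfile",
    "ProfileBuilder",
    "temporal_filter",
    "build_patient_profile",
    "load_patients",
]

logger = logging.getLogger(__name__)

DIAGNOSIS = "diagnosis"
NOTE = "note"


@dataclass(frozen=True)
class DataEntry:
    """One timestamped piece of EHR information (a diagnosis or a note)."""

    kind: str
    text: str
    timestamp: dt.date
    icd9: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in (DIAGNOSIS, NOTE):
            raise ValueError(f"unknown entry kind {self.kind!r}")
        if self.kind == NOTE and self.icd9 is not None:
            raise ValueError("note entries never carry an ICD-9 code")


@dataclass
class PatientRecord:
    patient_id: str
    birth_date: dt.date
    gender: str
    entries: list[DataEntry] = field(default_factory=list)
    enrollments: list[tuple[str, dt.date]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for e in self.entries:
            if e.timestamp < self.birth_date:
                raise ValueError(
                    f"{self.patient_id}: entry dated {e.timestamp} before "
                    f"birth {self.birth_date}"
                )

    def enrollment_date(self, nct_id: str) -> dt.date | None:
        for trial_id, date in self.enrollments:
            if trial_id == nct_id:
                return date
        return None

    @property
    def note_dates(self) -> set[dt.date]:
        return {e.timestamp for e in self.entries if e.kind == NOTE}


@dataclass(frozen=True)
class PatientProfile:
    patient_id: str
    vector: TermVector
    note_dates: frozenset[dt.date] = frozenset()


def temporal_filter(
    record: PatientRecord, trial: TrialProfile
) -> list[DataEntry]:
    """Entries visible at decision time for this trial.

    Non-enrolled patients: keep entries dated on or before the trial's
    closing date (whole-day granularity, close date itself included).
    Enrolled patients: keep entries dated strictly before the enrollment
    date — information written on or after it was not available when the
    physician decided.
    """
    enrollment = record.enrollment_date(trial.nct_id)
    if enrollment is not None:
        return [e for e in record.entries if e.timestamp < enrollment]
    return [e for e in record.entries if e.timestamp <= trial.close_date]


class ProfileBuilder:
    """Builds patient profiles, caching per-entry extraction.

    Concept extraction from an entry does not depend on the trial — only
    the temporal filter does — so each entry's key set is computed once and
    profiles for different trials are cheap unions over filtered entries.
    """

    def __init__(
        self,
        index: TerminologyIndex,
        icd9_map: Icd9Map | None = None,
        triggers: TriggerLexicon | None = None,
        *,
        window: int = DEFAULT_NEGATION_WINDOW,
        include_raw_tokens: bool = True,
        use_diagnoses: bool = True,
        use_notes: bool = True,
        stopwords: frozenset[str] | None = None,
    ) -> None:
        self.index = index
        self.icd9_map = icd9_map or Icd9Map()
        self.triggers = triggers or default_triggers()
        self.window = window
        self.include_raw_tokens = include_raw_tokens
        self.use_diagnoses = use_diagnoses
        self.use_notes = use_notes
        self.stopwords = (
            stopwords if stopwords is not None else default_stopwords()
        )
        self._entry_cache: dict[int, frozenset[str]] = {}

    def entry_keys(self, entry: DataEntry) -> frozenset[str]:
        cached = self._entry_cache.get(id(entry))
        if cached is not None:
            return cached
        if entry.kind == DIAGNOSIS:
            keys = self._diagnosis_keys(entry)
        else:
            keys = self._note_keys(entry)
        self._entry_cache[id(entry)] = keys
        return keys

    def _diagnosis_keys(self, entry: DataEntry) -> frozenset[str]:
        # Negation off: a structured problem-list label asserts presence.
        # Raw tokens off: diagnosis strings are codes' labels, not narrative.
        tokens = tokenize(entry.text)
        mentions = extract_mentions(tokens, self.index)
        keys = {m.key for m in mentions}
        if entry.icd9:
            keys.update(map_icd9(entry.icd9, self.icd9_map))
        return frozenset(keys)

    def _note_keys(self, entry: DataEntry) -> frozenset[str]:
        tokens = tokenize(entry.text)
        mentions = extract_mentions(tokens, self.index)
        mentions = detect_negation(
            tokens, mentions, self.triggers, self.window
        )
        return to_term_vector(
            mentions,
            tokens,
            include_raw_tokens=self.include_raw_tokens,
            stopwords=self.stopwords,
        ).terms

    def build(
        self, record: PatientRecord, trial: TrialProfile
    ) -> PatientProfile:
        keys: set[str] = set()
        note_dates: set[dt.date] = set()
        for entry in temporal_filter(record, trial):
            if entry.kind == DIAGNOSIS and not self.use_diagnoses:
                continue
            if entry.kind == NOTE and not self.use_notes:
                continue
            keys.update(self.entry_keys(entry))
            if entry.kind == NOTE:
                note_dates.add(entry.timestamp)
        return PatientProfile(
            patient_id=record.patient_id,
            vector=TermVector.from_keys(keys),
            note_dates=frozenset(note_dates),
        )


def build_patient_profile(
    record: PatientRecord,
    trial: TrialProfile,
    index: TerminologyIndex,
    icd9_map: Icd9Map | None = None,
    triggers: TriggerLexicon | None = None,
    **kwargs,
) -> PatientProfile:
    """One-shot convenience wrapper around :class:`ProfileBuilder`."""
    return ProfileBuilder(
        index, icd9_map, triggers, **kwargs
    ).build(record, trial)


def load_patients(
    path: str | Path,
    trials: dict[str, TrialProfile] | None = None,
) -> list[PatientRecord]:
    """Read patient records from JSON Lines.

    Each line holds one object with keys patient_id, birth_date, gender,
    diagnoses ([{text, icd9, date}]), notes ([{text, date}]) and
    enrollments ([{nct_id, date}]). When ``trials`` is given, enrollment
    dates outside the named trial's window are warned about (not fatal).
    """
    path = Path(path)
    records: list[PatientRecord] = []
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ValueError(f"{path.name}:{lineno}: {exc}") from exc
            entries = [
                DataEntry(
                    kind=DIAGNOSIS,
                    text=d["text"],
                    icd9=d.get("icd9"),
                    timestamp=dt.date.fromisoformat(d["date"]),
                )
                for d in obj.get("diagnoses", [])
            ] + [
                DataEntry(
                    kind=NOTE,
                    text=n["text"],
                    timestamp=dt.date.fromisoformat(n["date"]),
                )
                for n in obj.get("notes", [])
            ]
            enrollments = [
                (e["nct_id"], dt.date.fromisoformat(e["date"]))
                for e in obj.get("enrollments", [])
            ]
            record = PatientRecord(
                patient_id=obj["patient_id"],
                birth_date=dt.date.fromisoformat(obj["birth_date"]),
                gender=obj["gender"],
                entries=entries,
                enrollments=enrollments,
            )
            if trials:
                for nct_id, date in enrollments:
                    trial = trials.get(nct_id)
                    if trial and not (
                        trial.open_date <= date <= trial.close_date
                    ):
                        logger.warning(
                            "%s: enrollment in %s dated %s outside window "
                            "[%s, %s]",
                            record.patient_id, nct_id, date,
                            trial.open_date, trial.close_date,
                        )
            records.append(record)
    return records
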