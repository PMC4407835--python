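"""Demographic pre-filter, trial–patient scoring, and bidirectional ranking.

The matching score between a trial vector T and a patient vector P is a
binary cosine with a subtractive polarity-contradiction penalty:

    score = |T ∩ P| / sqrt(|T|·|P|)  −  λ · n_contra / sqrt(|T|·|P|)

where n_contra counts concepts asserted on one side and negated on the
other — i.e. a patient exhibiting a finding the trial excludes (or lacking
one it requires as absent) is pushed down the ranking rather than merely
failing to gain. λ = 1 by default; λ = 0 recovers plain cosine. The score
is symmetric, lies in [−λ·…, 1], and equals 1 exactly for identical
non-empty vectors with no penalty.

Ranking is deterministic: descending score, ties broken by candidate id.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .criteria_parser import Gender, TrialProfile
from .patient_profile import PatientRecord, ProfileBuilder
from .text_processing import NEG_PREFIX, RAW_PREFIX, TermVector

__all__ = [
    "MatchScore",
    "RankedList",
    "demographics_filter",
    "match_score",
    "rank_patients_for_trial",
    "rank_trials_for_patient",
    "baseline_shuffle",
    "write_ranked_tsv",
    "read_ranked_tsv",
    "PATIENTS_FOR_TRIAL",
    "TRIALS_FOR_PATIENT",
]

PATIENTS_FOR_TRIAL = "patients_for_trial"
TRIALS_FOR_PATIENT = "trials_for_patient"


@dataclass(frozen=True)
class MatchScore:
    value: float
    shared_terms: int = 0
    contradictions: int = 0


@dataclass
class RankedList:
    """Ordered candidates for one anchor (a trial or a patient).

    Contains exactly the candidates that passed the demographic pre-filter;
    scores are non-increasing, ties resolved by candidate id ascending.
    """

    direction: str
    anchor_id: str
    items: list[tuple[str, MatchScore | None]] = field(default_factory=list)

    @property
    def candidate_ids(self) -> list[str]:
        return [cid for cid, _ in self.items]

    def rank_of(self, candidate_id: str) -> int | None:
        """1-based rank, or None if the candidate was filtered out."""
        for i, (cid, _) in enumerate(self.items, start=1):
            if cid == candidate_id:
                return i
        return None

    def __len__(self) -> int:
        return len(self.items)


def demographics_filter(record: PatientRecord, trial: TrialProfile) -> bool:
    """Logic-based pre-filter on gender, age, and in-window notes.

    Passes iff (a) the trial accepts the patient's gender; (b) the
    patient's age interval across the enrollment window overlaps the
    trial's age bounds (eligible if age fits on any day of the window —
    the least restrictive reading, and sound for ranking); and (c) the
    patient has at least one clinical note dated inside the window —
    a patient with no notes during enrollment was not in the institution's
    care and is ruled out.
    """
    if trial.gender != Gender.ANY and record.gender != trial.gender:
        return False
    age_at_open = (trial.open_date - record.birth_date).days
    age_at_close = (trial.close_date - record.birth_date).days
    if age_at_close < 0:  # born after the window
        return False
    if not trial.age.overlaps(max(age_at_open, 0), age_at_close):
        return False
    return any(
        trial.open_date <= d <= trial.close_date for d in record.note_dates
    )


def _contradictions(t: TermVector, p: TermVector) -> int:
    count = 0
    for key in t.concept_keys():
        if key.startswith(NEG_PREFIX):
            if key[len(NEG_PREFIX) :] in p:
                count += 1
        elif NEG_PREFIX + key in p:
            count += 1
    return count


def match_score(
    trial_v: TermVector, patient_v: TermVector, lam: float = 1.0
) -> MatchScore:
    """Score two signed binary vectors (symmetric in its arguments)."""
    if lam < 0:
        raise ValueError(f"penalty weight must be non-negative, got {lam}")
    if len(trial_v) == 0 or len(patient_v) == 0:
        return MatchScore(0.0)
    shared = len(trial_v.terms & patient_v.terms)
    contra = _contradictions(trial_v, patient_v)
    norm = math.sqrt(len(trial_v) * len(patient_v))
    return MatchScore(
        value=(shared - lam * contra) / norm,
        shared_terms=shared,
        contradictions=contra,
    )


def _sorted_items(
    scored: list[tuple[str, MatchScore]]
) -> list[tuple[str, MatchScore]]:
    return sorted(scored, key=lambda it: (-it[1].value, it[0]))


def rank_patients_for_trial(
    trial: TrialProfile,
    records: Sequence[PatientRecord],
    builder: ProfileBuilder,
    lam: float = 1.0,
) -> RankedList:
    """Filter, score and rank the patient population for one trial."""
    scored = []
    for record in records:
        if not demographics_filter(record, trial):
            continue
        profile = builder.build(record, trial)
        scored.append(
            (record.patient_id, match_score(trial.vector, profile.vector, lam))
        )
    return RankedList(
        direction=PATIENTS_FOR_TRIAL,
        anchor_id=trial.nct_id,
        items=_sorted_items(scored),
    )


def rank_trials_for_patient(
    record: PatientRecord,
    trials: Sequence[TrialProfile],
    builder: ProfileBuilder,
    lam: float = 1.0,
) -> RankedList:
    """Filter, score and rank the open trials for one patient."""
    scored = []
    for trial in trials:
        if not demographics_filter(record, trial):
            continue
        profile = builder.build(record, trial)
        scored.append(
            (trial.nct_id, match_score(trial.vector, profile.vector, lam))
        )
    return RankedList(
        direction=TRIALS_FOR_PATIENT,
        anchor_id=record.patient_id,
        items=_sorted_items(scored),
    )


def baseline_shuffle(
    candidates: Sequence[str],
    seed: int,
    direction: str = PATIENTS_FOR_TRIAL,
    anchor_id: str = "",
) -> RankedList:
    """Random-order baseline over the post-filter candidates.

    Emulates screening without content matching: demographics decide who is
    in the pool, the review order is a uniform permutation reproducible by
    seed. No scores are attached.
    """
    order = list(candidates)
    random.Random(seed).shuffle(order)
    return RankedList(
        direction=direction,
        anchor_id=anchor_id,
        items=[(cid, None) for cid in order],
    )


def write_ranked_tsv(ranked: RankedList, out_dir: str | Path) -> Path:
    """Write ``<anchor_id>.ranked.tsv``: rank, id, score, shared, contra."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / f"{ranked.anchor_id}.ranked.tsv"
    with path.open("w", encoding="utf-8") as fh:
        fh.write("rank\tcandidate_id\tscore\tshared_terms\tcontradictions\n")
        for rank, (cid, score) in enumerate(ranked.items, start=1):
            if score is None:
                fh.write(f"{rank}\t{cid}\t\t\t\n")
            else:
                fh.write(
                    f"{rank}\t{cid}\t{score.value:.6f}\t"
                    f"{score.shared_terms}\t{score.contradictions}\n"
                )
    return path


def read_ranked_tsv(path: str | Path, direction: str = "") -> RankedList:
    path = Path(path)
    anchor_id = path.name.removesuffix(".ranked.tsv")
    items: list[tuple[str, MatchScore | None]] = []
    with path.open(encoding="utf-8") as fh:
        fh.readline()
        for line in fh:
            if not line.strip():
                continue
            _, cid, score, shared, contra = line.rstrip("\n").split("\t")
            items.append(
                (
                    cid,
                    MatchScore(float(score), int(shared), int(contra))
                    if score
                    else None,
                )
            )
    return RankedList(direction=direction, anchor_id=anchor_id, items=items)
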