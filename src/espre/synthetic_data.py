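"""Synthetic trial/patient corpora with planted, controllable signal.

The generator emits everything the pipeline reads — a terminology TSV, an
ICD-9 map, per-trial criteria files, a patient JSON-Lines file and a
reference CSV of enrollments — together with the ground truth used to plant
them, so every stage is testable end-to-end without any external data.

Construction guarantees (what makes recovery provable rather than merely
likely):

* each trial receives a *signature* of inclusion concepts and a small set
  of exclusion concepts; signatures and exclusion sets are pairwise
  disjoint across trials whenever the concept pool is large enough;
* criteria sentences are rendered from templates whose filler words are
  all stopwords, so a trial vector contains only its concept keys, its
  flipped exclusion keys, and a handful of boilerplate header words that
  never occur in patient notes;
* an eligible patient gets one "plant" note per trial they are eligible
  for, dated inside the window and before any enrollment date, mentioning
  each signature concept with probability ``signal``; ineligible patients
  draw concepts only from a background pool disjoint from every signature.

Hence at ``signal=1.0, distractor_rate=0.0`` an eligible patient shares the
full signature with the trial while every other patient shares nothing
(score exactly 0, or negative when they assert an excluded concept), which
is the separation the recovery tests assert. The population shape
(tens of trials, O(100) patients, a handful to tens of notes each, notes of
tens to hundreds of tokens, near-universal enrollment of eligibles at 0.9)
mirrors a pediatric-oncology screening cohort at desk scale.
"""

from __future__ import annotations

import datetime as dt
import json
import random
import re
from dataclasses import dataclass, field, replace
from pathlib import Path

__all__ = [
    "SimConfig",
    "SimTruth",
    "World",
    "SimConfigError",
    "generate_world",
    "corrupt_world",
]


class SimConfigError(ValueError):
    """Raised on infeasible or malformed simulation configs."""


@dataclass(frozen=True)
class SimConfig:
    """Knobs of the synthetic world; the seed is mandatory.

    ``signal`` is the probability that a signature concept is planted in an
    eligible patient's plant note (1.0 = full overlap); ``distractor_rate``
    is the per-note probability of an off-signature background concept;
    ``eligible_fraction`` is the per-trial fraction of patients planted as
    truly eligible; ``enrollment_prob`` the chance an eligible pair turns
    into a historical enrollment; ``demographic_fail_rate`` the fraction of
    patients whose age makes them fail every trial's demographic filter.
    """

    seed: int
    n_trials: int = 20
    n_patients: int = 100
    n_concepts: int = 150
    notes_per_patient: tuple[int, int] = (2, 40)
    note_length: tuple[int, int] = (50, 300)
    eligible_fraction: float = 0.05
    enrollment_prob: float = 0.9
    signal: float = 0.9
    distractor_rate: float = 0.05
    demographic_fail_rate: float = 0.1

    def __post_init__(self) -> None:
        for name in (
            "eligible_fraction",
            "enrollment_prob",
            "signal",
            "distractor_rate",
            "demographic_fail_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SimConfigError(f"{name} must be in [0, 1], got {v}")
        if self.n_trials < 1 or self.n_patients < 1 or self.n_concepts < 10:
            raise SimConfigError("world too small to generate")
        if round(self.eligible_fraction * self.n_patients) < 1:
            raise SimConfigError(
                "eligible_fraction * n_patients < 1: no patient could be "
                "planted as eligible, so no enrollment can exist"
            )


@dataclass(frozen=True)
class SimTruth:
    """Planted ground truth: who is truly eligible, who actually enrolled."""

    eligibility: frozenset[tuple[str, str]]
    enrollments: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        if not self.enrollments <= self.eligibility:
            raise SimConfigError("enrollments must be a subset of eligibility")


@dataclass
class World:
    """In-memory synthetic corpus; ``write`` materializes the file formats
    the rest of the package reads."""

    config: SimConfig
    terminology_rows: list[tuple[str, str, str, str]]
    icd9_rows: list[tuple[str, str]]
    trials: list[dict]  # nct_id, open_date, close_date, text
    patients: list[dict]  # JSONL schema
    reference: list[dict]  # patient_id, nct_id, enrollment_date
    truth: SimTruth
    signatures: dict[str, list[str]] = field(default_factory=dict)
    exclusions: dict[str, list[str]] = field(default_factory=dict)

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        (out / "trials").mkdir(parents=True, exist_ok=True)
        paths = {
            "terminology": out / "terminology.tsv",
            "icd9_map": out / "icd9_map.tsv",
            "patients": out / "patients.jsonl",
            "reference": out / "reference.csv",
            "eligibility": out / "eligibility.csv",
            "simconfig": out / "simconfig.json",
            "trials_dir": out / "trials",
        }
        with paths["terminology"].open("w", encoding="utf-8") as fh:
            fh.write("concept_id\tpreferred_term\tsynonyms\tvocabulary\n")
            for row in self.terminology_rows:
                fh.write("\t".join(row) + "\n")
        with paths["icd9_map"].open("w", encoding="utf-8") as fh:
            fh.write("icd9_code\tconcept_id\n")
            for code, cid in self.icd9_rows:
                fh.write(f"{code}\t{cid}\n")
        for trial in self.trials:
            (out / "trials" / f"{trial['nct_id']}.txt").write_text(
                trial["text"], encoding="utf-8"
            )
        with paths["patients"].open("w", encoding="utf-8") as fh:
            for patient in self.patients:
                fh.write(json.dumps(patient) + "\n")
        with paths["reference"].open("w", encoding="utf-8") as fh:
            fh.write("patient_id,nct_id,enrollment_date\n")
            for row in self.reference:
                fh.write(
                    f"{row['patient_id']},{row['nct_id']},"
                    f"{row['enrollment_date']}\n"
                )
        with paths["eligibility"].open("w", encoding="utf-8") as fh:
            fh.write("patient_id,nct_id\n")
            for nct_id, pid in sorted(self.truth.eligibility):
                fh.write(f"{pid},{nct_id}\n")
        cfg = {
            k: list(v) if isinstance(v, tuple) else v
            for k, v in vars(self.config).items()
        }
        paths["simconfig"].write_text(
            json.dumps(cfg, indent=2) + "\n", encoding="utf-8"
        )
        return paths


# Deterministic concept-name inventory: mixed-radix over word banks.
_ADJECTIVES = [
    "acute", "chronic", "refractory", "juvenile", "metastatic",
    "recurrent", "diffuse", "focal", "nodular", "cystic",
]
_TISSUES = [
    "renal", "hepatic", "cardiac", "neural", "osseous", "lymphoid",
    "myeloid", "dermal", "pulmonary", "gastric", "pancreatic", "ocular",
    "splenic", "thymic", "vascular",
]
_KINDS = [
    "sarcoma", "carcinoma", "blastoma", "lymphoma", "leukemia",
    "neoplasm", "adenoma", "cytoma", "glioma", "myoma",
]

# Filler for generic notes: clinical-flavored, all absent from the criteria
# templates and from every concept name, so filler never matches a trial key.
_NOTE_FILLER = [
    "afebrile", "stable", "tolerating", "wellhydrated", "alert",
    "playful", "interactive", "appetite", "improving", "resting",
    "comfortable", "ambulating", "counts", "recovering", "reassuring",
    "unremarkable", "soft", "nontender", "clear", "regular",
]


def _concept_name(i: int) -> str:
    a = _ADJECTIVES[i % len(_ADJECTIVES)]
    t = _TISSUES[(i // len(_ADJECTIVES)) % len(_TISSUES)]
    k = _KINDS[(i // (len(_ADJECTIVES) * len(_TISSUES))) % len(_KINDS)]
    return f"{a} {t} {k}"


def _make_terminology(
    n_concepts: int,
) -> tuple[list[tuple[str, str, str, str]], list[tuple[str, str]], list[str]]:
    rows, icd9_rows, concept_ids = [], [], []
    for i in range(n_concepts):
        cid = str(90000000 + i)
        name = _concept_name(i)
        synonyms = [name]
        if i % 5 == 0:
            synonyms.append(f"{name} of childhood")
        rows.append((cid, name, "|".join(synonyms), "SYNTH"))
        concept_ids.append(cid)
        icd9_rows.append((f"{140 + i // 10}.{i % 10}", cid))
    return rows, icd9_rows, concept_ids


def _render_criteria(
    nct_id: str,
    open_date: dt.date,
    close_date: dt.date,
    age_lo_years: int,
    age_hi_years: int,
    gender: str,
    inclusion_terms: list[str],
    exclusion_terms: list[str],
) -> str:
    gender_label = {"male": "Male", "female": "Female", "any": "Both"}[gender]
    # demographic lines sit inside the inclusion section: the section
    # splitter keeps only text after the inclusion header
    lines = [
        f"NCT_ID: {nct_id}",
        f"OPEN_DATE: {open_date.isoformat()}",
        f"CLOSE_DATE: {close_date.isoformat()}",
        "",
        "Inclusion Criteria:",
        f"- Ages Eligible for Study: {age_lo_years} Years to "
        f"{age_hi_years} Years",
        f"- Genders Eligible for Study: {gender_label}",
    ]
    lines += [f"- Must have {term}." for term in inclusion_terms]
    lines.append("")
    lines.append("Exclusion Criteria:")
    lines += [f"- {term}." for term in exclusion_terms]
    return "\n".join(lines) + "\n"


def generate_world(config: SimConfig) -> World:
    """Build a complete synthetic corpus, byte-reproducible by seed."""
    rng = random.Random(config.seed)
    n_sig, n_excl = 4, 2
    term_rows, icd9_rows, concept_ids = _make_terminology(config.n_concepts)
    names = {row[0]: row[1] for row in term_rows}
    icd9_of = {cid: code for code, cid in icd9_rows}

    # Disjoint signatures when the pool allows; otherwise sampled freely.
    per_trial = n_sig + n_excl
    pool = list(concept_ids)
    rng.shuffle(pool)
    signatures: dict[str, list[str]] = {}
    exclusions: dict[str, list[str]] = {}
    trial_meta: list[dict] = []
    period_start = dt.date(2010, 1, 1)
    for t in range(config.n_trials):
        nct_id = f"NCT{90000000 + t:08d}"
        if (t + 1) * per_trial <= len(pool):
            chunk = pool[t * per_trial : (t + 1) * per_trial]
        else:
            chunk = rng.sample(concept_ids, per_trial)
        signatures[nct_id] = chunk[:n_sig]
        exclusions[nct_id] = chunk[n_sig:]
        open_date = period_start + dt.timedelta(days=rng.randrange(0, 200))
        close_date = open_date + dt.timedelta(days=rng.randrange(300, 550))
        if rng.random() < 0.15:
            gender = rng.choice(["male", "female"])
        else:
            gender = "any"
        trial_meta.append(
            {
                "nct_id": nct_id,
                "open_date": open_date,
                "close_date": close_date,
                "gender": gender,
                "age_lo": rng.choice([0, 1]),
                "age_hi": rng.choice([18, 21]),
            }
        )
    background = set(concept_ids) - {
        c for s in signatures.values() for c in s
    } - {c for e in exclusions.values() for c in e}
    background_ids = sorted(background)
    if not background_ids:  # tiny pools: reuse anything, separation degrades
        background_ids = sorted(concept_ids)

    # Patients: demographics first.
    n_fail = round(config.demographic_fail_rate * config.n_patients)
    patient_meta = []
    for p in range(config.n_patients):
        pid = f"P{p:04d}"
        gender = rng.choice(["male", "female"])
        if p < n_fail:
            # adults in a pediatric population: age out of every trial
            age_years = rng.randrange(25, 40)
        else:
            age_years = rng.randrange(2, 16)
        birth_date = period_start - dt.timedelta(
            days=round(age_years * 365.25) + rng.randrange(0, 300)
        )
        patient_meta.append(
            {"patient_id": pid, "gender": gender, "birth_date": birth_date}
        )

    # Eligibility: per trial, sample demographically compatible patients.
    k_eligible = max(1, round(config.eligible_fraction * config.n_patients))
    eligibility: set[tuple[str, str]] = set()
    eligible_trials: dict[str, list[str]] = {
        m["patient_id"]: [] for m in patient_meta
    }
    for tm in trial_meta:
        compatible = [
            m
            for m in patient_meta[n_fail:]
            if tm["gender"] == "any" or m["gender"] == tm["gender"]
        ]
        chosen = rng.sample(compatible, min(k_eligible, len(compatible)))
        for m in chosen:
            eligibility.add((tm["nct_id"], m["patient_id"]))
            eligible_trials[m["patient_id"]].append(tm["nct_id"])

    enrollments = {
        pair for pair in sorted(eligibility)
        if rng.random() < config.enrollment_prob
    }

    trial_by_id = {tm["nct_id"]: tm for tm in trial_meta}
    trials = [
        {
            "nct_id": tm["nct_id"],
            "open_date": tm["open_date"].isoformat(),
            "close_date": tm["close_date"].isoformat(),
            "text": _render_criteria(
                tm["nct_id"],
                tm["open_date"],
                tm["close_date"],
                tm["age_lo"],
                tm["age_hi"],
                tm["gender"],
                [names[c] for c in signatures[tm["nct_id"]]],
                [names[c] for c in exclusions[tm["nct_id"]]],
            ),
        }
        for tm in trial_meta
    ]

    def filler_sentence(n_words: int) -> str:
        words = [rng.choice(_NOTE_FILLER) for _ in range(n_words)]
        return " ".join(words)

    patients: list[dict] = []
    reference: list[dict] = []
    for m in patient_meta:
        pid = m["patient_id"]
        notes: list[dict] = []
        diagnoses: list[dict] = []
        my_trials = eligible_trials[pid]
        enroll_rows = []
        for nct_id in my_trials:
            tm = trial_by_id[nct_id]
            span = (tm["close_date"] - tm["open_date"]).days
            plant_day = tm["open_date"] + dt.timedelta(
                days=rng.randrange(0, max(1, span // 3))
            )
            enroll_day = tm["open_date"] + dt.timedelta(
                days=span // 2 + rng.randrange(0, max(1, span // 3))
            )
            sentences = []
            for cid in signatures[nct_id]:
                if rng.random() < config.signal:
                    sentences.append(f"Patient presents with {names[cid]}.")
            for cid in background_ids:
                if rng.random() < config.distractor_rate:
                    sentences.append(f"History notable for {names[cid]}.")
            sentences.append(filler_sentence(rng.randrange(5, 15)) + ".")
            notes.append(
                {"text": " ".join(sentences), "date": plant_day.isoformat()}
            )
            if (nct_id, pid) in enrollments:
                enroll_rows.append(
                    {"nct_id": nct_id, "date": enroll_day.isoformat()}
                )
            # a structured diagnosis echoing the first signature concept
            dx = signatures[nct_id][0]
            diagnoses.append(
                {
                    "text": names[dx],
                    "icd9": icd9_of.get(dx),
                    "date": plant_day.isoformat(),
                }
            )
        if not my_trials:
            for _ in range(rng.randrange(1, 3)):
                cid = rng.choice(background_ids)
                diagnoses.append(
                    {
                        "text": names[cid],
                        "icd9": icd9_of.get(cid),
                        "date": (
                            period_start + dt.timedelta(days=rng.randrange(0, 600))
                        ).isoformat(),
                    }
                )
        n_notes = rng.randrange(
            config.notes_per_patient[0], config.notes_per_patient[1] + 1
        )
        for _ in range(max(0, n_notes - len(notes))):
            date = period_start + dt.timedelta(days=rng.randrange(0, 650))
            length = rng.randrange(
                config.note_length[0], config.note_length[1] + 1
            )
            sentences = []
            remaining = length
            for cid in background_ids:
                if rng.random() < config.distractor_rate:
                    sentences.append(f"History notable for {names[cid]}.")
                    remaining -= 4
            while remaining > 0:
                n_words = min(remaining, rng.randrange(6, 14))
                sentences.append(filler_sentence(n_words) + ".")
                remaining -= n_words
            notes.append({"text": " ".join(sentences), "date": date.isoformat()})
        patients.append(
            {
                "patient_id": pid,
                "birth_date": m["birth_date"].isoformat(),
                "gender": m["gender"],
                "diagnoses": diagnoses,
                "notes": notes,
                "enrollments": enroll_rows,
            }
        )
        for row in enroll_rows:
            reference.append(
                {
                    "patient_id": pid,
                    "nct_id": row["nct_id"],
                    "enrollment_date": row["date"],
                }
            )

    return World(
        config=config,
        terminology_rows=term_rows,
        icd9_rows=icd9_rows,
        trials=trials,
        patients=patients,
        reference=reference,
        truth=SimTruth(
            eligibility=frozenset(eligibility),
            enrollments=frozenset(enrollments),
        ),
        signatures=signatures,
        exclusions=exclusions,
    )


# ---------------------------------------------------------------------------
# Controlled degradation for robustness testing

_CORRUPT_OPS = ("typo_injection", "negation_flip", "date_shift")


def corrupt_world(world: World, op: str, rate: float, seed: int) -> World:
    """Return a degraded copy of the world; ``rate`` 0 is the identity.

    * ``typo_injection``: each word of each note is independently mangled
      (a letter replaced) with probability ``rate``, breaking dictionary
      matches the way misspellings do;
    * ``negation_flip``: each planted concept mention in a note gains a
      leading "no " with probability ``rate``, emulating wrong assertion
      status;
    * ``date_shift``: each note is pushed 400 days later with probability
      ``rate``, emulating entries recorded after the decision window.
    """
    if op not in _CORRUPT_OPS:
        raise ValueError(f"unknown corruption op {op!r}")
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must be in [0, 1]")
    rng = random.Random(seed)
    concept_names = sorted(
        (row[1] for row in world.terminology_rows), key=len, reverse=True
    )
    name_re = re.compile(
        "|".join(re.escape(n) for n in concept_names), re.IGNORECASE
    )

    def mangle_word(word: str) -> str:
        if len(word) < 2 or not word.isalpha():
            return word
        i = rng.randrange(len(word))
        repl = "z" if word[i].lower() != "z" else "q"
        return word[:i] + repl + word[i + 1 :]

    def corrupt_note(note: dict) -> dict:
        text, date = note["text"], note["date"]
        if op == "typo_injection" and rate > 0:
            text = " ".join(
                mangle_word(w) if rng.random() < rate else w
                for w in text.split(" ")
            )
        elif op == "negation_flip" and rate > 0:
            text = name_re.sub(
                lambda m: ("no " + m.group(0))
                if rng.random() < rate
                else m.group(0),
                text,
            )
        elif op == "date_shift" and rng.random() < rate:
            date = (
                dt.date.fromisoformat(date) + dt.timedelta(days=400)
            ).isoformat()
        return {"text": text, "date": date}

    patients = [
        {**p, "notes": [corrupt_note(n) for n in p["notes"]]}
        for p in world.patients
    ]
    return replace(world, patients=patients)
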