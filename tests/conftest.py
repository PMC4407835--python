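import datetime as dt
from importlib import resources
from pathlib import Path

import pytest

import espre as E


def data_file(name: str) -> str:
    return str(resources.files("espre").joinpath("data", name))


@pytest.fixture(scope="session")
def bundled_index() -> E.TerminologyIndex:
    return E.load_terminology(data_file("terminology.tsv"))


@pytest.fixture(scope="session")
def bundled_icd9(bundled_index) -> E.Icd9Map:
    return E.load_icd9_map(data_file("icd9_to_concept.tsv"), bundled_index)


@pytest.fixture(scope="session")
def triggers() -> E.TriggerLexicon:
    return E.default_triggers()


@pytest.fixture(scope="session")
def mini_index() -> E.TerminologyIndex:
    """Five-phrase dictionary for oracle comparisons on tiny texts."""
    index = E.TerminologyIndex()
    for cid, pref, syns in [
        ("C1", "cns disease", ("central nervous system disease",)),
        ("C2", "fever", ()),
        ("C3", "leukemia", ()),
        ("C4", "acute lymphoblastic leukemia", ()),
        ("C5", "disease", ()),
    ]:
        index.add(E.Concept(cid, pref, (pref,) + syns))
    return index


def make_trial(
    nct_id="NCT00000001",
    open_date=dt.date(2010, 1, 1),
    close_date=dt.date(2011, 1, 1),
    age=None,
    gender=E.Gender.ANY,
    keys=(),
) -> E.TrialProfile:
    return E.TrialProfile(
        nct_id=nct_id,
        age=age or E.AgeBounds(),
        gender=gender,
        open_date=open_date,
        close_date=close_date,
        vector=E.TermVector.from_keys(keys),
    )


def make_record(
    patient_id="P1",
    birth_date=dt.date(2000, 6, 1),
    gender="female",
    notes=(),
    diagnoses=(),
    enrollments=(),
) -> E.PatientRecord:
    entries = [
        E.DataEntry(kind="note", text=text, timestamp=date)
        for text, date in notes
    ] + [
        E.DataEntry(kind="diagnosis", text=text, icd9=icd9, timestamp=date)
        for text, icd9, date in diagnoses
    ]
    return E.PatientRecord(
        patient_id=patient_id,
        birth_date=birth_date,
        gender=gender,
        entries=entries,
        enrollments=list(enrollments),
    )


@pytest.fixture(scope="session")
def recovery_corpus(tmp_path_factory):
    """Small planted world with perfect signal, fully enrolled."""
    cfg = E.SimConfig(
        seed=11,
        n_trials=8,
        n_patients=40,
        n_concepts=80,
        notes_per_patient=(2, 6),
        note_length=(20, 60),
        eligible_fraction=0.1,
        enrollment_prob=1.0,
        signal=1.0,
        distractor_rate=0.0,
    )
    world = E.generate_world(cfg)
    out = tmp_path_factory.mktemp("recovery_world")
    paths = world.write(out)
    rc = E.RunConfig(
        trials_dir=str(paths["trials_dir"]),
        patients=str(paths["patients"]),
        terminology=str(paths["terminology"]),
        icd9_map=str(paths["icd9_map"]),
        reference=str(paths["reference"]),
        out_dir=str(out / "out"),
        seed=5,
    )
    return world, rc, E.load_corpus(rc)
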