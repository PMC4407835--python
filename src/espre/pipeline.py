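"""End-to-end orchestration: extract → match → evaluate, reproducibly.

A run is described by a flat key:value config (YAML-compatible) naming the
input files and the matching parameters. The trial-centered run ranks the
patient population for every trial; the patient-centered run ranks the open
trials for every patient, reported both on the sub-population of patients
with at least one historical enrollment and on the full population (where a
patient without enrollments costs a review of their whole post-filter trial
list). Both runs share one profile builder, so the underlying trial–patient
score matrix is identical across directions.

Every artifact (ranked TSVs, per-anchor metrics CSV, JSON summary) is a
pure function of config + seed.
"""

from __future__ import annotations

import csv
import datetime as dt
import json
import logging
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path

import yaml

from .criteria_parser import TrialProfile, build_trial_profile, parse_trial_file
from .evaluation import (
    ReferenceStandard,
    ScreeningMetrics,
    aggregate,
    expected_random_workload,
    load_reference,
    metrics_at_workload,
    paired_workload_test,
    workload,
)
from .matching import (
    PATIENTS_FOR_TRIAL,
    TRIALS_FOR_PATIENT,
    RankedList,
    baseline_shuffle,
    rank_patients_for_trial,
    rank_trials_for_patient,
    write_ranked_tsv,
)
from .patient_profile import PatientRecord, ProfileBuilder, load_patients
from .terminology import load_icd9_map, load_terminology
from .text_processing import (
    DEFAULT_NEGATION_WINDOW,
    default_triggers,
    load_triggers,
)

__all__ = ["RunConfig", "RunConfigError", "Corpus", "load_corpus",
           "run_trial_centered", "run_patient_centered"]

logger = logging.getLogger(__name__)


class RunConfigError(ValueError):
    """Raised on unknown keys, missing paths, or bad parameter values."""


@dataclass
class RunConfig:
    trials_dir: str
    patients: str
    terminology: str
    reference: str
    out_dir: str
    icd9_map: str | None = None
    triggers: str | None = None
    lam: float = 1.0
    negation_window: int = DEFAULT_NEGATION_WINDOW
    include_raw_tokens: bool = True
    negex_in_exclusion: bool = True
    use_diagnoses: bool = True
    use_notes: bool = True
    seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Load a flat ``key: value`` config file (YAML-compatible syntax);
        unknown keys are rejected."""
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        if not isinstance(raw, dict):
            raise RunConfigError(f"{path}: config must be key: value pairs")
        known = {f.name for f in dc_fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise RunConfigError(
                f"{path}: unknown config keys {sorted(unknown)}"
            )
        try:
            config = cls(**raw)
        except TypeError as exc:
            raise RunConfigError(f"{path}: {exc}") from exc
        config.validate()
        return config

    def validate(self) -> None:
        if self.lam < 0:
            raise RunConfigError("lam must be non-negative")
        if self.negation_window < 1:
            raise RunConfigError("negation_window must be >= 1")
        for name in ("trials_dir", "patients", "terminology", "reference"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise RunConfigError(f"{name} path does not exist: {p}")
        for name in ("icd9_map", "triggers"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise RunConfigError(f"{name} path does not exist: {p}")


@dataclass
class Corpus:
    """Loaded inputs plus the shared profile builder."""

    trials: list[TrialProfile]
    records: list[PatientRecord]
    builder: ProfileBuilder
    reference: ReferenceStandard
    config: RunConfig = field(repr=False, default=None)


def load_corpus(config: RunConfig) -> Corpus:
    index = load_terminology(config.terminology)
    icd9_map = (
        load_icd9_map(config.icd9_map, index) if config.icd9_map else None
    )
    triggers = (
        load_triggers(config.triggers) if config.triggers
        else default_triggers()
    )
    trials = []
    for path in sorted(Path(config.trials_dir).glob("*.txt")):
        criteria = parse_trial_file(path)
        trials.append(
            build_trial_profile(
                criteria,
                index,
                triggers,
                window=config.negation_window,
                include_raw_tokens=config.include_raw_tokens,
                negex_in_exclusion=config.negex_in_exclusion,
            )
        )
    trial_map = {t.nct_id: t for t in trials}
    records = load_patients(config.patients, trials=trial_map)
    builder = ProfileBuilder(
        index,
        icd9_map,
        triggers,
        window=config.negation_window,
        include_raw_tokens=config.include_raw_tokens,
        use_diagnoses=config.use_diagnoses,
        use_notes=config.use_notes,
    )
    reference = load_reference(config.reference)
    logger.info(
        "corpus loaded: %d trials, %d patients, %d reference matches",
        len(trials), len(records), len(reference),
    )
    return Corpus(
        trials=trials, records=records, builder=builder,
        reference=reference, config=config,
    )


def _evaluate_anchor(
    ranked: RankedList,
    positives: frozenset[str],
    n_universe: int,
    seed: int,
) -> tuple[ScreeningMetrics, int, float]:
    """Metrics for one anchor plus its shuffled-baseline and expected
    baseline workloads over the same post-filter pool."""
    wl = workload(ranked, positives, n_universe)
    metrics = metrics_at_workload(
        wl, len(positives), n_universe, anchor_id=ranked.anchor_id
    )
    shuffled = baseline_shuffle(
        ranked.candidate_ids, seed, ranked.direction, ranked.anchor_id
    )
    wl_base = workload(shuffled, positives, n_universe)
    n_found = sum(1 for p in positives if ranked.rank_of(p) is not None)
    if n_found < len(positives):
        expected = float(n_universe)  # filter error forces full review
    else:
        expected = expected_random_workload(len(ranked), n_found)
    return metrics, wl_base, expected


def _write_metrics_csv(path: Path, rows: list[ScreeningMetrics]) -> None:
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["anchor_id", "workload", "n_candidates", "n_positives",
             "precision", "specificity", "recall", "npv"]
        )
        for m in rows:
            writer.writerow(
                [m.anchor_id, m.workload, m.n_candidates, m.n_positives,
                 f"{m.precision:.6f}", f"{m.specificity:.6f}",
                 f"{m.recall:.6f}", f"{m.npv:.6f}"]
            )


def _summarize(
    metrics: list[ScreeningMetrics],
    baseline_wl: list[int],
    expected_wl: list[float],
) -> dict:
    summary = aggregate(metrics).as_dict()
    summary["baseline_mean_workload"] = (
        sum(baseline_wl) / len(baseline_wl) if baseline_wl else 0.0
    )
    summary["baseline_expected_workload"] = (
        sum(expected_wl) / len(expected_wl) if expected_wl else 0.0
    )
    wl = [m.workload for m in metrics]
    if len(wl) >= 2:
        summary["paired_p_vs_baseline"] = paired_workload_test(
            wl, baseline_wl
        )
    else:
        summary["paired_p_vs_baseline"] = None
    return summary


def run_trial_centered(config: RunConfig, corpus: Corpus | None = None) -> dict:
    """Rank the patient population for every trial and score workloads.

    Writes ``trial_centered/ranked/<nct_id>.ranked.tsv``, a per-trial
    metrics CSV, and a JSON summary with baseline comparison and the paired
    workload test. Returns the summary dict.
    """
    if corpus is None:
        corpus = load_corpus(config)
    out = Path(config.out_dir) / "trial_centered"
    ranked_dir = out / "ranked"
    ranked_dir.mkdir(parents=True, exist_ok=True)
    n_universe = len(corpus.records)
    all_metrics, baseline_wl, expected_wl = [], [], []
    for i, trial in enumerate(sorted(corpus.trials, key=lambda t: t.nct_id)):
        ranked = rank_patients_for_trial(
            trial, corpus.records, corpus.builder, config.lam
        )
        write_ranked_tsv(ranked, ranked_dir)
        if len(ranked) == 0:
            logger.warning(
                "trial %s: no candidates passed the demographic filter",
                trial.nct_id,
            )
            all_metrics.append(
                ScreeningMetrics(trial.nct_id, 0, 0, 0, 0.0, 1.0)
            )
            baseline_wl.append(0)
            expected_wl.append(0.0)
            continue
        positives = corpus.reference.positives_for_trial(trial.nct_id)
        metrics, wl_base, expected = _evaluate_anchor(
            ranked, positives, n_universe, config.seed + i
        )
        all_metrics.append(metrics)
        baseline_wl.append(wl_base)
        expected_wl.append(expected)
    _write_metrics_csv(out / "metrics.csv", all_metrics)
    summary = {
        "direction": PATIENTS_FOR_TRIAL,
        "n_universe": n_universe,
        "summary": _summarize(all_metrics, baseline_wl, expected_wl),
    }
    (out / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n",
        encoding="utf-8",
    )
    return summary


def run_patient_centered(
    config: RunConfig, corpus: Corpus | None = None
) -> dict:
    """Rank the open trials for every patient; report sub- and
    full-population summaries.

    The sub-population covers patients with at least one historical
    enrollment; the full population adds patients with none, whose
    workload is their entire post-filter trial list.
    """
    if corpus is None:
        corpus = load_corpus(config)
    out = Path(config.out_dir) / "patient_centered"
    ranked_dir = out / "ranked"
    ranked_dir.mkdir(parents=True, exist_ok=True)
    n_universe = len(corpus.trials)
    all_metrics, baseline_wl, expected_wl = [], [], []
    enrolled_idx = []
    for i, record in enumerate(
        sorted(corpus.records, key=lambda r: r.patient_id)
    ):
        ranked = rank_trials_for_patient(
            record, corpus.trials, corpus.builder, config.lam
        )
        write_ranked_tsv(ranked, ranked_dir)
        positives = corpus.reference.positives_for_patient(record.patient_id)
        if len(ranked) == 0 and not positives:
            logger.warning(
                "patient %s: no trials passed the demographic filter",
                record.patient_id,
            )
            all_metrics.append(
                ScreeningMetrics(record.patient_id, 0, 0, 0, 0.0, 1.0)
            )
            baseline_wl.append(0)
            expected_wl.append(0.0)
            continue
        metrics, wl_base, expected = _evaluate_anchor(
            ranked, positives, n_universe, config.seed + 10_000 + i
        )
        if positives:
            enrolled_idx.append(len(all_metrics))
        all_metrics.append(metrics)
        baseline_wl.append(wl_base)
        expected_wl.append(expected)
    _write_metrics_csv(out / "metrics.csv", all_metrics)
    sub_metrics = [all_metrics[i] for i in enrolled_idx]
    sub_base = [baseline_wl[i] for i in enrolled_idx]
    sub_exp = [expected_wl[i] for i in enrolled_idx]
    summary = {
        "direction": TRIALS_FOR_PATIENT,
        "n_universe": n_universe,
        "full_population": _summarize(all_metrics, baseline_wl, expected_wl),
        "sub_population": (
            _summarize(sub_metrics, sub_base, sub_exp) if sub_metrics else None
        ),
    }
    (out / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n",
        encoding="utf-8",
    )
    return summary
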