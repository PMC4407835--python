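import datetime as dt
import math

import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import espre as E
from conftest import make_record, make_trial

D = dt.date


def V(*keys):
    return E.TermVector.from_keys(keys)


class TestDemographicsFilter:
    def test_no_notes_in_window_fails(self, ):
        trial = make_trial(open_date=D(2010, 1, 1), close_date=D(2011, 1, 1))
        record = make_record(notes=[("x", D(2011, 6, 1))])
        assert not E.demographics_filter(record, trial)

    def test_gender_mismatch_fails(self):
        trial = make_trial(gender=E.Gender.FEMALE)
        record = make_record(
            gender="male", notes=[("x", D(2010, 6, 1))]
        )
        assert not E.demographics_filter(record, trial)

    def test_age_overlap_with_in_window_note_passes(self):
        # patient aged 20 at the window opening, trial accepts 1-21 years
        trial = make_trial(
            age=E.AgeBounds(min_days=365, max_days=round(21 * 365.25)),
            open_date=D(2010, 1, 1),
            close_date=D(2010, 12, 31),
        )
        record = make_record(
            birth_date=D(1990, 1, 1), notes=[("x", D(2010, 6, 1))]
        )
        assert E.demographics_filter(record, trial)
        # brute-force day-by-day age scan agrees
        days_ok = any(
            trial.age.contains(
                (trial.open_date + dt.timedelta(days=k) - record.birth_date).days
            )
            for k in range((trial.close_date - trial.open_date).days + 1)
        )
        assert days_ok

    def test_age_outside_bounds_fails(self):
        trial = make_trial(age=E.AgeBounds(min_days=0, max_days=6574))
        record = make_record(
            birth_date=D(1980, 1, 1), notes=[("x", D(2010, 6, 1))]
        )
        assert not E.demographics_filter(record, trial)

    def test_born_after_window_fails(self):
        trial = make_trial(open_date=D(2010, 1, 1), close_date=D(2010, 6, 1))
        record = make_record(
            birth_date=D(2011, 1, 1), notes=[("x", D(2011, 2, 1))]
        )
        assert not E.demographics_filter(record, trial)


class TestMatchScore:
    def test_identical_vectors_score_one(self):
        score = E.match_score(V("A", "B"), V("A", "B"))
        assert score.value == 1.0 and score.contradictions == 0

    def test_disjoint_vectors_score_zero(self):
        assert E.match_score(V("A", "B"), V("C", "D")).value == 0.0

    def test_contradiction_penalty_hand_example(self):
        score = E.match_score(V("A", "NEGB"), V("A", "B"), lam=1.0)
        assert score.shared_terms == 1
        assert score.contradictions == 1
        assert score.value == pytest.approx(0.0)

    def test_empty_vector_scores_zero(self):
        assert E.match_score(V(), V("A")).value == 0.0

    def test_negative_lambda_rejected(self):
        with pytest.raises(ValueError):
            E.match_score(V("A"), V("A"), lam=-0.5)

    def test_lambda_zero_is_pure_cosine(self):
        score = E.match_score(V("A", "NEGB"), V("A", "B"), lam=0.0)
        assert score.value == pytest.approx(0.5)

    keysets = st.sets(
        st.sampled_from(["1", "2", "3", "NEG1", "NEG2", "w:x"]), max_size=5
    ).map(lambda s: E.TermVector.from_keys(s))

    @settings(derandomize=True, max_examples=150)
    @given(t=keysets, p=keysets, lam=st.floats(0, 2))
    def test_symmetry_and_cosine_bound(self, t, p, lam):
        ab = E.match_score(t, p, lam)
        ba = E.match_score(p, t, lam)
        assert ab.value == pytest.approx(ba.value)
        assert ab.contradictions == ba.contradictions
        if len(t) and len(p):
            cosine = ab.shared_terms / math.sqrt(len(t) * len(p))
            assert ab.value <= cosine + 1e-12
            assert cosine <= 1 + 1e-12

    def test_value_one_iff_equal_nonempty_and_no_penalty(self):
        assert E.match_score(V("A"), V("A")).value == 1.0
        assert E.match_score(V("A", "B"), V("A")).value < 1.0


class TestRanking:
    def _corpus(self, bundled_index, triggers):
        trial = make_trial(keys=("91857003", "w:relapsed"))
        builder = E.ProfileBuilder(bundled_index, None, triggers)
        strong = make_record(
            patient_id="P2",
            notes=[("acute lymphoblastic leukemia relapsed", D(2010, 6, 1))],
        )
        weak = make_record(
            patient_id="P1",
            notes=[("fever only", D(2010, 6, 1))],
        )
        adult = make_record(
            patient_id="P3",
            birth_date=D(1950, 1, 1),
            notes=[("acute lymphoblastic leukemia", D(2010, 6, 1))],
        )
        trial_adultproof = make_trial(
            keys=("91857003",),
            age=E.AgeBounds(min_days=0, max_days=8000),
        )
        return trial, trial_adultproof, builder, strong, weak, adult

    def test_filtered_patient_never_ranked(self, bundled_index, triggers):
        _, trial, builder, strong, weak, adult = self._corpus(
            bundled_index, triggers
        )
        ranked = E.rank_patients_for_trial(
            trial, [strong, weak, adult], builder
        )
        assert adult.patient_id not in ranked.candidate_ids

    def test_scores_sorted_descending(self, bundled_index, triggers):
        trial, _, builder, strong, weak, _ = self._corpus(
            bundled_index, triggers
        )
        ranked = E.rank_patients_for_trial(trial, [weak, strong], builder)
        assert ranked.candidate_ids == ["P2", "P1"]
        values = [s.value for _, s in ranked.items]
        assert values == sorted(values, reverse=True)

    def test_equal_scores_tie_break_by_id(self, bundled_index, triggers):
        trial = make_trial(keys=("91857003",))
        builder = E.ProfileBuilder(bundled_index, None, triggers)
        twins = [
            make_record(patient_id=pid, notes=[("well child", D(2010, 6, 1))])
            for pid in ["P9", "P3", "P5"]
        ]
        ranked = E.rank_patients_for_trial(trial, twins, builder)
        assert ranked.candidate_ids == ["P3", "P5", "P9"]

    def test_rank_trials_for_patient_symmetric(
        self, bundled_index, triggers
    ):
        builder = E.ProfileBuilder(bundled_index, None, triggers)
        record = make_record(
            notes=[("acute lymphoblastic leukemia", D(2010, 6, 1))]
        )
        t_match = make_trial(nct_id="NCT00000002", keys=("91857003",))
        t_other = make_trial(nct_id="NCT00000003", keys=("38661007",))
        t_closed = make_trial(
            nct_id="NCT00000004",
            keys=("91857003",),
            open_date=D(2012, 1, 1),
            close_date=D(2012, 6, 1),
        )
        ranked = E.rank_trials_for_patient(
            record, [t_other, t_match, t_closed], builder
        )
        assert ranked.candidate_ids[0] == "NCT00000002"
        assert "NCT00000004" not in ranked.candidate_ids  # no in-window note

    def test_empty_pool_gives_empty_list(self, bundled_index, triggers):
        builder = E.ProfileBuilder(bundled_index, None, triggers)
        record = make_record(notes=[])
        ranked = E.rank_trials_for_patient(
            record, [make_trial(keys=("91857003",))], builder
        )
        assert len(ranked) == 0


class TestBaselineShuffle:
    def test_same_seed_reproduces_order(self):
        ids = [f"P{i}" for i in range(10)]
        a = E.baseline_shuffle(ids, seed=42)
        b = E.baseline_shuffle(ids, seed=42)
        assert a.candidate_ids == b.candidate_ids

    def test_single_candidate(self):
        assert E.baseline_shuffle(["P1"], seed=0).candidate_ids == ["P1"]

    def test_rank1_uniform_over_seeds(self):
        # each of 3 candidates should lead in about 1/3 of shuffles
        counts = {"A": 0, "B": 0, "C": 0}
        n = 3000
        for seed in range(n):
            counts[E.baseline_shuffle(["A", "B", "C"], seed).candidate_ids[0]] += 1
        chi2 = sum((c - n / 3) ** 2 / (n / 3) for c in counts.values())
        assert chi2 < stats.chi2.ppf(0.999, df=2)


class TestRankedIO:
    def test_tsv_round_trip(self, tmp_path):
        ranked = E.RankedList(
            direction="patients_for_trial",
            anchor_id="NCT00000001",
            items=[
                ("P1", E.MatchScore(0.75, 3, 0)),
                ("P2", E.MatchScore(0.25, 1, 1)),
            ],
        )
        path = E.write_ranked_tsv(ranked, tmp_path)
        loaded = E.read_ranked_tsv(path)
        assert loaded.anchor_id == "NCT00000001"
        assert loaded.candidate_ids == ["P1", "P2"]
        assert loaded.items[0][1].value == pytest.approx(0.75)
        assert loaded.items[1][1].contradictions == 1
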