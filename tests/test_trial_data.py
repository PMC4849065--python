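"""Data model, I/O, dropout summaries, scenario reclassification, survival
coding and mean profiles."""

import io

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from jmdropout.trial_data import (
    Cause,
    Measurement,
    PatientRecord,
    TrialDataError,
    TrialDataset,
    apply_scenario,
    mean_profiles,
    read_trial_long,
    summarize_dropout,
    to_survival_records,
    write_trial_long,
)


def _mini_dataset(values=(3.0, 2.5)):
    recs = []
    for i, arm in enumerate((1, 0)):
        pid = f"p{i}"
        recs.append(
            PatientRecord(
                patient_id=pid,
                arm=arm,
                measurements=[
                    Measurement(pid, t, values[i] + 0.125 * j)
                    for j, t in enumerate((0.0, 20.0, 40.0))
                ],
                event_time=40.0,
                cause=Cause.COMPLETED,
            )
        )
    return TrialDataset(recs, schedule=[0, 20, 40], admin_censor_time=40.0)


class TestReadWrite:
    def test_round_trip_is_identity(self, tmp_path, small_trial):
        paths = write_trial_long(small_trial, tmp_path)
        back = read_trial_long(*paths)
        assert back == small_trial

    def test_non_integer_scores_preserved_exactly(self, tmp_path):
        d = _mini_dataset(values=(3.123456789012345, 2.0))
        back = read_trial_long(*write_trial_long(d, tmp_path))
        assert back.records[0].measurements[0].value == 3.123456789012345

    def test_empty_dataset_writes_header_only_tables(self, tmp_path):
        d = TrialDataset([], schedule=[0, 20, 40], admin_censor_time=40.0)
        meas, events = write_trial_long(d, tmp_path)
        assert pd.read_csv(meas).empty and pd.read_csv(events).empty

    @pytest.mark.parametrize(
        "meas_rows, event_rows, match",
        [
            # measurement after the event time
            ("pA,1,0,3\npA,1,120,3", "pA,60,good", "pA"),
            # unknown cause string
            ("pA,1,0,3", "pA,60,withdrew", "allowed"),
            # duplicate (patient, time) rows
            ("pA,1,0,3\npA,1,0,4", "pA,60,good", "duplicate"),
            # unmatched ids
            ("pA,1,0,3", "pB,60,good", "pA|pB"),
        ],
    )
    def test_malformed_tables_are_rejected_naming_the_patient(
        self, meas_rows, event_rows, match
    ):
        meas = io.StringIO("patient_id,arm,time_min,score\n" + meas_rows)
        events = io.StringIO("patient_id,event_time_min,cause\n" + event_rows)
        with pytest.raises(TrialDataError, match=match):
            read_trial_long(meas, events)


class TestDropoutSummary:
    def test_published_count_table_percentages(self, table1_trial):
        s = summarize_dropout(table1_trial)
        c, p = s.counts, s.percents
        assert c.loc["dropout"].tolist() == [63, 37, 100]
        assert round(p.loc["dropout", "active"], 1) == 25.4
        assert round(p.loc["dropout", "control"], 1) == 14.6
        assert round(p.loc["dropout", "total"], 1) == 19.9
        assert c.loc["case1_good", "total"] == 15
        assert round(p.loc["case1_good", "total"], 1) == 15.0
        assert round(p.loc["completed", "active"], 1) == 74.6
        assert round(p.loc["baseline", "active"], 1) == 49.4

    def test_empty_dataset_gives_zero_counts_blank_percentages(self):
        s = summarize_dropout(TrialDataset([], schedule=[0], admin_censor_time=1))
        assert (s.counts == 0).all().all()
        assert s.percents.isna().all().all()


class TestScenarios:
    def test_paper_allocation_reproduces_published_scenario1_counts(
        self, table1_trial, paper_allocation
    ):
        out = apply_scenario(table1_trial, 1, explicit_allocation=paper_allocation)
        c = summarize_dropout(out).counts
        assert c.loc["case1_good", "total"] == 25
        assert c.loc["case2_poor", "total"] == 14
        assert c.loc["case3_unknown", "total"] == 0

    def test_scenario2_reproduces_published_counts(self, table1_trial):
        c = summarize_dropout(apply_scenario(table1_trial, 2)).counts
        assert c.loc["case1_good", "total"] == 15
        assert c.loc["case2_poor", "total"] == 24

    def test_no_unknowns_is_a_noop(self, table1_trial):
        base = apply_scenario(table1_trial, 2)
        assert apply_scenario(base, 1, seed=3) == base
        assert apply_scenario(base, 2) == base

    def test_allocation_referencing_non_unknown_patient_rejected(self, table1_trial):
        completer = next(
            r.patient_id for r in table1_trial.records if r.cause is Cause.COMPLETED
        )
        with pytest.raises(TrialDataError, match="not unknown"):
            apply_scenario(table1_trial, 1, explicit_allocation={completer: "good"})

    def test_uneven_allocation_rejected(self, table1_trial, paper_allocation):
        skew = {pid: "good" for pid in paper_allocation}
        with pytest.raises(TrialDataError, match="split"):
            apply_scenario(table1_trial, 1, explicit_allocation=skew)

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(
        n_unknown=st.tuples(st.integers(0, 9), st.integers(0, 9)),
        seed=st.integers(0, 2**31 - 1),
    )
    def test_scenario1_conserves_and_splits_evenly(self, n_unknown, seed):
        recs = []
        k = 0
        for arm, n_u in zip((1, 0), n_unknown):
            for cause in [Cause.UNKNOWN] * n_u + [Cause.GOOD, Cause.COMPLETED]:
                pid = f"q{k}"
                k += 1
                et = 40.0 if cause is Cause.COMPLETED else 25.0
                recs.append(
                    PatientRecord(
                        pid, arm, [Measurement(pid, 0.0, 4.0)], et, cause
                    )
                )
        d = TrialDataset(recs, schedule=[0, 20, 40], admin_censor_time=40.0)
        before = summarize_dropout(d).counts
        out = apply_scenario(d, 1, seed=seed)
        after = summarize_dropout(out).counts
        for col in ("active", "control"):
            assert (
                after.loc["case1_good", col] + after.loc["case2_poor", col]
                == before.loc[["case1_good", "case2_poor", "case3_unknown"], col].sum()
            )
            n_u = before.loc["case3_unknown", col]
            newly_good = after.loc["case1_good", col] - before.loc["case1_good", col]
            assert abs(newly_good - (n_u - newly_good)) <= 1


class TestSurvivalCoding:
    def test_completer_is_censored_at_final_visit(self, table1_trial):
        recs = to_survival_records(table1_trial, K=1)
        completers = [s for s in recs if s.status == 0]
        assert all(s.time == 240.0 for s in completers)

    def test_scenario2_counts_k2(self, table1_trial):
        recs = to_survival_records(apply_scenario(table1_trial, 2), K=2)
        counts = pd.Series([s.status for s in recs]).value_counts()
        assert counts[1] == 15 and counts[2] == 24 and counts[0] == 463

    def test_k1_default_and_censor_unrelated_variant(self, table1_trial):
        assert sum(s.status for s in to_survival_records(table1_trial, K=1)) == 100
        recs = to_survival_records(table1_trial, K=1, informative_unrelated=False)
        assert sum(s.status for s in recs) == 39

    def test_unknown_with_k2_rejected(self, table1_trial):
        with pytest.raises(TrialDataError, match="apply_scenario"):
            to_survival_records(table1_trial, K=2)

    def test_one_record_per_patient(self, small_trial):
        recs = to_survival_records(small_trial, K=1)
        assert len(recs) == len(small_trial)
        assert len({s.patient_id for s in recs}) == len(small_trial)


class TestMeanProfiles:
    def test_constant_values_give_constant_means(self):
        d = _mini_dataset(values=(3.0, 3.0))
        for r in d.records:
            r.measurements = [Measurement(r.patient_id, m.time, 3.0) for m in r.measurements]
        prof = mean_profiles(d, "completion")
        assert (prof["mean"] == 3.0).all()

    def test_dropout_contributes_only_before_event(self):
        d = _mini_dataset()
        pid = "drop"
        d.records.append(
            PatientRecord(
                pid,
                1,
                [Measurement(pid, 0.0, 5.0), Measurement(pid, 20.0, 5.0)],
                25.0,
                Cause.GOOD,
            )
        )
        d.validate()
        prof = mean_profiles(d, "completion").set_index(["group", "time_min"])
        assert prof.loc[("dropout", 0.0), "count"] == 1
        assert prof.loc[("dropout", 20.0), "count"] == 1
        assert prof.loc[("dropout", 40.0), "count"] == 0
        assert np.isnan(prof.loc[("dropout", 40.0), "mean"])

    def test_by_cause_grouping_covers_all_causes(self, small_trial):
        prof = mean_profiles(small_trial, "cause", by_arm=True)
        present = {r.cause.value for r in small_trial.records}
        assert set(prof["group"]) == present
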