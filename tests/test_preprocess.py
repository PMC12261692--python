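import numpy as np
import pandas as pd
import pytest

from hbmon import SyntheticConfig, generate_cohort
from hbmon.preprocess import (
    FilterRules,
    apply_inclusion_filters,
    build_model_rows,
    deduplicate_same_day,
    holdout_split,
)
from conftest import make_cohort_frame


class TestDeduplication:
    def test_first_in_file_order_survives(self):
        cohort = make_cohort_frame(
            [
                ("A", "2013-01-01", 8.0, "female", 1960),
                ("A", "2013-01-01", 8.4, "female", 1960),
                ("A", "2013-02-01", 8.2, "female", 1960),
            ]
        )
        out, rec = deduplicate_same_day(cohort)
        day1 = out.measurements[out.measurements["date"] == "2013-01-01"]
        assert len(day1) == 1 and day1["hb_mmol_l"].iloc[0] == 8.0
        assert rec.n_measurements_before - rec.n_measurements_after == 1

    def test_no_duplicates_is_identity(self, small_cohort):
        out, rec = deduplicate_same_day(small_cohort)
        assert rec.n_measurements_after == rec.n_measurements_before

    def test_triple_same_day_keeps_exactly_one(self):
        cohort = make_cohort_frame(
            [("A", "2013-01-01", v, "male", 1950) for v in (8.0, 8.1, 8.2)]
        )
        out, rec = deduplicate_same_day(cohort)
        assert len(out.measurements) == 1
        assert rec.n_measurements_before - rec.n_measurements_after == 2


class TestInclusionFilters:
    def test_toy_cohort_two_survivors(self, toy_cohort):
        out, log = apply_inclusion_filters(toy_cohort, FilterRules(min_measurements=3))
        assert set(out.measurements["patient_id"]) == {"A", "B"}
        stages = [r.stage for r in log]
        assert stages == ["min_age", "hb_range", "measurement_count"]

    def test_vacuous_rules_are_identity(self, toy_cohort):
        rules = FilterRules(min_age=0, hb_min=-np.inf, hb_max=np.inf, min_measurements=1)
        out, _ = apply_inclusion_filters(toy_cohort, rules)
        assert len(out.measurements) == len(toy_cohort.measurements)

    def test_single_out_of_range_value_excludes_whole_patient(self):
        rows = [("A", f"2013-{m:02d}-01", 8.0, "female", 1960) for m in range(1, 10)]
        rows.append(("A", "2013-11-01", 16.6, "female", 1960))
        cohort = make_cohort_frame(rows)
        out, _ = apply_inclusion_filters(cohort, FilterRules())
        assert out.measurements.empty

    def test_gender_specific_bounds(self):
        cohort = make_cohort_frame(
            [
                ("F1", "2013-01-01", 12.5, "female", 1960),  # above female cap 12
                ("F1", "2013-02-01", 9.0, "female", 1960),
                ("F1", "2013-03-01", 9.1, "female", 1960),
                ("M1", "2013-01-01", 12.5, "male", 1960),  # fine for males
                ("M1", "2013-02-01", 9.0, "male", 1960),
                ("M1", "2013-03-01", 9.1, "male", 1960),
            ]
        )
        rules = FilterRules(hb_min_f=6, hb_max_f=12, hb_min_m=7, hb_max_m=13)
        out, _ = apply_inclusion_filters(cohort, rules)
        assert set(out.measurements["patient_id"]) == {"M1"}

    def test_invalid_rules_rejected(self, toy_cohort):
        with pytest.raises(ValueError):
            apply_inclusion_filters(toy_cohort, FilterRules(hb_min=10, hb_max=6))

    def test_attrition_counts_never_increase(self, small_cohort):
        cohort, _ = deduplicate_same_day(small_cohort)
        _, log = apply_inclusion_filters(cohort, FilterRules())
        for rec in log:
            assert rec.n_patients_after <= rec.n_patients_before
            assert rec.n_measurements_after <= rec.n_measurements_before

    def test_brute_force_filter_oracle(self):
        """Surviving patients equal an independent per-patient rule check."""
        cohort = generate_cohort(
            SyntheticConfig(n_patients=20, drift_fraction=0.3, drift_rate=2.0, seed=31)
        )
        cohort, _ = deduplicate_same_day(cohort)
        rules = FilterRules(min_age=40, hb_min=6.5, hb_max=10.5, min_measurements=5, max_measurements=40)
        out, _ = apply_inclusion_filters(cohort, rules)

        survivors = set()
        for pid, g in cohort.measurements.sort_values(["patient_id", "date"]).groupby("patient_id"):
            first = g.iloc[0]
            age = (
                first["date"].year + (first["date"].dayofyear - 1) / 365.25 - first["birth_year"]
            )
            if age < rules.min_age:
                continue
            if ((g["hb_mmol_l"] < rules.hb_min) | (g["hb_mmol_l"] > rules.hb_max)).any():
                continue
            if not rules.min_measurements <= len(g) <= rules.max_measurements:
                continue
            survivors.add(pid)
        assert set(out.measurements["patient_id"]) == survivors


class TestModelRows:
    def test_forced_arithmetic(self):
        cohort = make_cohort_frame(
            [
                ("A", "2013-01-01", 8.0, "female", 1960),
                ("A", "2013-01-11", 9.0, "female", 1960),
                ("A", "2013-01-31", 10.0, "female", 1960),
            ]
        )
        rows = build_model_rows(cohort)
        assert list(rows["y"]) == [9.0, 10.0]
        assert list(rows["time_since_first_days"]) == [10.0, 30.0]
        assert list(rows["past_mean"]) == [8.0, 8.5]

    def test_constant_series_constant_past_mean(self):
        cohort = make_cohort_frame(
            [("A", f"2013-0{m}-01", 8.0, "male", 1950) for m in range(1, 5)]
        )
        rows = build_model_rows(cohort)
        assert (rows["past_mean"] == 8.0).all()

    def test_expanding_mean_matches_brute_force_prefix_means(self):
        rng = np.random.default_rng(0)
        values = rng.uniform(7, 10, 50)
        dates = pd.date_range("2012-01-01", periods=50, freq="13D")
        cohort = make_cohort_frame(
            [("A", d, v, "female", 1970) for d, v in zip(dates, values)]
        )
        rows = build_model_rows(cohort)
        expected = [values[:i].mean() for i in range(1, 50)]
        np.testing.assert_allclose(rows["past_mean"], expected, rtol=1e-13)

    def test_first_row_dropped_and_singletons_skipped(self):
        cohort = make_cohort_frame(
            [
                ("A", "2013-01-01", 8.0, "female", 1960),
                ("B", "2013-01-01", 8.0, "male", 1950),
                ("B", "2013-02-01", 8.5, "male", 1950),
            ]
        )
        rows = build_model_rows(cohort)
        assert set(rows["patient_id"]) == {"B"} and len(rows) == 1

    def test_train_constant_mode_uses_pre_holdout_mean(self):
        cohort = make_cohort_frame(
            [
                ("A", "2013-01-01", 8.0, "female", 1960),
                ("A", "2013-02-01", 9.0, "female", 1960),
                ("A", "2013-03-01", 10.0, "female", 1960),
            ]
        )
        rows = build_model_rows(cohort, past_mean_mode="train_constant")
        np.testing.assert_allclose(rows["past_mean"], [8.5, 8.5])

    def test_no_lookahead_mutating_future_leaves_earlier_rows_unchanged(self):
        rng = np.random.default_rng(4)
        values = rng.uniform(7, 10, 12)
        dates = pd.date_range("2012-01-01", periods=12, freq="30D")
        recs = [("A", d, v, "female", 1970) for d, v in zip(dates, values)]
        base = build_model_rows(make_cohort_frame(recs))
        # mutate the last measurement
        mutated = recs[:-1] + [("A", dates[-1], 99.0, "female", 1970)]
        mut_rows = build_model_rows(make_cohort_frame(mutated))
        pd.testing.assert_frame_equal(base.iloc[:-1], mut_rows.iloc[:-1])
        # delete a future measurement
        trunc = build_model_rows(make_cohort_frame(recs[:-3]))
        pd.testing.assert_frame_equal(base.iloc[: len(trunc)], trunc)


class TestHoldoutSplit:
    def test_latest_row_goes_to_test(self):
        cohort = make_cohort_frame(
            [
                ("A", "2013-01-01", 8.0, "female", 1960),
                ("A", "2013-01-11", 9.0, "female", 1960),
                ("A", "2013-01-31", 10.0, "female", 1960),
            ]
        )
        split = holdout_split(build_model_rows(cohort))
        assert split.test["time_since_first_days"].iloc[0] == 30.0
        assert split.train["time_since_first_days"].iloc[0] == 10.0

    def test_patient_with_single_row_excluded_entirely(self):
        cohort = make_cohort_frame(
            [
                ("A", "2013-01-01", 8.0, "female", 1960),
                ("A", "2013-02-01", 8.5, "female", 1960),  # only one model row
                ("B", "2013-01-01", 9.0, "male", 1950),
                ("B", "2013-02-01", 9.1, "male", 1950),
                ("B", "2013-03-01", 9.2, "male", 1950),
            ]
        )
        split = holdout_split(build_model_rows(cohort))
        assert split.excluded_patients == ["A"]
        assert set(split.train["patient_id"]) == {"B"}

    def test_one_test_row_per_patient(self, small_split):
        assert small_split.test["patient_id"].is_unique
        assert len(small_split.test) == small_split.train["patient_id"].nunique()
        # per patient, the test date strictly follows every train date
        latest_train = small_split.train.groupby("patient_id")["date"].max()
        merged = small_split.test.set_index("patient_id")["date"]
        assert (merged > latest_train.loc[merged.index]).all()

    def test_empty_input_yields_empty_split(self):
        from hbmon.preprocess import MODEL_ROW_COLUMNS

        split = holdout_split(pd.DataFrame(columns=MODEL_ROW_COLUMNS))
        assert split.train.empty and split.test.empty
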