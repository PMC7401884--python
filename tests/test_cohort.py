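"""Codings, CSV round-trips and the crude summary table."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from crprog import (
    Cohort,
    bin_age,
    bin_lbtd,
    code_cause_of_death,
    load_cohort,
    summarize_cohort,
)
from crprog.cohort import CohortSchemaError, lbtd_bin_label

from conftest import make_raw_cohort


class TestBinning:
    @pytest.mark.parametrize(
        "mm,expected,label",
        [
            (2.4, 1, "<10.1"),
            (10.0, 1, "<10.1"),
            (10.05, 2, "10.1-12.0"),
            (12.0, 2, "10.1-12.0"),
            (12.1, 3, "12.1-14.0"),
            (14.0, 3, "12.1-14.0"),
            (16.0, 4, "14.1-16.0"),
            (18.0, 5, "16.1-18.0"),
            (18.1, 6, "18.1-28.0"),
            (28.0, 6, "18.1-28.0"),
        ],
    )
    def test_lbtd_bin_edges(self, mm, expected, label):
        assert bin_lbtd(mm) == expected
        assert lbtd_bin_label(expected) == label

    def test_lbtd_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            bin_lbtd(0.0)
        with pytest.raises(ValueError):
            bin_lbtd(-3.0)

    def test_lbtd_warns_outside_typical_range(self):
        with pytest.warns(UserWarning):
            bin_lbtd(30.0)

    @settings(derandomize=True, max_examples=100)
    @given(
        a=st.floats(min_value=2.4, max_value=28.0),
        b=st.floats(min_value=2.4, max_value=28.0),
    )
    def test_lbtd_binning_is_monotone(self, a, b):
        if a > b:
            a, b = b, a
        assert bin_lbtd(a) <= bin_lbtd(b)

    @pytest.mark.parametrize("age,expected", [(80.0, 0), (81.0, 1), (80.5, 1), (25.0, 0)])
    def test_age_threshold_at_80(self, age, expected):
        assert bin_age(age) == expected

    def test_age_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            bin_age(-1.0)


class TestCauseCoding:
    @pytest.mark.parametrize(
        "category,expected",
        [
            (1, 1),  # definite metastatic UM
            (2, 1),  # probable metastatic UM
            (3, 2),  # possible metastatic UM counts as other death
            (4, 2),
            (5, 2),
            (6, 2),  # unknown cause counts as other death
            ("alive", 0),
            ("definite_metastatic_um", 1),
            ("possible_metastatic_um", 2),
        ],
    )
    def test_registry_rule(self, category, expected):
        assert code_cause_of_death(category) == expected

    def test_unknown_code_rejected(self):
        with pytest.raises(ValueError):
            code_cause_of_death(7)
        with pytest.raises(ValueError):
            code_cause_of_death("mystery")


class TestCohortIO:
    def test_load_counts_and_missing_c3s(self, tmp_path):
        raw = make_raw_cohort(n=30, seed=1)
        path = tmp_path / "cohort.csv"
        raw.to_csv(path, index=False)
        cohort = load_cohort(path)
        assert cohort.n == 30
        blank = (raw["c3s"] == "").sum()
        assert cohort.n_missing_c3s == blank
        assert cohort.df["m3"].isna().sum() == blank

    def test_round_trip_is_identical(self, tmp_path):
        raw = make_raw_cohort(n=40, seed=2)
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        raw.to_csv(p1, index=False)
        c1 = load_cohort(p1)
        c1.to_csv(p2)
        c2 = load_cohort(p2)
        cols = ["lbtd_bin", "age_bin", "event", "time"]
        pd.testing.assert_frame_equal(c1.df[cols], c2.df[cols])
        assert (c1.df["m3"].fillna(-1) == c2.df["m3"].fillna(-1)).all()

    def test_missing_required_column_names_it(self):
        raw = make_raw_cohort(n=5).drop(columns=["followup_years"])
        with pytest.raises(CohortSchemaError, match="followup_years"):
            Cohort.from_dataframe(raw)

    def test_invalid_rows_rejected_and_logged(self, caplog):
        raw = make_raw_cohort(n=6, seed=3)
        raw["lbtd_mm"] = raw["lbtd_mm"].astype(object)
        raw.loc[2, "followup_years"] = 0.0
        raw.loc[4, "lbtd_mm"] = "not-a-number"
        with caplog.at_level("WARNING", logger="crprog.cohort"):
            cohort = Cohort.from_dataframe(raw)
        assert cohort.n == 4
        assert cohort.provenance["n_rejected_rows"] == 2
        assert any("rejected" in r.message for r in caplog.records)

    def test_unknown_column_warns(self):
        raw = make_raw_cohort(n=5)
        raw["shoe_size"] = 42
        with pytest.warns(UserWarning, match="shoe_size"):
            Cohort.from_dataframe(raw)


class TestSummary:
    def test_counts_partition_cohort(self, cohort_n2000):
        s = summarize_cohort(cohort_n2000)
        body = s.by_c3s.iloc[:6]
        assert body[["unknown_n", "D3_n", "M3_n"]].to_numpy().sum() == cohort_n2000.n
        body_age = s.by_age.iloc[:6]
        assert body_age[["le80_n", "gt80_n"]].to_numpy().sum() == cohort_n2000.n

    def test_percentages_are_crude_ratios(self, cohort_n2000):
        s = summarize_cohort(cohort_n2000)
        for _, row in s.by_c3s.iloc[:6].iterrows():
            for col in ("unknown", "D3", "M3"):
                n, d, pct = row[f"{col}_n"], row[f"{col}_deaths"], row[f"{col}_pct"]
                if n > 0:
                    assert pct == pytest.approx(100.0 * d / n, abs=0.05 + 1e-9)

    def test_zero_death_cell_is_zero_pct(self):
        raw = make_raw_cohort(n=20, seed=5)
        raw["outcome"] = "alive"
        s = summarize_cohort(Cohort.from_dataframe(raw))
        pcts = s.by_c3s.iloc[:6][["unknown_pct", "D3_pct", "M3_pct"]].to_numpy(dtype=float)
        assert np.nanmax(pcts) == 0.0
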