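"""Ages, indices, LMS transforms, status bands, eligibility and summaries."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st

from tmiscreen import anthro
from tmiscreen.anthro import (
    LMSReference,
    bmi,
    classify_status,
    compute_age,
    eligibility_filter,
    endpoint_outcomes,
    lms_inverse,
    lms_zscore,
    round_half_up,
    summarize_cohort,
    tmi,
)


class TestComputeAge:
    @pytest.mark.parametrize(
        "exam, birth, days",
        [
            (dt.date(2005, 9, 1), dt.date(1998, 9, 1), 2557),
            (dt.date(2016, 9, 1), dt.date(1998, 3, 15), 6745),
            (dt.date(2010, 5, 5), dt.date(2010, 5, 5), 0),
        ],
    )
    def test_day_quotient(self, exam, birth, days):
        assert compute_age(exam, birth) == pytest.approx(days / 365.25, abs=0)

    def test_exam_before_birth_rejected(self):
        with pytest.raises(ValueError):
            compute_age(dt.date(2000, 1, 1), dt.date(2001, 1, 1))


class TestIndices:
    @pytest.mark.parametrize(
        "w, h, expected_bmi, expected_tmi",
        [(50, 160, 19.531, 12.207), (64, 200, 16.0, 8.0)],
    )
    def test_values(self, w, h, expected_bmi, expected_tmi):
        assert bmi(w, h) == pytest.approx(expected_bmi, abs=1e-3)
        assert tmi(w, h) == pytest.approx(expected_tmi, abs=1e-3)

    @given(
        w=st.floats(10, 150),
        h=st.floats(80, 210),
    )
    @settings(max_examples=50, deadline=None)
    def test_ratio_is_height_in_metres(self, w, h):
        assert bmi(w, h) / tmi(w, h) == pytest.approx(h / 100.0, rel=1e-12)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            bmi(-1, 160)
        with pytest.raises(ValueError):
            tmi(50, 0)


class TestLMS:
    def test_at_median_zero(self):
        assert lms_zscore(18.0, -1.5, 18.0, 0.1) == pytest.approx(0.0, abs=1e-12)

    def test_unit_l_reduces_to_proportional_deviation(self):
        assert lms_zscore(19.8, 1.0, 18.0, 0.1) == pytest.approx(1.0, rel=1e-12)

    def test_hand_computed_value(self):
        # ((21/16)^-1.6 - 1) / (-1.6 * 0.11), evaluated independently
        z = lms_zscore(21.0, -1.6, 16.0, 0.11)
        assert z == pytest.approx(2.0045235068099623, rel=1e-12)
        assert lms_inverse(z, -1.6, 16.0, 0.11) == pytest.approx(21.0, abs=1e-9)

    @given(
        L=st.one_of(st.floats(-3, -1e-3), st.floats(1e-3, 3), st.just(0.0), st.floats(-1e-7, 1e-7)),
        M=st.floats(10, 30),
        S=st.floats(0.05, 0.2),
        z=st.floats(-3.5, 3.5),
    )
    @settings(max_examples=200, deadline=None)
    def test_roundtrip_including_l_near_zero(self, L, M, S, z):
        assume(1.0 + L * S * z > 0.05)  # inside the transform's domain
        x = lms_inverse(z, L, M, S)
        assert lms_zscore(x, L, M, S) == pytest.approx(z, abs=1e-9)


class TestClassify:
    @pytest.mark.parametrize(
        "z, label",
        [
            (0.0, "normal"),
            (1.0, "normal"),  # boundary: overweight is strictly above +1
            (1.5, "overweight"),
            (2.0, "overweight"),  # boundary: obesity is strictly above +2
            (2.5, "obesity"),
            (-3.0, "normal"),
        ],
    )
    def test_bands(self, z, label):
        assert classify_status(z) == label

    @given(st.floats(-10, 10))
    @settings(max_examples=100, deadline=None)
    def test_partition(self, z):
        assert classify_status(z) in {"normal", "overweight", "obesity"}


def _toy_cohort(children):
    """children: list of (child_id, sex, [ages], [z-like bmi offsets])."""
    rows = []
    for cid, sex, ages in children:
        for a in ages:
            rows.append(
                {"child_id": cid, "sex": sex, "age": a, "age_int": int(a),
                 "bmi": 18.0, "tmi": 12.0, "bmi_z": 0.0}
            )
    return pd.DataFrame(rows)


class TestEligibility:
    def test_too_few_measurements(self):
        df = _toy_cohort([("a", "M", [9, 10, 11, 12, 13, 14, 17])])  # 7 rows
        kept, report = eligibility_filter(df)
        assert kept.empty
        assert report.reasons.iloc[0]["reason"] == "too_few"

    def test_no_endpoint_window(self):
        df = _toy_cohort([("a", "M", [7, 8, 9, 10, 11, 12, 13, 14, 15.9])])
        kept, report = eligibility_filter(df)
        assert kept.empty
        assert report.reasons.iloc[0]["reason"] == "no_endpoint_window"

    def test_kept_with_exactly_eight(self):
        df = _toy_cohort([("a", "F", [9, 10, 11, 12, 13, 14, 15, 16.2])])
        kept, report = eligibility_filter(df)
        assert report.n_kept == 1
        assert len(kept) == 8


class TestEndpoint:
    def _df(self, ages_z):
        rows = [
            {"child_id": "a", "sex": "M", "age": a, "age_int": int(a),
             "bmi": 20.0, "tmi": 12.0, "bmi_z": z}
            for a, z in ages_z
        ]
        return pd.DataFrame(rows)

    def test_last_in_window_defines_status(self):
        df = self._df([(15.0, 0.0), (16.1, 1.2), (17.3, 2.4)])
        out = endpoint_outcomes(df)
        assert out.iloc[0]["status"] == "obesity"
        assert bool(out.iloc[0]["ob"]) and bool(out.iloc[0]["ow_incl_ob"])
        assert out.iloc[0]["endpoint_age"] == pytest.approx(17.3)

    def test_measurement_outside_window_ignored(self):
        df = self._df([(16.5, 0.2), (18.9, 3.0)])
        out = endpoint_outcomes(df)
        assert out.iloc[0]["endpoint_age"] == pytest.approx(16.5)
        assert out.iloc[0]["status"] == "normal"
        assert not bool(out.iloc[0]["ow_incl_ob"])


class TestSummarize:
    def test_percentages_sum_to_100(self, small_cohort):
        cohort, endpoints = small_cohort
        summary = summarize_cohort(cohort, endpoints)
        for _, row in summary.iterrows():
            total = row["normal_pct"] + row["overweight_pct"] + row["obesity_pct"]
            assert total == pytest.approx(100.0, abs=0.1)

    def test_all_normal(self):
        df = _toy_cohort([(f"c{i}", "M", [9, 10, 11, 12, 13, 14, 15, 16.5]) for i in range(5)])
        summary = summarize_cohort(df)
        assert summary.iloc[0]["normal_pct"] == 100.0

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            summarize_cohort(pd.DataFrame(columns=["child_id", "sex", "age"]))


class TestRounding:
    @pytest.mark.parametrize(
        "num, den, expected",
        [(982, 9604, 10.2), (432, 8211, 5.3), (317, 9604, 3.3), (93, 8211, 1.1),
         (8305, 9604, 86.5), (7686, 8211, 93.6), (9604, 17815, 53.9)],
    )
    def test_printed_table_arithmetic(self, num, den, expected):
        assert round_half_up(100.0 * num / den) == expected

    def test_half_rounds_up(self):
        assert round_half_up(10.25) == 10.3
        assert round_half_up(10.15) == 10.2


class TestLMSReference:
    def test_age_outside_grid_names_age(self, reference):
        with pytest.raises(ValueError, match="25.0"):
            reference.zscore("M", 25.0, 20.0)

    def test_interpolated_roundtrip(self, reference):
        for age in (7.25, 9.0, 16.75):
            x = reference.value_at_z("F", age, 1.3)
            assert reference.zscore("F", age, x) == pytest.approx(1.3, abs=1e-9)

    def test_non_monotone_grid_rejected(self):
        bad = pd.DataFrame(
            {"sex": ["M", "M"], "age_years": [7.0, 7.0], "L": [-1, -1],
             "M": [16, 16], "S": [0.1, 0.1]}
        )
        with pytest.raises(ValueError):
            LMSReference(bad)
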