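"""Scale definition, cohort loading/validation, totals, alpha, summaries."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from symptomnet.scale import (
    KEDS,
    CohortTable,
    CohortValidationError,
    EmptyMatrixError,
    ITEM_KEYS,
    ScaleDefinition,
    complete_cases,
    cronbach_alpha,
    load_cohort,
    summarize_cohort,
    total_score,
)

from conftest import constant_cohort, make_cohort_frame


class TestScaleDefinition:
    def test_keds_constants(self):
        assert KEDS.n_items == 9
        assert (KEDS.item_min, KEDS.item_max) == (0, 6)
        assert KEDS.max_total == 54
        assert KEDS.risk_cutoff == 19
        assert KEDS.reliable_change == 9

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"item_max": 0, "item_min": 0},
            {"item_labels": ("a", "a", "b")},
            {"risk_cutoff": 100},
            {"reliable_change": 0},
        ],
    )
    def test_invalid_definitions_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ScaleDefinition(**kwargs)


class TestLoadCohort:
    def test_wide_round_trip(self, tmp_path):
        frame = make_cohort_frame(
            [
                {"subject_id": "a", "timepoint": "assessment", "scores": [0, 1, 2, 3, 4, 5, 6, 5, 4]},
                {"subject_id": "a", "timepoint": "end", "scores": [6] * 9},
                {"subject_id": "b", "timepoint": "assessment", "scores": [0] * 9},
            ]
        )
        path = tmp_path / "cohort.csv"
        frame.to_csv(path, index=False)
        cohort = load_cohort(path)
        assert len(cohort.data) == 3
        assert cohort.n_subjects == 2
        pd.testing.assert_frame_equal(
            cohort.data[frame.columns].astype({k: int for k in ITEM_KEYS}),
            frame.astype({k: int for k in ITEM_KEYS}),
        )

    def test_long_layout(self, tmp_path):
        rows = [
            {"subject_id": "a", "timepoint": "assessment", "item": k, "score": i % 7}
            for i, k in enumerate(ITEM_KEYS)
        ]
        path = tmp_path / "long.csv"
        pd.DataFrame(rows).to_csv(path, index=False)
        cohort = load_cohort(path, layout="long")
        assert len(cohort.data) == 1
        assert cohort.data.loc[0, ITEM_KEYS[3]] == 3

    def test_out_of_range_score_rejected(self, tmp_path):
        frame = make_cohort_frame(
            [{"subject_id": "a", "timepoint": "assessment", "scores": [7] + [3] * 8}]
        )
        path = tmp_path / "bad.csv"
        frame.to_csv(path, index=False)
        with pytest.raises(CohortValidationError, match="out of range"):
            load_cohort(path)

    def test_duplicate_subject_timepoint_rejected(self, tmp_path):
        frame = make_cohort_frame(
            [
                {"subject_id": "a", "timepoint": "assessment"},
                {"subject_id": "a", "timepoint": "assessment"},
            ]
        )
        path = tmp_path / "dup.csv"
        frame.to_csv(path, index=False)
        with pytest.raises(CohortValidationError, match="duplicate"):
            load_cohort(path)

    def test_missing_encoded_as_na(self, tmp_path):
        path = tmp_path / "na.csv"
        header = "subject_id,timepoint," + ",".join(ITEM_KEYS)
        path.write_text(header + "\na,assessment,NA,3,3,3,3,3,3,3,\n")
        cohort = load_cohort(path)
        assert cohort.data[ITEM_KEYS[0]].isna().all()
        assert cohort.data[ITEM_KEYS[-1]].isna().all()

    def test_unknown_timepoint_rejected(self):
        frame = make_cohort_frame([{"subject_id": "a", "timepoint": "week99"}])
        with pytest.raises(CohortValidationError, match="timepoint"):
            CohortTable(data=frame)


class TestTotalScore:
    @pytest.mark.parametrize(
        "scores,expected",
        [([6] * 9, 54), ([0] * 9, 0), (list(range(9)), 36)],
    )
    def test_complete_totals(self, scores, expected):
        assert total_score(scores) == expected

    def test_partial_missing_is_missing(self):
        scores = [3.0] * 8 + [float("nan")]
        assert math.isnan(total_score(scores))

    @given(
        scores=st.lists(st.integers(0, 6), min_size=9, max_size=9),
        item=st.integers(0, 8),
    )
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_each_item(self, scores, item):
        if scores[item] == 6:
            return
        bumped = list(scores)
        bumped[item] += 1
        assert total_score(bumped) > total_score(scores)


class TestCompleteCases:
    def test_filters_incomplete_records(self):
        records = [
            {"subject_id": f"S{i}", "timepoint": "end", "scores": [2] * 9}
            for i in range(10)
        ]
        frame = make_cohort_frame(records)
        frame.loc[0, ITEM_KEYS[4]] = np.nan
        frame.loc[5, ITEM_KEYS[0]] = np.nan
        cohort = CohortTable(data=frame)
        matrix = complete_cases(cohort, "end")
        assert matrix.n == 8
        assert matrix.timepoint == "end"

    def test_identity_on_complete_cohort(self):
        cohort = constant_cohort(n=12)
        matrix = complete_cases(cohort, "assessment")
        assert matrix.n == 12
        assert list(matrix.subject_ids) == list(cohort.data["subject_id"])

    def test_empty_result_raises(self):
        frame = make_cohort_frame(
            [{"subject_id": "a", "timepoint": "assessment"}]
        )
        frame.loc[0, ITEM_KEYS[0]] = np.nan
        with pytest.raises(EmptyMatrixError):
            complete_cases(CohortTable(data=frame), "assessment")


class TestCronbachAlpha:
    def test_identical_items_give_one(self, rng):
        col = rng.integers(0, 7, size=40)
        x = np.tile(col[:, None], (1, 9))
        assert cronbach_alpha(x) == pytest.approx(1.0)

    def test_independent_items_give_zero(self, rng):
        x = rng.integers(0, 7, size=(10_000, 9))
        assert abs(cronbach_alpha(x)) < 0.05

    def test_two_item_hand_oracle(self):
        # items [1,2,3,4] and [1,3,2,4]: totals variance 6, item variances 5/3
        # each => alpha = 2 * (1 - (10/3)/6) = 8/9
        x = np.array([[1, 1], [2, 3], [3, 2], [4, 4]], dtype=float)
        assert cronbach_alpha(x) == pytest.approx(8.0 / 9.0, abs=1e-12)

    def test_invariant_under_item_location_shift(self, rng):
        x = rng.integers(0, 7, size=(60, 9)).astype(float)
        shifted = x + np.arange(9)
        assert cronbach_alpha(shifted) == pytest.approx(cronbach_alpha(x), abs=1e-12)

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError, match="zero total-score variance"):
            cronbach_alpha(np.full((5, 9), 3.0))


class TestSummarizeCohort:
    def test_constant_cohort_summary(self):
        cohort = constant_cohort(n=8, score=3)
        summary = summarize_cohort(cohort)
        assert len(summary) == 1
        row = summary.iloc[0]
        for item in ITEM_KEYS:
            assert row[f"{item}_mean"] == pytest.approx(3.0)
            assert row[f"{item}_sd"] == pytest.approx(0.0)
        assert row["total_mean"] == pytest.approx(27.0)
        assert row["missing_n"] == 0

    def test_missing_percentage_rounding(self):
        # 132 of 915 records absent at follow-up -> 14% missing
        records = [
            {"subject_id": f"S{i:04d}", "timepoint": "assessment"} for i in range(915)
        ] + [
            {"subject_id": f"S{i:04d}", "timepoint": "followup12m"}
            for i in range(915 - 132)
        ]
        cohort = CohortTable(data=make_cohort_frame(records))
        summary = summarize_cohort(cohort).set_index("timepoint")
        assert summary.loc["followup12m", "missing_n"] == 132
        assert summary.loc["followup12m", "missing_pct"] == 14

    def test_missing_plus_complete_partition(self, rng):
        records = []
        for i in range(50):
            records.append({"subject_id": f"S{i}", "timepoint": "assessment"})
            if i % 3:
                records.append({"subject_id": f"S{i}", "timepoint": "end"})
        frame = make_cohort_frame(records)
        cohort = CohortTable(data=frame)
        summary = summarize_cohort(cohort).set_index("timepoint")
        for tp in ("assessment", "end"):
            n_complete = complete_cases(cohort, tp).n
            assert summary.loc[tp, "missing_n"] + n_complete == cohort.n_subjects
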