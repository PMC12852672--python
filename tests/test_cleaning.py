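import numpy as np
import pandas as pd
import pytest

import audiophen as ap
from audiophen import cleaning
from conftest import curve_row, curve_table


class TestRemoveEmptyCurves:
    def test_all_missing_row_removed(self):
        t = curve_table([curve_row(thresholds=[None] * 6)])
        assert len(cleaning.remove_empty_curves(t)) == 0

    def test_incomplete_ac_removed_partial_bc_kept(self):
        t = curve_table(
            [
                curve_row(thresholds=[20, 20, 20, 20, 20, None], record_index=0),
                curve_row(modality="BC", thresholds=[None, 20, 20, 20, None, None],
                          record_index=1),
            ]
        )
        out = cleaning.remove_empty_curves(t)
        assert out["record_index"].tolist() == [1]


class TestDropExactDuplicates:
    def test_same_day_identical_keeps_lowest_index(self):
        t = curve_table(
            [curve_row(record_index=3), curve_row(record_index=1)]
        )
        out = cleaning.drop_exact_duplicates(t)
        assert out["record_index"].tolist() == [1]

    def test_different_date_or_modality_kept(self):
        t = curve_table(
            [
                curve_row(record_index=0),
                curve_row(test_date="2020-02-01", record_index=1),
                curve_row(modality="BC", record_index=2),
            ]
        )
        assert len(cleaning.drop_exact_duplicates(t)) == 3


class TestSelectSameDayCurve:
    def test_most_complete_curve_wins(self):
        t = curve_table(
            [
                curve_row(thresholds=[20, 20, None, 20, None, 20], record_index=0),
                curve_row(thresholds=[25, 25, 25, 25, 25, 25], record_index=1),
            ]
        )
        out = cleaning.select_same_day_curve(t)
        assert out["record_index"].tolist() == [1]

    def test_tie_breaks_to_lowest_record_index(self):
        t = curve_table(
            [
                curve_row(thresholds=[25] * 6, record_index=7),
                curve_row(thresholds=[30] * 6, record_index=2),
            ]
        )
        out = cleaning.select_same_day_curve(t)
        assert out["record_index"].tolist() == [2]

    def test_singleton_group_unchanged(self):
        t = curve_table([curve_row()])
        assert cleaning.select_same_day_curve(t).equals(
            cleaning.select_same_day_curve(cleaning.select_same_day_curve(t))
        )


class TestJoinCurves:
    def test_ac_bc_merged_on_same_key(self):
        t = curve_table(
            [
                curve_row(record_index=0),
                curve_row(modality="BC", thresholds=[None, 10, 10, 10, None, None],
                          record_index=1),
            ]
        )
        out = cleaning.join_curves(t)
        assert len(out) == 1
        assert out.loc[0, "b500"] == 10
        assert out.loc[0, "t500"] == 20

    def test_ac_only_and_bc_only(self):
        t = curve_table(
            [
                curve_row(record_index=0),
                curve_row(patient_id="P2", modality="BC",
                          thresholds=[None, 10, 10, 10, None, None], record_index=1),
            ]
        )
        out = cleaning.join_curves(t)
        assert len(out) == 1  # BC-only test yields no audiogram
        assert out[[c for c in out.columns if c.startswith("b")]].isna().all().all()


class TestValidateThresholds:
    @pytest.mark.parametrize(
        "thresholds, kept",
        [
            ([20, 20, 20, 20, 20, 121], False),  # beyond 120 dB
            ([20, 20, 7, 20, 20, 20], False),  # not a multiple of 5
            ([120, 120, 120, 120, 120, -10], True),  # boundary values valid
            ([-15, 20, 20, 20, 20, 20], False),  # below -10 dB
        ],
    )
    def test_validity_rules(self, thresholds, kept):
        t = curve_table([curve_row(thresholds=thresholds)])
        out = cleaning.validate_thresholds(cleaning.join_curves(t))
        assert (len(out) == 1) is kept


class TestDetectChl:
    @pytest.mark.parametrize(
        "bc, expected",
        [
            ([None, 20, 20, 40, None, None], True),  # gaps 30,30,10
            ([None, 20, 40, 40, None, None], False),  # gaps 30,10,10
            (None, False),  # no BC: SNHL candidate
        ],
    )
    def test_air_bone_gap_rule(self, bc, expected):
        rows = [curve_row(thresholds=[50] * 6, record_index=0)]
        if bc is not None:
            rows.append(curve_row(modality="BC", thresholds=bc, record_index=1))
        aud = cleaning.join_curves(curve_table(rows))
        assert cleaning.detect_chl(aud).tolist() == [expected]


class TestBilateralAdultSnhl:
    def _both_ears(self, age=50, right_bc=None):
        rows = [
            curve_row(ear="L", record_index=0, age=age),
            curve_row(ear="R", record_index=1, age=age),
        ]
        if right_bc is not None:
            rows.append(
                curve_row(ear="R", modality="BC", thresholds=right_bc,
                          record_index=2, age=age)
            )
        return cleaning.join_curves(curve_table(rows))

    def test_chl_in_one_ear_excludes_patient_date(self):
        aud = self._both_ears(right_bc=[None, -10, -10, -10, None, None])
        assert len(cleaning.filter_bilateral_adult_snhl(aud)) == 0

    @pytest.mark.parametrize("age, kept", [(17, False), (18, True), (100, True), (101, False)])
    def test_adult_age_boundary_inclusive(self, age, kept):
        aud = self._both_ears(age=age)
        assert (len(cleaning.filter_bilateral_adult_snhl(aud)) == 1) is kept

    def test_single_ear_excluded(self):
        aud = cleaning.join_curves(curve_table([curve_row(ear="L")]))
        out = cleaning.filter_bilateral_adult_snhl(aud)
        assert len(out) == 0

    def test_missing_demographics_excluded_unless_looked_up(self):
        rows = [
            curve_row(ear="L", age=None, sex=None, record_index=0),
            curve_row(ear="R", age=None, sex=None, record_index=1),
        ]
        t = curve_table(rows)
        ears, _ = cleaning.clean_pipeline(t, seed=0)
        assert len(ears) == 0
        lookup = pd.DataFrame({"patient_id": ["P1"], "age": [60], "sex": ["F"]})
        ears, _ = cleaning.clean_pipeline(t, demo_lookup=lookup, seed=0)
        assert len(ears) == 2


class TestSampleOnePerPatient:
    def _table(self):
        rows = []
        for i, d in enumerate(["2020-01-01", "2020-06-01", "2021-01-01"]):
            rows += [
                curve_row(ear="L", test_date=d, record_index=2 * i),
                curve_row(ear="R", test_date=d, record_index=2 * i + 1),
            ]
        return cleaning.filter_bilateral_adult_snhl(
            cleaning.join_curves(curve_table(rows))
        )

    def test_selection_uniform_over_dates(self):
        table = self._table()
        counts = {d: 0 for d in table["test_date"]}
        n = 10_000
        for s in range(n):
            picked = cleaning.sample_one_per_patient(table, seed=s)
            counts[picked.loc[0, "test_date"]] += 1
        for c in counts.values():
            assert abs(c / n - 1 / 3) < 0.02

    def test_deterministic_and_idempotent(self):
        table = self._table()
        a = cleaning.sample_one_per_patient(table, seed=3)
        b = cleaning.sample_one_per_patient(table, seed=3)
        assert a.equals(b)
        assert cleaning.sample_one_per_patient(a, seed=9).equals(a.reset_index(drop=True))


class TestPipelineProperties:
    def test_audit_conservation_each_stage(self, demo_specs):
        cor = ap.CorruptionSpec(
            empty_rate=0.1, exact_duplicate_rate=0.1, same_day_multiple_rate=0.1,
            invalid_value_rate=0.05, chl_rate=0.1, unilateral_rate=0.05,
            under18_rate=0.05, missing_demo_rate=0.05,
        )
        curves, _ = ap.generate_curve_table(demo_specs, cor, 150, seed=4)
        _, audit = cleaning.clean_pipeline(curves, seed=0)
        for stage, n_in, n_out, removed in audit.stages:
            assert n_out == n_in - removed, stage

    def test_curve_stage_idempotence(self, demo_specs):
        cor = ap.CorruptionSpec(empty_rate=0.2, exact_duplicate_rate=0.2,
                                same_day_multiple_rate=0.2)
        curves, _ = ap.generate_curve_table(demo_specs, cor, 80, seed=8)
        once = cleaning.select_same_day_curve(
            cleaning.drop_exact_duplicates(cleaning.remove_empty_curves(curves))
        )
        twice = cleaning.select_same_day_curve(
            cleaning.drop_exact_duplicates(cleaning.remove_empty_curves(once))
        )
        assert once.reset_index(drop=True).equals(twice.reset_index(drop=True))

    def test_ear_expansion_doubles_and_round_trips(self, demo_specs):
        curves, _ = ap.generate_curve_table(
            demo_specs, ap.CorruptionSpec(), 10, seed=1, tests_per_patient_mean=1.0
        )
        ears, audit = cleaning.clean_pipeline(curves, seed=0)
        assert len(ears) == 20
        by_patient = ears.groupby("patient_id")["ear"].agg(sorted)
        assert all(v == ["L", "R"] for v in by_patient)

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="missing columns"):
            cleaning.clean_pipeline(pd.DataFrame({"patient_id": []}))
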