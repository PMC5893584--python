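"""Data model, wide-table I/O and preprocessing."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_table
from uromet.datamodel import (
    RESERVED_COLUMNS,
    DesignError,
    FormatError,
    NormalizationError,
    StudyDesign,
    ValidationError,
    read_profile_table,
    write_profile_table,
)
from uromet.preprocess import (
    impute_zeros,
    normalize_to_creatinine,
    qc_repeatability,
    transform_scale,
)
from uromet.synthetic import GeneratorConfig, generate_study


class TestIO:
    def test_generated_study_has_full_crossover_row_count(self, study_table, tmp_path):
        table, _ = study_table
        path = tmp_path / "study.csv"
        table.write(path)
        back = read_profile_table(path, design=GeneratorConfig().design)
        assert len(back.experimental) == 12 * 5 * 2
        assert len(back.metabolites) == 120

    def test_write_read_round_trip_is_identity(self, study_table, tmp_path):
        table, _ = study_table
        path = tmp_path / "rt.tsv"
        write_profile_table(table, path, "wide_tsv")
        back = read_profile_table(path, "wide_tsv")
        pd.testing.assert_frame_equal(back.data, table.data)
        assert back.metabolites == table.metabolites

    def test_missing_metadata_column_is_format_error(self, study_table, tmp_path):
        table, _ = study_table
        path = tmp_path / "bad.csv"
        table.data.drop(columns=["creatinine_mmol_per_L"]).to_csv(path, index=False)
        with pytest.raises(FormatError, match="creatinine_mmol_per_L"):
            read_profile_table(path)

    def test_negative_raw_concentration_is_validation_error(self):
        with pytest.raises(ValidationError, match="negative"):
            make_table([[1.0, -2.0]])

    def test_duplicate_design_cell_is_design_error(self):
        with pytest.raises(DesignError, match="duplicate"):
            make_table(np.ones((2, 2)), subjects=["S01", "S01"],
                       times=[1, 1])

    def test_incomplete_time_series_fails_design_validation(self):
        table = make_table(np.ones((4, 2)), subjects=["S01"] * 4,
                           times=[0, 1, 2, 3])
        design = StudyDesign(subjects=("S01",), interventions=("alcohol",),
                             crossover_assignment={"S01": "alcohol"})
        with pytest.raises(DesignError, match="S01"):
            table.validate(design)


class TestStudyDesign:
    def test_default_is_two_period_crossover_over_12_subjects(self):
        d = StudyDesign()
        assert d.n_subjects == 12
        first = list(d.crossover_assignment.values())
        assert first.count("vehicle") == first.count("alcohol") == 6

    def test_one_sided_assignment_rejected(self):
        with pytest.raises(DesignError):
            StudyDesign(subjects=("A", "B"),
                        crossover_assignment={"A": "vehicle", "B": "vehicle"})


class TestNormalization:
    def test_division_by_creatinine(self):
        t = make_table([[100.0]], creatinine=[10.0])
        assert normalize_to_creatinine(t).values.iat[0, 0] == pytest.approx(10.0)

    def test_unit_creatinine_leaves_values_unchanged(self):
        t = make_table([[3.0, 7.0]], creatinine=[1.0])
        out = normalize_to_creatinine(t)
        np.testing.assert_allclose(out.values, t.values)

    def test_normalization_inverts_exactly(self, study_table):
        table, _ = study_table
        out = normalize_to_creatinine(table)
        back = out.values.mul(out.data["creatinine_mmol_per_L"], axis=0)
        np.testing.assert_allclose(back.to_numpy(), table.values.to_numpy(),
                                   rtol=1e-12)

    def test_nonpositive_creatinine_names_the_sample(self):
        t = make_table([[1.0], [1.0]], subjects=["S01", "S02"],
                       creatinine=[10.0, 0.0])
        with pytest.raises(NormalizationError, match="S02"):
            normalize_to_creatinine(t)

    def test_double_normalization_rejected(self, study_table):
        table, _ = study_table
        with pytest.raises(NormalizationError):
            normalize_to_creatinine(normalize_to_creatinine(table))


class TestImputeZeros:
    def test_half_minimum_rule(self):
        t = make_table([[0.0], [4.0], [8.0]], times=[0, 1, 2])
        out = impute_zeros(t)
        np.testing.assert_allclose(out.values["m1"], [2.0, 4.0, 8.0])
        assert out.transform_state == "imputed"

    def test_all_zero_column_dropped_and_reported(self):
        t = make_table([[0.0, 1.0], [0.0, 2.0]], times=[0, 1])
        with pytest.warns(UserWarning, match="m1"):
            out = impute_zeros(t)
        assert out.metabolites == ["m2"]
        assert out.dropped_metabolites == ["m1"]

    def test_no_zeros_is_identity(self):
        t = make_table([[1.0, 2.0], [3.0, 4.0]], times=[0, 1])
        out = impute_zeros(t)
        np.testing.assert_array_equal(out.values, t.values)


class TestTransformScale:
    def test_auto_scaling_gives_zero_mean_unit_variance(self, study_table):
        table, _ = study_table
        scaled = transform_scale(impute_zeros(normalize_to_creatinine(table)))
        vals = scaled.values
        np.testing.assert_allclose(vals.mean(), 0.0, atol=1e-10)
        np.testing.assert_allclose(vals.std(ddof=1), 1.0, atol=1e-10)

    def test_constant_column_centers_to_zero_without_scaling(self):
        t = make_table([[5.0], [5.0], [5.0]], times=[0, 1, 2],
                       transform_state="imputed")
        out = transform_scale(t, "none")
        np.testing.assert_allclose(out.values["m1"], 0.0)

    def test_retained_parameters_reproduce_training_rows(self):
        rng = np.random.default_rng(5)
        t = make_table(rng.lognormal(1, 0.5, size=(6, 3)),
                       times=[0, 1, 2, 3, 4, 0],
                       subjects=["S01"] * 5 + ["S02"],
                       transform_state="imputed")
        out = transform_scale(t, "auto")
        reproj = out.scaler.project(t.values)
        np.testing.assert_allclose(reproj.to_numpy(), out.values.to_numpy(),
                                   atol=1e-12)

    def test_zero_variance_column_flagged_under_auto(self):
        vals = np.column_stack([np.full(3, 2.0), [1.0, 2.0, 3.0]])
        t = make_table(vals, times=[0, 1, 2], transform_state="imputed")
        with pytest.warns(UserWarning, match="m1"):
            out = transform_scale(t, "auto")
        assert out.scaler.zero_variance == ["m1"]

    def test_transform_state_cannot_move_backwards(self):
        t = make_table([[1.0]], transform_state="log")
        with pytest.raises(ValidationError, match="backwards"):
            t.replace_values(t.values, transform_state="raw")

    def test_preprocessing_commutes_with_row_permutation(self, study_table):
        table, _ = study_table
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(table.data))
        shuffled = table.subset(table.data.index[perm])

        def chain(t):
            return transform_scale(impute_zeros(normalize_to_creatinine(t)))

        a = chain(table).values.to_numpy()[perm]
        b = chain(shuffled).values.to_numpy()
        np.testing.assert_allclose(a, b, atol=1e-12)


class TestQCRepeatability:
    def _batch(self, qc_values, rep_value=None, orig_value=3.0):
        """One batch: 5 conditioning QCs, usable QCs, one experimental
        sample and optionally one repeat of it."""
        rows, roles, times, subjects, orders = [], [], [], [], []
        order = 1
        for _ in range(5):  # conditioning block, must be excluded
            rows.append([999.0]); roles.append("qc"); times.append(0)
            subjects.append("POOL"); orders.append(order); order += 1
        for v in qc_values:
            rows.append([v]); roles.append("qc"); times.append(0)
            subjects.append("POOL"); orders.append(order); order += 1
        rows.append([orig_value]); roles.append("experimental"); times.append(0)
        subjects.append("S01"); orders.append(order); order += 1
        if rep_value is not None:
            rows.append([rep_value]); roles.append("repeat"); times.append(0)
            subjects.append("S01"); orders.append(order); order += 1
        return make_table(np.array(rows), roles=roles, times=times,
                          subjects=subjects, injection=orders)

    def test_identical_qc_rows_give_zero_rsd(self):
        out = qc_repeatability(self._batch([7.0, 7.0, 7.0]))
        assert out["qc_rsd_percent"].iloc[0] == 0.0

    def test_repeat_equal_to_original_gives_zero_difference(self):
        out = qc_repeatability(self._batch([7.0, 7.0], rep_value=3.0))
        assert out["repeat_max_abs_diff_percent"].iloc[0] == 0.0

    def test_three_qc_batch_matches_hand_arithmetic(self):
        vals = np.array([10.0, 10.0, 13.0])
        out = qc_repeatability(self._batch(list(vals)))
        expect = 100.0 * vals.std(ddof=1) / vals.mean()
        assert out["qc_rsd_percent"].iloc[0] == pytest.approx(expect)

    def test_conditioning_qcs_are_excluded(self):
        # usable QCs identical; the wild conditioning values must not leak in
        out = qc_repeatability(self._batch([4.0, 4.0, 4.0, 4.0]))
        assert out["qc_rsd_percent"].iloc[0] == 0.0

    def test_single_usable_qc_marks_batch_unavailable(self):
        out = qc_repeatability(self._batch([7.0]))
        assert np.isnan(out["qc_rsd_percent"].iloc[0])
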