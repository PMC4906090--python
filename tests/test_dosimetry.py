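"""MIRD dose engine: remainder S-values, coefficient folding, human-dose
scaling, cohort statistics and toxicity checks."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from prrtdose import (
    SMatrix,
    cohort_mean_sd,
    dose_coefficients,
    remainder_s_value,
    round_dose_gy,
    scale_to_administered,
    summarize_cohort,
    toxicity_check,
)
from prrtdose.dosimetry import DoseCoefficientReport


def _smatrix(values: dict, masses: dict, phantom="test") -> SMatrix:
    return SMatrix(phantom, pd.DataFrame(values).T, masses)


@pytest.fixture()
def toy3():
    """Hand-built 3-region matrix; the expected numbers below were worked
    out with pencil and paper from these entries."""
    values = {
        "a": {"a": 2.0, "b": 0.1, "total_body": 0.30},
        "b": {"a": 0.1, "b": 1.0, "total_body": 0.25},
    }
    masses = {"a": 1.0, "b": 2.0, "total_body": 10.0}
    return _smatrix(values, masses)


class TestRemainderSValue:
    def test_no_explicit_sources_returns_total_body(self, toy3):
        assert remainder_s_value(toy3, "a", []) == pytest.approx(0.30)

    def test_algebraic_identity_half_mass_equal_s(self):
        values = {"t": {"k": 0.4, "total_body": 0.4}}
        masses = {"k": 5.0, "total_body": 10.0}
        s = _smatrix(values, masses)
        assert remainder_s_value(s, "t", ["k"]) == pytest.approx(0.4)

    def test_hand_computed_toy(self, toy3):
        # [0.30*10 - 2.0*1 - 0.1*2] / (10 - 3) = 0.8 / 7
        assert remainder_s_value(toy3, "a", ["a", "b"]) == pytest.approx(0.8 / 7.0)
        # [0.25*10 - 0.1*1 - 1.0*2] / 7 = 0.4 / 7
        assert remainder_s_value(toy3, "b", ["a", "b"]) == pytest.approx(0.4 / 7.0)

    def test_nonpositive_remainder_mass_rejected(self, toy3):
        s = _smatrix(
            {"a": {"a": 1.0, "total_body": 0.5}}, {"a": 10.0, "total_body": 10.0}
        )
        with pytest.raises(ValueError, match="remainder mass"):
            remainder_s_value(s, "a", ["a"])


class TestDoseCoefficients:
    def test_diagonal_matrix_reduces_to_elementwise(self):
        organs = ["liver", "kidneys"]
        masses = {"liver": 1.8, "kidneys": 0.3, "total_body": 70.0}
        values = {o: {o2: (1.0 if o == o2 else 0.0) for o2 in organs} for o in organs}
        for o in organs:
            # consistent total-body column -> remainder S-value is exactly 0
            values[o]["total_body"] = masses[o] / masses["total_body"]
        s = _smatrix(values, masses)
        tiacs = {"liver": 4.24, "kidneys": 9.42, "remainder": 46.51}
        report = dose_coefficients(tiacs, s, "p1")
        assert report.coefficients_mgy_per_mbq["liver"] == pytest.approx(4.24)
        assert report.coefficients_mgy_per_mbq["kidneys"] == pytest.approx(9.42)

    def test_all_zero_tiacs(self, toy3):
        report = dose_coefficients({"a": 0.0, "b": 0.0}, toy3)
        assert all(v == 0.0 for v in report.coefficients_mgy_per_mbq.values())

    def test_hand_computed_with_remainder(self, toy3):
        tiacs = {"a": 2.0, "b": 3.0, "remainder": 7.0}
        report = dose_coefficients(tiacs, toy3)
        assert report.coefficients_mgy_per_mbq["a"] == pytest.approx(
            2.0 * 2.0 + 3.0 * 0.1 + 7.0 * 0.8 / 7.0
        )
        assert report.coefficients_mgy_per_mbq["b"] == pytest.approx(
            2.0 * 0.1 + 3.0 * 1.0 + 7.0 * 0.4 / 7.0
        )

    def test_unmapped_source_named(self, toy3):
        with pytest.raises(ValueError, match="spleen"):
            dose_coefficients({"a": 1.0, "spleen": 1.0}, toy3)

    @settings(derandomize=True)
    @given(k=st.floats(0.1, 8.0))
    def test_linear_in_tiacs(self, k):
        values = {
            "a": {"a": 2.0, "b": 0.1, "total_body": 0.30},
            "b": {"a": 0.1, "b": 1.0, "total_body": 0.25},
        }
        masses = {"a": 1.0, "b": 2.0, "total_body": 10.0}
        s = _smatrix(values, masses)
        base = dose_coefficients({"a": 1.1, "b": 0.7, "remainder": 3.0}, s)
        scaled = dose_coefficients(
            {"a": 1.1 * k, "b": 0.7 * k, "remainder": 3.0 * k}, s
        )
        for t in base.coefficients_mgy_per_mbq:
            assert scaled.coefficients_mgy_per_mbq[t] == pytest.approx(
                k * base.coefficients_mgy_per_mbq[t], rel=1e-12
            )


class TestScaleToAdministered:
    def test_kidney_human_prediction(self):
        doses = scale_to_administered({"kidneys": 2.73}, 5000.0)
        assert doses["kidneys"] == pytest.approx(13.65)
        assert round_dose_gy(doses["kidneys"]) == 13.7

    def test_osteogenic_human_prediction(self):
        doses = scale_to_administered({"osteogenic_cells": 0.789}, 5000.0)
        assert round_dose_gy(doses["osteogenic_cells"]) == 3.9

    def test_unit_activity(self):
        assert scale_to_administered({"x": 2.0}, 1.0)["x"] == pytest.approx(0.002)

    def test_nonpositive_activity_rejected(self):
        with pytest.raises(ValueError):
            scale_to_administered({"x": 1.0}, 0.0)


class TestCohortStats:
    def test_kidney_tiacs(self, study_tiacs):
        values = dict(study_tiacs.loc["kidneys"])
        mean, sd = cohort_mean_sd(values)
        assert mean == pytest.approx(9.42, abs=0.005)
        assert sd == pytest.approx(3.58, abs=0.005)

    def test_kidney_tiacs_excluding_pig4(self, study_tiacs):
        mean, sd = cohort_mean_sd(dict(study_tiacs.loc["kidneys"]), exclude=["pig4"])
        assert mean == pytest.approx(7.92, abs=0.005)
        assert sd == pytest.approx(1.46, abs=0.005)

    def test_identical_values_sd_zero(self):
        mean, sd = cohort_mean_sd({"a": 2.0, "b": 2.0, "c": 2.0})
        assert (mean, sd) == (2.0, 0.0)

    def test_too_few_after_exclusion_rejected(self):
        with pytest.raises(ValueError, match="n >= 2"):
            cohort_mean_sd({"a": 1.0, "b": 2.0}, exclude=["b"])

    def test_summarize_cohort_records_exclusions(self):
        reports = [
            DoseCoefficientReport(f"p{i}", {"kidneys": float(i)}) for i in range(1, 5)
        ]
        summary = summarize_cohort(reports, exclude=["p4"])
        assert summary.n == 3
        assert summary.excluded == ("p4",)
        assert summary.mean["kidneys"] == pytest.approx(2.0)


class TestToxicity:
    def test_kidneys_pass_with_margin(self):
        out = toxicity_check({"kidneys": 13.7})
        assert out["kidneys"].passed is True
        assert out["kidneys"].margin_gy == pytest.approx(9.3)

    def test_boundary_inclusive_failure(self):
        assert toxicity_check({"kidneys": 23.0})["kidneys"].passed is False

    def test_organ_without_limit_unchecked(self):
        out = toxicity_check({"liver": 1.0})
        assert out["liver"].passed is None

    def test_negative_dose_rejected(self):
        with pytest.raises(ValueError):
            toxicity_check({"kidneys": -1.0})


class TestSMatrixIO:
    def test_toy_matrix_loads_with_masses(self, toy_s):
        assert "kidneys" in toy_s.sources
        assert toy_s.masses_kg["total_body"] == pytest.approx(73.7)
        assert toy_s.s("kidneys", "kidneys") > toy_s.s("kidneys", "liver")

    def test_negative_values_rejected(self):
        with pytest.raises(ValueError):
            _smatrix({"a": {"a": -1.0, "total_body": 0.1}}, {"a": 1.0, "total_body": 10.0})

    def test_source_without_mass_rejected(self):
        with pytest.raises(ValueError, match="mass"):
            _smatrix({"a": {"a": 1.0, "total_body": 0.1}}, {"total_body": 10.0})

    def test_self_dose_below_cross_dose_warns(self):
        with pytest.warns(UserWarning, match="self-dose"):
            _smatrix(
                {"a": {"a": 0.1, "b": 1.0, "total_body": 0.1}},
                {"a": 1.0, "b": 1.0, "total_body": 10.0},
            )
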