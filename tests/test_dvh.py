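"""Dose-volume curve metrics: interpolation, indices and their invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from kbplan.dvh import (
    ConformityInputs,
    DoseMetricSpec,
    DVHCurve,
    DVHValidationError,
    MetricDomainError,
    MetricKind,
    PlanRecord,
    ci_inputs_from_plan,
    conformity_index,
    dose_at_absolute_volume,
    dose_at_volume,
    evaluate_metric,
    evaluate_metric_on_curve,
    homogeneity_index,
    mean_dose,
    minimum_dose,
    volume_at_dose,
)

from conftest import random_monotone_curve


class TestCurveValidation:
    def test_rejects_short_unsorted_or_nonmonotone(self):
        with pytest.raises(DVHValidationError):
            DVHCurve("x", 10, np.array([0.0]), np.array([1.0]))
        with pytest.raises(DVHValidationError):
            DVHCurve("x", 10, np.array([0.0, 5.0, 5.0]), np.array([1.0, 0.5, 0.2]))
        with pytest.raises(DVHValidationError):
            DVHCurve("x", 10, np.array([0.0, 5.0, 10.0]), np.array([1.0, 0.4, 0.6]))
        with pytest.raises(DVHValidationError):
            DVHCurve("x", -1, np.array([0.0, 5.0]), np.array([1.0, 0.5]))
        with pytest.raises(DVHValidationError):
            DVHCurve("x", 10, np.array([1.0, 5.0]), np.array([1.0, 0.5]))

    def test_sub_tolerance_glitch_repaired(self):
        c = DVHCurve(
            "x", 10, np.array([0.0, 5.0, 10.0]), np.array([1.0, 0.5, 0.5 + 5e-10])
        )
        assert np.all(np.diff(c.rel_volume) <= 0)


class TestVolumeAtDose:
    @pytest.mark.parametrize(
        "dose, expected", [(0.0, 1.0), (25.0, 0.0), (15.0, 0.25), (10.0, 0.5)]
    )
    def test_interpolation(self, ramp_curve, dose, expected):
        assert volume_at_dose(ramp_curve, dose) == pytest.approx(expected)

    def test_negative_dose_rejected(self, ramp_curve):
        with pytest.raises(MetricDomainError):
            volume_at_dose(ramp_curve, -1.0)


class TestDoseAtVolume:
    @pytest.mark.parametrize(
        "fraction, expected", [(0.5, 10.0), (1.0, 0.0), (0.25, 15.0)]
    )
    def test_inverse_interpolation(self, ramp_curve, fraction, expected):
        assert dose_at_volume(ramp_curve, fraction) == pytest.approx(expected)

    def test_full_coverage_plateau(self, plateau_curve):
        assert dose_at_volume(plateau_curve, 1.0) == pytest.approx(10.0)

    def test_out_of_range_fraction(self, ramp_curve):
        with pytest.raises(MetricDomainError):
            dose_at_volume(ramp_curve, 1.5)

    def test_round_trip_on_random_strictly_decreasing_curves(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            c = random_monotone_curve(rng)
            for f in rng.uniform(0.01, 0.99, size=5):
                d = dose_at_volume(c, f)
                assert volume_at_dose(c, d) == pytest.approx(f, abs=1e-9)


class TestMeanDose:
    def test_triangle_and_plateau(self, plateau_curve):
        tri = DVHCurve("t", 10, np.array([0.0, 10.0]), np.array([1.0, 0.0]))
        assert mean_dose(tri) == pytest.approx(5.0)
        assert mean_dose(plateau_curve) == pytest.approx(15.0)
        flat = DVHCurve("f", 10, np.array([0.0, 1.0]), np.array([1.0, 1.0]))
        assert mean_dose(flat) == pytest.approx(1.0)

    def test_dose_rescaling_scales_mean(self):
        rng = np.random.default_rng(3)
        for k in (0.5, 2.0, 3.7):
            c = random_monotone_curve(rng)
            scaled = DVHCurve(c.structure_name, c.volume_cc, k * c.dose_grid, c.rel_volume)
            assert mean_dose(scaled) == pytest.approx(k * mean_dose(c), rel=1e-12)


class TestNearMaxAndMin:
    def test_hot_spot_dose(self):
        c = DVHCurve("t", 60.0, np.array([0.0, 50.0]), np.array([1.0, 0.0]))
        assert dose_at_absolute_volume(c, 0.03) == pytest.approx(49.975)

    def test_whole_structure_is_the_plateau_end(self, ramp_curve):
        assert dose_at_absolute_volume(ramp_curve, ramp_curve.volume_cc) == 0.0

    def test_half_structure(self):
        c = DVHCurve("t", 40.0, np.array([0.0, 10.0, 20.0]), np.array([1.0, 0.5, 0.0]))
        assert dose_at_absolute_volume(c, 20.0) == pytest.approx(10.0)

    def test_cc_beyond_volume_rejected(self, ramp_curve):
        with pytest.raises(MetricDomainError):
            dose_at_absolute_volume(ramp_curve, ramp_curve.volume_cc + 1)

    def test_minimum_dose_plateau(self, plateau_curve, ramp_curve):
        assert minimum_dose(plateau_curve) == pytest.approx(10.0)
        assert minimum_dose(ramp_curve) == 0.0


class TestConformity:
    def test_examples(self):
        assert conformity_index(ConformityInputs(100, 100, 100)) == 1.0
        assert conformity_index(ConformityInputs(100, 90, 150)) == pytest.approx(0.54)
        assert conformity_index(ConformityInputs(100, 0, 150)) == 0.0

    def test_invalid_inputs(self):
        with pytest.raises(MetricDomainError):
            ConformityInputs(0, 0, 100)
        with pytest.raises(MetricDomainError):
            ConformityInputs(100, 120, 100)

    @given(
        v_t=hst.floats(1, 1e3),
        cov=hst.floats(0, 1),
        extra=hst.floats(0, 1e3),
    )
    @settings(max_examples=200, deadline=None)
    def test_ci_always_in_unit_interval(self, v_t, cov, extra):
        v_tref = v_t * cov
        v_ref = v_tref + extra if v_tref + extra > 0 else 1e-6
        ci = conformity_index(ConformityInputs(v_t, min(v_tref, v_ref), v_ref))
        assert 0.0 <= ci <= 1.0

    def test_inputs_from_plan_composition(self):
        grid = np.array([0.0, 42.0, 43.0, 80.0])
        target = DVHCurve("t", 100.0, grid, np.array([1.0, 0.95, 0.9, 0.0]))
        body = DVHCurve("body", 200.0, grid, np.array([1.0, 0.8, 0.75, 0.0]))
        inputs = ci_inputs_from_plan(target, body, rx=45.0, iso_fraction=43.0 / 45.0)
        assert inputs.v_t == 100.0
        assert inputs.v_tref == pytest.approx(90.0)
        assert inputs.v_ref == pytest.approx(150.0)
        assert conformity_index(inputs) == pytest.approx(0.54)

    def test_zero_iso_fraction_covers_everything(self):
        grid = np.array([0.0, 10.0])
        target = DVHCurve("t", 50.0, grid, np.array([1.0, 0.0]))
        body = DVHCurve("body", 500.0, grid, np.array([1.0, 0.0]))
        inputs = ci_inputs_from_plan(target, body, rx=45.0, iso_fraction=0.0)
        assert inputs.v_tref == 50.0 and inputs.v_ref == 500.0


class TestHomogeneity:
    def test_rectangular_curve_is_perfectly_homogeneous(self):
        c = DVHCurve("t", 10, np.array([0.0, 45.0, 45.0001]), np.array([1.0, 1.0, 0.0]))
        assert homogeneity_index(c) == pytest.approx(0.0, abs=1e-5)

    def test_known_spread(self):
        # linear drop from full coverage at 40 Gy to zero at 50 Gy:
        # D2 = 49.8, D98 = 40.2, D50 = 45
        c = DVHCurve("t", 10, np.array([0.0, 40.0, 50.0]), np.array([1.0, 1.0, 0.0]))
        assert homogeneity_index(c) == pytest.approx((49.8 - 40.2) / 45.0)

    def test_hi_nonnegative_on_random_curves(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            assert homogeneity_index(random_monotone_curve(rng)) >= 0.0


class TestEvaluateMetric:
    def _plan(self, curves):
        return PlanRecord("p1", curves, {"pgtvnd": 60.0, "pctv": 45.0})

    def test_dispatch(self, ramp_curve):
        plan = self._plan({"ramp": ramp_curve})
        v18 = DoseMetricSpec(MetricKind.VOLUME_AT_DOSE, 18.0)
        assert evaluate_metric(plan, "ramp", v18) == pytest.approx(10.0)  # percent
        dmean = DoseMetricSpec(MetricKind.MEAN_DOSE)
        tri = self._plan({"t": DVHCurve("t", 10, np.array([0.0, 10.0]), np.array([1.0, 0.0]))})
        assert evaluate_metric(tri, "t", dmean) == pytest.approx(5.0)

    def test_unknown_structure(self, ramp_curve):
        plan = self._plan({"ramp": ramp_curve})
        with pytest.raises(LookupError):
            evaluate_metric(plan, "missing", DoseMetricSpec(MetricKind.MEAN_DOSE))

    def test_agrees_with_fine_grid_recomputation(self):
        """Endpoints on a coarse curve match a 0.001 Gy brute-force regrid."""
        rng = np.random.default_rng(21)
        specs = [
            DoseMetricSpec(MetricKind.VOLUME_AT_DOSE, 18.0),
            DoseMetricSpec(MetricKind.DOSE_AT_RELATIVE_VOLUME, 35.0),
            DoseMetricSpec(MetricKind.MEAN_DOSE),
        ]
        for _ in range(10):
            c = random_monotone_curve(rng)
            fine_grid = np.arange(0.0, c.dose_grid[-1] + 0.001, 0.001)
            fine = DVHCurve(
                c.structure_name,
                c.volume_cc,
                fine_grid,
                np.interp(fine_grid, c.dose_grid, c.rel_volume),
            )
            for spec in specs:
                a = evaluate_metric_on_curve(c, spec)
                b = evaluate_metric_on_curve(fine, spec)
                assert a == pytest.approx(b, abs=2e-3)
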