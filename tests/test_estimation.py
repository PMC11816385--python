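"""Per-point inversion, grid fit, error propagation, weighted averaging."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bwsle import (
    BWModel,
    SLEDataset,
    SLEPoint,
    aad,
    bw_branch_temperature,
    curve_sensitivity,
    estimate_zw_from_point,
    estimate_zw_pointwise,
    fit_zw_grid,
    liquidus_temperature,
    weighted_mean_zw,
    zw_error_from_enthalpy,
    zw_error_from_temperature,
    zw_error_from_tm,
)
from bwsle.estimators import zw_from_branch_point
from bwsle.synthetic import SyntheticSpec, generate_dataset

KJ = 1000.0


def _branch_point(pair, zw, x):
    """A melting point lying exactly on the A branch of (pair, zw)."""
    t = bw_branch_temperature(BWModel(pair, zw), "A", x)
    return SLEPoint(x, float(t))


class TestPointInversion:
    def test_algebraic_round_trip(self, menthol_lauric):
        point = _branch_point(menthol_lauric, -10 * KJ, 0.3)
        zw_a, _, _ = estimate_zw_from_point(menthol_lauric, point)
        assert zw_a == pytest.approx(-10 * KJ, abs=1e-6)

    def test_ideal_branch_gives_zero(self, menthol_lauric):
        point = _branch_point(menthol_lauric, 0.0, 0.4)
        zw_a, _, _ = estimate_zw_from_point(menthol_lauric, point)
        assert zw_a == pytest.approx(0.0, abs=1e-8)

    def test_chosen_is_numerically_smaller(self, menthol_lauric):
        # a point on the true liquidus: inverting the non-limiting branch
        # overshoots, so the chosen (min) estimate sits on the limiting branch
        model = BWModel(menthol_lauric, -8 * KJ)
        for x in (0.2, 0.5, 0.8):
            t = liquidus_temperature(model, x)
            zw_a, zw_b, chosen = estimate_zw_from_point(
                menthol_lauric, SLEPoint(x, float(t)))
            assert chosen == min(zw_a, zw_b)
            assert chosen == pytest.approx(-8 * KJ, abs=1e-6)

    def test_boundary_point_rejected(self, menthol_lauric):
        with pytest.raises(ValueError, match="boundary"):
            estimate_zw_from_point(menthol_lauric, SLEPoint(1.0, 315.7))

    @settings(max_examples=80, deadline=None, derandomize=True)
    @given(zw=st.floats(-40 * KJ, 20 * KJ), x=st.floats(0.1, 0.9))
    def test_round_trip_property(self, menthol_lauric, zw, x):
        t = bw_branch_temperature(BWModel(menthol_lauric, zw), "A", x)
        if np.isnan(t):
            return  # nonphysical forward map: nothing to invert
        assert zw_from_branch_point(menthol_lauric.a, x, float(t)) == pytest.approx(
            zw, abs=1e-8 * KJ)


class TestGridFit:
    def test_noise_free_recovery_within_one_step(self, menthol_lauric):
        ds = generate_dataset(SyntheticSpec(menthol_lauric, -20 * KJ, 15, noise_sd=0.0))
        res = fit_zw_grid(ds)
        assert res.zw == pytest.approx(-20 * KJ, abs=100.0)
        assert res.n_points_used == 15

    def test_ideal_data_fits_zero(self, menthol_lauric):
        ds = generate_dataset(SyntheticSpec(menthol_lauric, 0.0, 12, noise_sd=0.0))
        res = fit_zw_grid(ds)
        assert res.zw == 0.0
        assert res.aad_bw == pytest.approx(0.0, abs=1e-10)
        assert res.aad_ideal == pytest.approx(0.0, abs=1e-10)

    def test_fit_never_worse_than_ideal(self, menthol_lauric):
        ds = generate_dataset(SyntheticSpec(menthol_lauric, -6 * KJ, 20,
                                            noise_sd=3.0, seed=7))
        res = fit_zw_grid(ds)
        assert res.aad_bw <= res.aad_ideal

    def test_refinement_improves_off_grid_truth(self, menthol_lauric):
        ds = generate_dataset(SyntheticSpec(menthol_lauric, -8.05 * KJ, 15, noise_sd=0.0))
        coarse = fit_zw_grid(ds)
        fine = fit_zw_grid(ds, refine=True)
        assert fine.aad_bw <= coarse.aad_bw
        assert abs(fine.zw + 8.05 * KJ) < abs(coarse.zw + 8.05 * KJ) + 1e-9

    def test_tie_breaks_toward_smallest_magnitude(self, menthol_lauric):
        # single point exactly on the ideal curve: a whole interval of
        # candidates has tiny objective, but zero residual only at zw = 0
        t = liquidus_temperature(BWModel(menthol_lauric, 0.0), 0.5)
        ds = SLEDataset(menthol_lauric, (SLEPoint(0.5, float(t)),))
        assert fit_zw_grid(ds).zw == 0.0

    def test_boundary_points_excluded_with_warning(self, menthol_lauric):
        t = liquidus_temperature(BWModel(menthol_lauric, -5 * KJ), 0.5)
        ds = SLEDataset(menthol_lauric, (
            SLEPoint(0.5, float(t)), SLEPoint(1.0, 315.7)))
        with pytest.warns(UserWarning, match="boundary"):
            res = fit_zw_grid(ds)
        assert res.n_points_used == 1

    def test_empty_dataset_errors(self, menthol_lauric):
        ds = SLEDataset(menthol_lauric, (SLEPoint(1.0, 315.7),))
        with pytest.warns(UserWarning), pytest.raises(ValueError, match="interior"):
            fit_zw_grid(ds)


class TestAAD:
    def test_zero_on_model_points(self, menthol_lauric):
        model = BWModel(menthol_lauric, -7 * KJ)
        x = np.linspace(0.1, 0.9, 9)
        t = np.asarray(liquidus_temperature(model, x))
        ds = SLEDataset(menthol_lauric, tuple(
            SLEPoint(float(a), float(b)) for a, b in zip(x, t)))
        assert aad(ds, model) == pytest.approx(0.0, abs=1e-12)

    def test_mean_of_absolute_residuals(self, menthol_lauric):
        model = BWModel(menthol_lauric, 0.0)
        x = np.array([0.3, 0.6])
        t = np.asarray(liquidus_temperature(model, x)) + np.array([2.0, -4.0])
        ds = SLEDataset(menthol_lauric, tuple(
            SLEPoint(float(a), float(b)) for a, b in zip(x, t)))
        assert aad(ds, model) == pytest.approx(3.0)


class TestErrorPropagation:
    X_PROBE = (0.2, 0.5, 0.8)

    def _fd(self, f, v, h):
        return (f(v + h) - f(v - h)) / (2 * h)

    def test_formulas_match_finite_differences(self, all_pairs):
        """The three propagated errors are the exact partial derivatives of
        the per-point inversion in T, dHm and Tm — on the chosen branch."""
        from bwsle import PureCompound
        for pair in all_pairs:
            for x in self.X_PROBE:
                t = float(liquidus_temperature(BWModel(pair, -5 * KJ), x))
                point = SLEPoint(x, t)
                zw_a, zw_b, _ = estimate_zw_from_point(pair, point)
                c, xc = (pair.a, x) if zw_a <= zw_b else (pair.b, 1 - x)

                d_t = self._fd(lambda v: zw_from_branch_point(c, xc, v), t, 1e-4)
                assert zw_error_from_temperature(pair, point, 1.0) == pytest.approx(
                    abs(d_t), rel=1e-4)

                d_h = self._fd(lambda v: zw_from_branch_point(
                    PureCompound(c.name, c.tm, v), xc, t), c.dhm, 1e-4 * c.dhm)
                assert zw_error_from_enthalpy(pair, point, 1.0) == pytest.approx(
                    abs(d_h), rel=1e-4)

                d_tm = self._fd(lambda v: zw_from_branch_point(
                    PureCompound(c.name, v, c.dhm), xc, t), c.tm, 1e-4 * c.tm)
                assert zw_error_from_tm(pair, point, 1.0) == pytest.approx(
                    abs(d_tm), rel=1e-4)

    def test_enthalpy_error_vanishes_at_branch_tm(self, menthol_lauric):
        # measuring a branch point at the branch compound's own melting
        # temperature makes the inversion independent of its enthalpy
        from bwsle.estimators import zw_error_from_enthalpy as raw
        assert float(raw(menthol_lauric.a, 0.5, menthol_lauric.a.tm, 5 * KJ)) == 0.0

    def test_boundary_blowup(self, menthol_lauric):
        """Each error diverges as (1-x)^-2 toward the pure-A boundary."""
        t = 300.0
        mid = SLEPoint(0.5, t)
        edge = SLEPoint(0.999, t)
        for fn, mag in [(zw_error_from_temperature, 5.0),
                        (zw_error_from_enthalpy, 5 * KJ),
                        (zw_error_from_tm, 5.0)]:
            assert fn(menthol_lauric, edge, mag) >= 1e4 * fn(menthol_lauric, mid, mag)

    def test_rejects_nonpositive_perturbation(self, menthol_lauric):
        with pytest.raises(ValueError, match="positive"):
            zw_error_from_temperature(menthol_lauric, SLEPoint(0.5, 300.0), 0.0)


class TestCurveSensitivity:
    def test_matches_finite_difference_in_zw(self, menthol_lauric):
        model = BWModel(menthol_lauric, -8 * KJ)
        for x in (0.2, 0.5, 0.8):
            t1 = bw_branch_temperature(model, "A", x)
            t2 = bw_branch_temperature(BWModel(menthol_lauric, -8 * KJ + 1.0), "A", x)
            assert curve_sensitivity(model, x, 1.0) == pytest.approx(
                float(t2 - t1), rel=1e-4)

    def test_vanishes_at_pure_compound(self, menthol_lauric):
        model = BWModel(menthol_lauric, -8 * KJ)
        assert curve_sensitivity(model, 1.0, 1 * KJ) == 0.0

    def test_bounded_over_composition(self, all_pairs):
        """No singular point: the liquidus responds boundedly to zw
        everywhere, unlike the per-point inverse problem."""
        x = np.linspace(1e-4, 1 - 1e-4, 2000)
        for pair in all_pairs:
            s = curve_sensitivity(BWModel(pair, 0.0), x, 1 * KJ)
            assert np.all(np.isfinite(s))
            assert np.nanmax(np.abs(s)) < 1e3  # kelvin, for a 1 kJ/mol change


class TestWeightedMean:
    def test_equal_errors_give_arithmetic_mean(self):
        mean, err = weighted_mean_zw([-10.0, -20.0, -30.0], [2.0, 2.0, 2.0])
        assert mean == pytest.approx(-20.0)
        assert err == pytest.approx(2.0 / np.sqrt(3))

    def test_closed_form_two_points(self):
        mean, err = weighted_mean_zw([-10.0, -20.0], [1.0, 2.0])
        assert mean == pytest.approx(-12.0)
        assert err == pytest.approx(2.0 / np.sqrt(5.0))

    def test_infinite_error_point_ignored(self):
        mean, _ = weighted_mean_zw([-10.0, 999.0], [1.0, np.inf])
        assert mean == pytest.approx(-10.0)

    def test_mean_within_range_of_estimates(self, menthol_lauric):
        ds = generate_dataset(SyntheticSpec(menthol_lauric, -9 * KJ, 15,
                                            noise_sd=1.5, seed=3))
        est = estimate_zw_pointwise(ds)
        assert est.zw_chosen.min() <= est.weighted_mean <= est.zw_chosen.max()

    def test_all_infinite_raises(self):
        with pytest.raises(ValueError, match="weights"):
            weighted_mean_zw([1.0], [np.inf])
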