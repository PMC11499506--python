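"""Patlak transform/fit, MRGlu arithmetic, TAC extraction, smoothing.

The two-tissue-compartment oracle here integrates the kinetic ODEs with
scipy's solve_ivp, independently of the exponential-integrator route used by
the phantom generator.
"""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from petglu.errors import (
    ConfigError,
    DegenerateInput,
    GeometryError,
    TimeGridMismatch,
)
from petglu.imaging import (
    DynamicPETSeries,
    FrameSchedule,
    ImageGeometry,
    TimeActivityCurve,
    VOIMask,
)
from petglu.kinetics import (
    MRGluResult,
    compute_mrglu,
    compute_tac,
    filter_negative,
    fit_patlak,
    patlak_transform,
    smooth_frames,
)
from petglu.phantom import InputFunctionParams, net_influx_ki


def ode_tissue_curve(t_min, cp_fn, k1, k2, k3):
    """Independent 2TC oracle: solve dC1/dt, dC2/dt with solve_ivp."""

    def rhs(t, y):
        return [k1 * cp_fn(t) - (k2 + k3) * y[0], k3 * y[0]]

    sol = solve_ivp(rhs, (0.0, float(t_min[-1])), [0.0, 0.0], t_eval=t_min,
                    rtol=1e-9, atol=1e-12, max_step=0.1)
    return sol.y[0] + sol.y[1]


def make_tac(t_min, values, label="t"):
    return TimeActivityCurve(np.asarray(t_min, float), np.asarray(values, float),
                             voxel_count=10, label=label)


class TestComputeTac:
    def test_constant_field(self):
        geom = ImageGeometry((4, 4, 4), (2, 2, 2))
        sched = FrameSchedule.from_durations([60.0] * 3)
        series = DynamicPETSeries(np.full((4, 4, 4, 3), 10.0), geom, sched)
        mask = np.zeros((4, 4, 4), dtype=bool)
        mask[1:3, 1:3, 1:3] = True
        tac = compute_tac(series, VOIMask(mask, geom))
        assert np.all(tac.activity == 10.0)

    def test_mean_arithmetic(self):
        geom = ImageGeometry((4, 1, 1), (2, 2, 2))
        sched = FrameSchedule.from_durations([60.0])
        vox = np.zeros((4, 1, 1, 1))
        vox[0, 0, 0, 0] = 4.0
        vox[1, 0, 0, 0] = 8.0
        mask = np.zeros((4, 1, 1), dtype=bool)
        mask[:2] = True
        tac = compute_tac(DynamicPETSeries(vox, geom, sched), VOIMask(mask, geom))
        assert tac.activity[0] == pytest.approx(6.0)

    def test_grid_mismatch(self, pet_phantom):
        pet, truth = pet_phantom
        other = ImageGeometry((4, 4, 4), (2, 2, 2))
        voi = VOIMask(np.ones((4, 4, 4), dtype=bool), other)
        with pytest.raises(GeometryError):
            compute_tac(pet, voi)

    def test_requires_decay_correction(self, pet_phantom):
        pet, truth = pet_phantom
        raw = DynamicPETSeries(pet.voxels, pet.geometry, pet.schedule,
                               decay_corrected=False)
        with pytest.raises(ConfigError):
            compute_tac(raw, truth.mask_voi("aorta"))

    def test_aorta_tac_tracks_blood_curve(self, pet_phantom):
        pet, truth = pet_phantom
        tac = compute_tac(pet, truth.mask_voi("aorta"))
        cp = truth.input_tac.activity
        late = tac.mid_times_min > 1.0
        assert np.all(np.abs(tac.activity - cp)[late] / cp[late] <= 0.05)


class TestPatlakTransform:
    def test_constant_input_linear_tissue_exact(self):
        t = [0.0, 1.0, 2.0, 3.0]
        cp = make_tac(t, [10.0] * 4)
        ct = make_tac(t, [10.0 * (0.05 * ti + 0.2) for ti in t])
        pts = patlak_transform(ct, cp)
        assert np.allclose(pts.x_min, [0.0, 1.0, 2.0, 3.0], atol=1e-12)
        assert np.allclose(pts.y, [0.20, 0.25, 0.30, 0.35], atol=1e-12)

    def test_zero_tissue_gives_zero_y(self):
        t = [0.5, 1.0, 2.0]
        pts = patlak_transform(make_tac(t, [0.0] * 3), make_tac(t, [5.0, 6.0, 7.0]))
        assert np.all(pts.y == 0.0)

    def test_mismatched_grids_raise(self):
        with pytest.raises(TimeGridMismatch):
            patlak_transform(make_tac([1.0, 2.0], [1, 1]),
                             make_tac([1.0, 3.0], [1, 1]))

    def test_nonpositive_input_frames_dropped(self):
        t = [0.5, 1.0, 2.0, 3.0]
        pts = patlak_transform(make_tac(t, [1, 1, 1, 1]),
                               make_tac(t, [5.0, 0.0, 6.0, 7.0]))
        assert pts.dropped == [1]
        assert len(pts) == 3

    def test_all_dropped_raises(self):
        t = [1.0, 2.0]
        with pytest.raises(DegenerateInput):
            patlak_transform(make_tac(t, [1, 1]), make_tac(t, [0.0, -1.0]))

    def test_late_points_collinear_for_2tc(self):
        """Biexponential-like input with 2TC tissue: the Patlak plot becomes
        a straight line at late times (r^2 >= 0.999 over the last 10 points)."""
        k1, k2, k3 = 0.6, 1.2, 0.1
        cp_params = InputFunctionParams()
        t = np.linspace(0.5, 40.0, 30)
        cp = cp_params(t)
        ct = ode_tissue_curve(t, cp_params, k1, k2, k3)
        pts = patlak_transform(make_tac(t, ct), make_tac(t, cp))
        fit = fit_patlak(pts, float(pts.t_min[-10]))
        assert fit.n_points == 10
        assert fit.r_squared >= 0.999

    def test_scale_invariance_of_slope(self):
        """Rescaling both TACs by the same constant leaves Ki and the
        intercept unchanged."""
        k1, k2, k3 = 0.3, 0.6, 0.05
        cp_params = InputFunctionParams()
        t = np.linspace(0.5, 40.0, 25)
        cp = cp_params(t)
        ct = ode_tissue_curve(t, cp_params, k1, k2, k3)
        f0 = fit_patlak(patlak_transform(make_tac(t, ct), make_tac(t, cp)), 10.0)
        f1 = fit_patlak(
            patlak_transform(make_tac(t, 3.7 * ct), make_tac(t, 3.7 * cp)), 10.0
        )
        assert f1.Ki == pytest.approx(f0.Ki, rel=1e-12)
        assert f1.intercept == pytest.approx(f0.intercept, rel=1e-12)


class TestFitPatlak:
    def _exact_points(self):
        t = [0.0, 1.0, 2.0, 3.0]
        cp = make_tac(t, [10.0] * 4)
        ct = make_tac(t, [10.0 * (0.05 * ti + 0.2) for ti in t])
        return patlak_transform(ct, cp)

    def test_exact_line(self):
        fit = fit_patlak(self._exact_points(), 0.0)
        assert fit.Ki == pytest.approx(0.05, abs=1e-12)
        assert fit.intercept == pytest.approx(0.20, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_t_star_beyond_data_raises(self):
        with pytest.raises(DegenerateInput):
            fit_patlak(self._exact_points(), 99.0)

    def test_ki_recovery_against_ode_oracle(self):
        k1, k2, k3 = 0.6, 1.2, 0.1
        cp_params = InputFunctionParams()
        t = np.linspace(0.25, 45.0, 40)
        cp = cp_params(t)
        ct = ode_tissue_curve(t, cp_params, k1, k2, k3)
        fit = fit_patlak(patlak_transform(make_tac(t, ct), make_tac(t, cp)), 10.0)
        ki_true = net_influx_ki(k1, k2, k3)
        assert ki_true == pytest.approx(0.046154, abs=1e-6)
        assert abs(fit.Ki - ki_true) / ki_true <= 0.05

    def test_auto_t_star_on_exact_line_uses_all_points(self):
        fit = fit_patlak(self._exact_points(), "auto")
        assert fit.t_star_min == 0.0
        assert fit.n_points == 4

    def test_auto_t_star_skips_early_curvature(self):
        k1, k2, k3 = 0.6, 0.6, 0.1
        cp_params = InputFunctionParams()
        t = np.linspace(0.25, 45.0, 40)
        cp = cp_params(t)
        ct = ode_tissue_curve(t, cp_params, k1, k2, k3)
        fit = fit_patlak(patlak_transform(make_tac(t, ct), make_tac(t, cp)), "auto")
        ki_true = net_influx_ki(k1, k2, k3)
        assert abs(fit.Ki - ki_true) / ki_true <= 0.05
        assert fit.t_star_min > t[0]


class TestMRGlu:
    def test_unit_conversion_arithmetic(self):
        fit = fit_patlak(
            patlak_transform(
                make_tac([0, 1, 2, 3], [10 * (0.025 * t + 0.2) for t in range(4)]),
                make_tac([0, 1, 2, 3], [10.0] * 4),
            ),
            0.0,
        )
        res = compute_mrglu(fit, 100.0, 1.0, "aorta")
        # 100 mg/dL = 5.5506 umol/mL; 0.025 * 5.5506 * 100 = 13.876
        assert res.value == pytest.approx(13.876, abs=1e-3)
        assert not res.negative

    def test_zero_ki(self):
        pts = patlak_transform(make_tac([0, 1, 2, 3], [2.0] * 4),
                               make_tac([0, 1, 2, 3], [10.0] * 4))
        res = compute_mrglu(fit_patlak(pts, 0.0), 100.0, 1.0)
        assert res.value == pytest.approx(0.0, abs=1e-12)
        assert not res.negative

    def test_negative_ki_propagates_sign(self):
        t = [0.0, 1.0, 2.0, 3.0]
        ct = make_tac(t, [10 * (-0.005 * ti + 0.5) for ti in t])
        res = compute_mrglu(fit_patlak(patlak_transform(ct, make_tac(t, [10.0] * 4)),
                                       0.0), 100.0, 1.0)
        assert res.value == pytest.approx(-2.775, abs=5e-4)
        assert res.negative

    def test_linear_in_glucose_inverse_in_lc(self):
        fit = fit_patlak(self_points(), 0.0)
        base = compute_mrglu(fit, 90.0, 1.0).value
        assert compute_mrglu(fit, 180.0, 1.0).value == pytest.approx(2 * base)
        assert compute_mrglu(fit, 90.0, 0.5).value == pytest.approx(2 * base)

    def test_invalid_inputs(self):
        fit = fit_patlak(self_points(), 0.0)
        with pytest.raises(ConfigError):
            compute_mrglu(fit, 0.0, 1.0)
        with pytest.raises(ConfigError):
            compute_mrglu(fit, 100.0, -1.0)


def self_points():
    t = [0.0, 1.0, 2.0, 3.0]
    return patlak_transform(
        make_tac(t, [10.0 * (0.05 * ti + 0.2) for ti in t]),
        make_tac(t, [10.0] * 4),
    )


class TestFilterNegative:
    @staticmethod
    def _result(value):
        return MRGluResult(value=value, district="d", Ki=value / 555.06,
                           plasma_glucose_mg_dl=100.0, lumped_constant=1.0)

    def test_partition_by_sign(self):
        res = [self._result(v) for v in (-2.5, 1.1, 0.0, 3.4)]
        kept, excluded = filter_negative(res)
        assert [r.value for r in kept] == [1.1, 0.0, 3.4]
        assert [r.value for r in excluded] == [-2.5]

    def test_all_nonnegative(self):
        kept, excluded = filter_negative([self._result(v) for v in (0.0, 2.0)])
        assert excluded == []

    def test_partition_is_exhaustive(self):
        rng = np.random.default_rng(3)
        res = [self._result(v) for v in rng.normal(0, 5, 20)]
        kept, excluded = filter_negative(res)
        assert len(kept) + len(excluded) == 20


class TestSmoothFrames:
    def _series(self):
        geom = ImageGeometry((16, 16, 16), (2, 2, 2))
        sched = FrameSchedule.from_durations([60.0] * 2)
        vox = np.zeros((16, 16, 16, 2))
        vox[8, 8, 8, :] = 100.0
        return DynamicPETSeries(vox, geom, sched)

    def test_zero_fwhm_is_identity(self):
        s = self._series()
        assert smooth_frames(s, 0.0) is s

    def test_constant_field_unchanged(self):
        geom = ImageGeometry((8, 8, 8), (2, 2, 2))
        sched = FrameSchedule.from_durations([60.0])
        s = DynamicPETSeries(np.full((8, 8, 8, 1), 3.0), geom, sched)
        out = smooth_frames(s, 6.0)
        assert np.allclose(out.voxels, 3.0, atol=1e-10)

    def test_point_source_total_activity_conserved(self):
        out = smooth_frames(self._series(), 5.0)
        for f in range(2):
            assert out.voxels[..., f].sum() == pytest.approx(100.0, rel=1e-3)

    def test_negative_fwhm_rejected(self):
        with pytest.raises(ConfigError):
            smooth_frames(self._series(), -1.0)
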