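"""Extended Tofts model, AIF fitting, T1 mapping, concentration conversion."""

import itertools

import numpy as np
import pytest

from petmrcorr.grids_io import DynamicSeries, ImageGrid, ParametricMap, ROIMask
from petmrcorr.kinetics import (AIFFitError, AIFModel, ToftsFitConfig,
                                ToftsParams, enhancement_to_concentration,
                                fit_aif, fit_tofts_map, fit_tofts_regional,
                                fit_tofts_voxel, spgr_signal,
                                t1_from_dual_flip, tofts_forward)

TIMES = np.arange(90) * 2.9  # 2.9 s sampling over ~4.3 min
AIF = AIFModel(t0=29.0)


class TestToftsForward:
    def test_null_model_is_zero(self):
        ct = tofts_forward(ToftsParams(0.0, 0.0, 0.0), AIF, TIMES)
        assert np.allclose(ct, 0.0)

    def test_pure_plasma_term(self):
        ct = tofts_forward(ToftsParams(0.0, 0.0, 0.05), AIF, TIMES)
        assert np.allclose(ct, 0.05 * AIF(TIMES), atol=1e-12)

    def test_constant_aif_closed_form(self):
        # C_t(t) = c (v_p + v_e (1 - exp(-Ktrans t / v_e)))
        aif = AIFModel("constant", a1=1.0, t0=0.0)
        ct = tofts_forward(ToftsParams(0.25, 0.30, 0.05), aif, TIMES)
        at_3min = np.interp(180.0, TIMES, ct)
        assert at_3min == pytest.approx(0.32537, abs=1e-4)
        t_min = TIMES / 60.0
        exact = 1.0 * (0.05 + 0.30 * (1.0 - np.exp(-0.25 * t_min / 0.30)))
        rel = np.abs(ct[1:] - exact[1:]) / exact[1:]
        assert rel.max() < 1e-3

    def test_closed_form_across_parameter_grid(self):
        aif = AIFModel("constant", a1=2.0, t0=0.0)
        t_min = TIMES / 60.0
        worst = 0.0
        for kt, ve, vp in itertools.product(np.linspace(0.01, 0.6, 3),
                                            np.linspace(0.05, 0.6, 3),
                                            np.linspace(0.01, 0.1, 3)):
            ct = tofts_forward(ToftsParams(kt, ve, vp), aif, TIMES)
            exact = 2.0 * (vp + ve * (1.0 - np.exp(-kt * t_min / ve)))
            worst = max(worst, np.max(np.abs(ct[1:] - exact[1:]) / exact[1:]))
        assert worst < 1e-3

    def test_undefined_kep_rejected(self):
        with pytest.raises(ValueError, match="k_ep"):
            tofts_forward(ToftsParams(0.2, 0.0, 0.05), AIF, TIMES)

    def test_early_curve_monotone_in_ktrans(self):
        curves = [tofts_forward(ToftsParams(kt, 0.3, 0.02), AIF, TIMES)
                  for kt in (0.05, 0.15, 0.3, 0.6)]
        early = TIMES <= 120.0
        for lo, hi in zip(curves, curves[1:]):
            assert np.all(hi[early] >= lo[early] - 1e-12)


class TestFitAif:
    def test_noiseless_parameter_recovery(self):
        truth = AIFModel(a1=4.0, a2=0.8, m1=2.5, m2=0.05, r=18.0, t0=29.0)
        fit = fit_aif(truth(TIMES), TIMES)
        for attr in ("a1", "a2", "m1", "m2", "r", "t0"):
            t, f = getattr(truth, attr), getattr(fit, attr)
            assert abs(f - t) / abs(t) < 0.01, attr

    def test_all_zero_curve_is_no_bolus(self):
        with pytest.raises(AIFFitError, match="bolus"):
            fit_aif(np.zeros_like(TIMES), TIMES)

    def test_time_shift_equivariance(self):
        truth = AIFModel(t0=29.0)
        shifted = AIFModel(t0=34.0)
        f0 = fit_aif(truth(TIMES), TIMES)
        f5 = fit_aif(shifted(TIMES), TIMES)
        assert abs((f5.t0 - f0.t0) - 5.0) <= 2.9


class TestFitToftsVoxel:
    def test_noiseless_recovery_within_one_percent(self):
        truth = ToftsParams(0.25, 0.30, 0.05)
        curve = 10.0 * tofts_forward(truth, AIF, TIMES)
        fit = fit_tofts_voxel(curve, TIMES, AIF, scale=10.0)
        assert fit.converged
        assert abs(fit.ktrans - 0.25) / 0.25 < 0.01
        assert abs(fit.ve - 0.30) / 0.30 < 0.01
        assert abs(fit.vp - 0.05) / 0.05 < 0.01

    def test_all_zero_curve_returns_null_params(self):
        fit = fit_tofts_voxel(np.zeros_like(TIMES), TIMES, AIF)
        assert fit.ktrans <= 1e-6 and fit.vp <= 1e-6
        assert fit.converged

    def test_noise_robustness_monte_carlo(self):
        truth = ToftsParams(0.25, 0.30, 0.05)
        clean = tofts_forward(truth, AIF, TIMES)
        sigma = 0.05 * clean.max()
        rng = np.random.default_rng(77)
        errs = []
        for _ in range(100):
            noisy = clean + rng.normal(0, sigma, clean.shape)
            fit = fit_tofts_voxel(noisy, TIMES, AIF)
            errs.append(abs(fit.ktrans - truth.ktrans) / truth.ktrans)
        assert np.median(errs) < 0.10

    def test_invariants_enforced_on_params(self):
        with pytest.raises(ValueError):
            ToftsParams(-0.1, 0.3, 0.05)
        with pytest.raises(ValueError):
            ToftsParams(0.1, 0.7, 0.5)


def _phantom_series(grid, kt, ve, vp, baseline=10):
    """Forward DCE series from parameter arrays (no noise)."""
    from petmrcorr.phantom import simulate_dce_series
    maps = [ParametricMap(grid, np.asarray(a, dtype=float), u)
            for a, u in ((kt, "min^-1"), (ve, "fraction"), (vp, "fraction"))]
    return simulate_dce_series(*maps, AIF, time_step=2.9, duration=258.0,
                               baseline_frames=baseline, noise_sigma=0.0,
                               scale=10.0, baseline_signal=100.0)


class TestFitToftsMap:
    GRID = ImageGrid((4, 3, 2), (2.8, 2.8, 2.0))

    def _truth(self, rng):
        kt = rng.uniform(0.05, 0.5, self.GRID.shape)
        ve = rng.uniform(0.1, 0.5, self.GRID.shape)
        vp = rng.uniform(0.01, 0.08, self.GRID.shape)
        return kt, ve, vp

    def test_recovers_truth_maps(self, rng):
        kt, ve, vp = self._truth(rng)
        series = _phantom_series(self.GRID, kt, ve, vp)
        mask = ROIMask(self.GRID, np.ones(self.GRID.shape, bool), "GTV")
        kt_m, ve_m, vp_m, diag = fit_tofts_map(
            series, mask, AIF, ToftsFitConfig(scale=10.0))
        assert diag["nonconverged_fraction"] == 0.0
        assert np.max(np.abs(kt_m.values - kt) / kt) < 0.01
        assert np.max(np.abs(ve_m.values - ve) / ve) < 0.01

    def test_single_voxel_mask(self, rng):
        kt, ve, vp = self._truth(rng)
        series = _phantom_series(self.GRID, kt, ve, vp)
        m = np.zeros(self.GRID.shape, bool)
        m[1, 1, 1] = True
        kt_m, _, _, diag = fit_tofts_map(series, ROIMask(self.GRID, m, "GTV"), AIF)
        assert np.isfinite(kt_m.values).sum() == 1
        assert diag["n_fit"] == 1


class TestFitToftsRegional:
    GRID = ImageGrid((3, 3, 4), (2.8, 2.8, 2.0))

    def test_homogeneous_block_equals_voxel_fit(self):
        kt = np.full(self.GRID.shape, 0.2)
        ve = np.full(self.GRID.shape, 0.35)
        vp = np.full(self.GRID.shape, 0.04)
        series = _phantom_series(self.GRID, kt, ve, vp)
        block = np.argwhere(np.ones(self.GRID.shape, bool))
        (regional,) = fit_tofts_regional(series, [block], AIF)
        voxel = fit_tofts_voxel(
            series.frames[:, 0, 0, 0] - series.frames[:10, 0, 0, 0].mean(),
            series.frame_starts, AIF, scale=ToftsFitConfig().scale)
        assert regional.ktrans == pytest.approx(voxel.ktrans, rel=1e-6)
        assert regional.ve == pytest.approx(voxel.ve, rel=1e-6)

    def test_block_order_equivariance(self, rng):
        kt = rng.uniform(0.1, 0.4, self.GRID.shape)
        ve = rng.uniform(0.1, 0.5, self.GRID.shape)
        vp = rng.uniform(0.01, 0.08, self.GRID.shape)
        series = _phantom_series(self.GRID, kt, ve, vp)
        all_idx = np.argwhere(np.ones(self.GRID.shape, bool))
        blocks = [all_idx[:18], all_idx[18:]]
        fwd = fit_tofts_regional(series, blocks, AIF)
        rev = fit_tofts_regional(series, blocks[::-1], AIF)
        assert fwd[0].ktrans == pytest.approx(rev[1].ktrans, rel=1e-9)
        assert fwd[1].ktrans == pytest.approx(rev[0].ktrans, rel=1e-9)

    def test_empty_block_skipped_with_warning(self):
        kt = np.full(self.GRID.shape, 0.2)
        series = _phantom_series(self.GRID, kt, np.full(self.GRID.shape, 0.3),
                                 np.full(self.GRID.shape, 0.03))
        block = np.argwhere(np.ones(self.GRID.shape, bool))
        with pytest.warns(RuntimeWarning, match="empty block"):
            out = fit_tofts_regional(series, [np.empty((0, 3), int), block], AIF)
        assert out[0] is None and out[1] is not None

    def test_overlapping_blocks_rejected(self):
        kt = np.full(self.GRID.shape, 0.2)
        series = _phantom_series(self.GRID, kt, np.full(self.GRID.shape, 0.3),
                                 np.full(self.GRID.shape, 0.03))
        block = np.argwhere(np.ones(self.GRID.shape, bool))
        with pytest.raises(ValueError, match="overlap"):
            fit_tofts_regional(series, [block, block[:1]], AIF)


class TestT1Mapping:
    GRID = ImageGrid((10, 5, 1), (1, 1, 1))

    def _signals(self, t1_ms, m0=5000.0, flips=(2.0, 12.0), tr=4.04):
        s1 = ParametricMap(self.GRID, spgr_signal(m0, t1_ms, flips[0], tr), "au")
        s2 = ParametricMap(self.GRID, spgr_signal(m0, t1_ms, flips[1], tr), "au")
        return s1, s2

    def test_recovery_across_physiological_range(self):
        t1 = np.resize(np.linspace(200.0, 3000.0, 50), self.GRID.shape)
        s1, s2 = self._signals(t1)
        out = t1_from_dual_flip(s1, s2, (2.0, 12.0), 4.04)
        assert out.valid.all()
        assert np.max(np.abs(out.t1 - t1)) < 1e-6

    def test_acquisition_worked_example(self):
        t1 = np.full(self.GRID.shape, 1000.0)
        s1, s2 = self._signals(t1, m0=5000.0)
        out = t1_from_dual_flip(s1, s2, (2.0, 12.0), 4.04)
        assert np.allclose(out.t1, 1000.0, atol=0.1)
        assert np.allclose(out.m0, 5000.0, rtol=1e-6)

    def test_global_scaling_leaves_t1_scales_m0(self):
        t1 = np.full(self.GRID.shape, 800.0)
        s1, s2 = self._signals(t1)
        out1 = t1_from_dual_flip(s1, s2, (2.0, 12.0), 4.04)
        out3 = t1_from_dual_flip(s1.with_values(3 * s1.values),
                                 s2.with_values(3 * s2.values), (2.0, 12.0), 4.04)
        assert np.allclose(out3.t1, out1.t1, rtol=1e-9)
        assert np.allclose(out3.m0, 3 * out1.m0, rtol=1e-9)

    def test_nonphysical_branch_flagged(self):
        s1 = ParametricMap(self.GRID, np.full(self.GRID.shape, 10.0), "au")
        s2 = ParametricMap(self.GRID, np.full(self.GRID.shape, 300.0), "au")
        out = t1_from_dual_flip(s1, s2, (2.0, 12.0), 4.04)
        assert not out.valid.any()
        assert np.isnan(out.t1).all()


class TestEnhancementToConcentration:
    GRID = ImageGrid((4, 4, 2), (1, 1, 1))

    def _t1map(self, t1=1000.0, m0=4000.0):
        from petmrcorr.kinetics import T1Map
        return T1Map(self.GRID, np.full(self.GRID.shape, t1),
                     np.full(self.GRID.shape, m0),
                     np.ones(self.GRID.shape, bool))

    def _series_from_conc(self, conc_per_frame, t1map, relaxivity=4.5,
                          tr=2.86, flip=12.0):
        base = spgr_signal(t1map.m0, t1map.t1, flip, tr)
        frames = []
        for c in conc_per_frame:
            r1 = 1000.0 / t1map.t1 + relaxivity * c
            frames.append(spgr_signal(t1map.m0, 1000.0 / r1, flip, tr) - base)
        return DynamicSeries(self.GRID, np.stack(frames),
                             np.arange(len(frames)) * 2.9,
                             np.full(len(frames), 2.9), "signal-difference")

    def test_zero_enhancement_is_zero_concentration(self):
        t1map = self._t1map()
        enh = self._series_from_conc([0.0, 0.0, 0.0], t1map)
        out = enhancement_to_concentration(enh, t1map, 4.5, 2.86, 12.0)
        assert np.allclose(out.frames, 0.0, atol=1e-10)
        assert out.unit == "mM"

    def test_round_trip_recovers_concentration(self):
        t1map = self._t1map()
        conc = [0.0, 0.2, 1.0, 3.0, 0.8]
        enh = self._series_from_conc(conc, t1map)
        out = enhancement_to_concentration(enh, t1map, 4.5, 2.86, 12.0)
        for i, c in enumerate(conc):
            assert np.allclose(out.frames[i], c, atol=1e-6)

    def test_doubling_relaxivity_halves_concentration(self):
        t1map = self._t1map()
        enh = self._series_from_conc([0.0, 0.5], t1map, relaxivity=4.5)
        c1 = enhancement_to_concentration(enh, t1map, 4.5, 2.86, 12.0)
        c2 = enhancement_to_concentration(enh, t1map, 9.0, 2.86, 12.0)
        assert np.allclose(c2.frames[1], 0.5 * c1.frames[1], rtol=1e-9)
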