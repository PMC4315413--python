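import numpy as np
import pytest

import ivimfun as iv
from conftest import make_noisy_stack

GM = iv.IVIMParameters(f=0.04, D=0.7e-3, Dstar=17e-3)


def grid_search_sse(curve, D_fixed):
    """Brute-force SSE minimum over a dense (f, D*) grid — independent oracle."""
    b = curve.scheme.b_values
    f_grid = np.arange(0.0, 0.3001, 0.001)
    ds_grid = np.arange(1e-3, 60.0001e-3, 0.1e-3)
    fast = np.exp(-np.outer(ds_grid, b))
    tissue = np.exp(-b * D_fixed)
    model = f_grid[:, None, None] * fast[None] + (1 - f_grid)[:, None, None] * tissue
    return float(((model - curve.values) ** 2).sum(-1).min())


class TestFitDiffusion:
    def test_mono_exponential_round_trip_to_machine_precision(self, scheme):
        curve = iv.SignalCurve(scheme, 0.96 * np.exp(-scheme.b_values * 0.7e-3))
        D, amp = iv.fit_diffusion(curve)
        assert D == pytest.approx(0.7e-3, rel=1e-12)
        assert amp == pytest.approx(0.96, rel=1e-12)

    def test_full_ivim_curve_gives_D_within_one_percent(self, scheme):
        # the residual vascular signal above b=200 biases D by well under 1%
        D, _ = iv.fit_diffusion(iv.predict_curve(GM, scheme))
        assert D == pytest.approx(0.7e-3, rel=0.01)

    def test_requires_points_above_threshold(self):
        sch = iv.AcquisitionScheme(np.array([0.0, 50.0, 100.0, 200.0]))
        curve = iv.SignalCurve(sch, np.exp(-sch.b_values * 1e-3))
        with pytest.raises(ValueError):
            iv.fit_diffusion(curve)


class TestFitPerfusion:
    def test_noiseless_round_trip_with_true_D(self, scheme):
        res = iv.fit_perfusion(iv.predict_curve(GM, scheme), D_fixed=GM.D)
        assert res.params.f == pytest.approx(GM.f, rel=1e-6)
        assert res.params.Dstar == pytest.approx(GM.Dstar, rel=1e-6)
        assert res.params.D == GM.D
        assert res.converged and res.valid

    def test_zero_perfusion_curve_fits_f_near_zero(self, scheme):
        mono = iv.IVIMParameters(f=0.0, D=0.7e-3, Dstar=17e-3)
        res = iv.fit_perfusion(iv.predict_curve(mono, scheme), D_fixed=0.7e-3)
        assert res.params.f <= 1e-4

    def test_matches_grid_search_oracle_on_noisy_curves(self, scheme):
        rng = np.random.default_rng(42)
        noise = iv.NoiseModel.constant_snr(100, scheme)
        for _ in range(10):
            curve = iv.simulate_noisy_curve(GM, scheme, noise, rng)
            D, amp = iv.fit_diffusion(curve)
            res = iv.fit_perfusion(curve, D, amp)
            assert res.residual_ss <= grid_search_sse(curve, D) + 1e-9

    def test_weak_identifiability_flagged(self, scheme):
        near = iv.IVIMParameters(f=0.1, D=0.7e-3, Dstar=1.2e-3)
        res = iv.fit_perfusion(iv.predict_curve(near, scheme), D_fixed=0.7e-3)
        assert res.weakly_identified


class TestFitIvim:
    def test_noiseless_round_trip_in_separable_regime(self, scheme):
        # with D* large enough that the vascular term is fully attenuated
        # beyond the stage-1 threshold, the two-step fit is exact
        for f in (0.02, 0.1, 0.25):
            truth = iv.IVIMParameters(f=f, D=0.8e-3, Dstar=45e-3)
            res = iv.fit_ivim(iv.predict_curve(truth, scheme))
            for got, want in [(res.params.f, truth.f), (res.params.D, truth.D),
                              (res.params.Dstar, truth.Dstar)]:
                assert got == pytest.approx(want, rel=1e-4)

    def test_intrinsic_bias_at_gm_baseline_below_one_percent(self, scheme):
        # at smaller D* the segmented fit carries a deterministic truncation
        # bias ~ exp(-300*(D*-D)); at the gray-matter truth it stays < 1%
        res = iv.fit_ivim(iv.predict_curve(GM, scheme))
        assert res.params.f == pytest.approx(GM.f, rel=0.01)
        assert res.params.D == pytest.approx(GM.D, rel=0.01)
        assert res.params.Dstar == pytest.approx(GM.Dstar, rel=0.01)

    def test_flat_curve_flagged_non_physical(self, scheme):
        res = iv.fit_ivim(iv.SignalCurve(scheme, np.ones(scheme.n_b)))
        assert not res.valid
        assert res.params.D <= 1e-10

    def test_high_convergence_rate_at_snr_100(self, scheme):
        rng = np.random.default_rng(5)
        noise = iv.NoiseModel.constant_snr(100, scheme)
        converged = sum(
            iv.fit_ivim(iv.simulate_noisy_curve(GM, scheme, noise, rng)).converged
            for _ in range(1000)
        )
        assert converged >= 950


class TestFitMaps:
    def test_uniform_noiseless_phantom_recovers_everywhere(self, scheme):
        clean = iv.ivim_signal(GM, scheme.b_values)
        stack = np.tile(clean, (4, 4, 1))
        maps = iv.fit_maps(stack, scheme)
        assert maps.valid.all()
        assert np.allclose(maps.f, GM.f, rtol=0.01)
        assert np.allclose(maps.Dstar, GM.Dstar, rtol=0.01)

    def test_masked_out_voxels_are_nan(self, scheme):
        clean = iv.ivim_signal(GM, scheme.b_values)
        stack = np.tile(clean, (3, 3, 1))
        mask = np.zeros((3, 3), dtype=bool)
        mask[1, 1] = True
        maps = iv.fit_maps(stack, scheme, mask)
        assert maps.valid[1, 1]
        assert np.isnan(maps.f[0, 0]) and not maps.valid[0, 0]

    def test_scale_invariance_of_fitted_maps(self, scheme):
        rng = np.random.default_rng(3)
        stack = make_noisy_stack(GM, scheme, (3, 3), 0.005, rng)
        a = iv.fit_maps(stack, scheme)
        b = iv.fit_maps(stack * 1000.0, scheme)
        assert np.allclose(a.f, b.f, equal_nan=True)
        assert np.allclose(a.Dstar, b.Dstar, equal_nan=True)

    def test_two_region_phantom_separates_baseline_from_stimulation(self, scheme):
        stim = iv.IVIMParameters(f=0.0534, D=0.711e-3, Dstar=30.5e-3)
        rng = np.random.default_rng(9)
        base_stack = make_noisy_stack(GM, scheme, (4, 4), 0.01, rng)
        stim_stack = make_noisy_stack(stim, scheme, (4, 4), 0.01, rng)
        mb = iv.fit_maps(base_stack, scheme)
        ms = iv.fit_maps(stim_stack, scheme)
        base_mean = np.nanmean(mb.fDstar)
        stim_mean = np.nanmean(ms.fDstar)
        base_se = np.nanstd(mb.fDstar) / np.sqrt(mb.valid.sum())
        stim_se = np.nanstd(ms.fDstar) / np.sqrt(ms.valid.sum())
        assert stim_mean - base_mean > 2 * (base_se + stim_se)


class TestFitRoi:
    def test_uniform_roi_equals_single_voxel_fit(self, scheme):
        clean = iv.ivim_signal(GM, scheme.b_values)
        stack = np.tile(clean, (5, 5, 1))
        roi = np.ones((5, 5), dtype=bool)
        res_roi = iv.fit_roi(stack, scheme, roi)
        res_vox = iv.fit_ivim(iv.SignalCurve(scheme, clean))
        assert res_roi.params.f == pytest.approx(res_vox.params.f, rel=1e-9)
        assert res_roi.params.Dstar == pytest.approx(res_vox.params.Dstar, rel=1e-9)

    def test_empty_roi_rejected(self, scheme):
        stack = np.tile(iv.ivim_signal(GM, scheme.b_values), (3, 3, 1))
        with pytest.raises(ValueError):
            iv.fit_roi(stack, scheme, np.zeros((3, 3), dtype=bool))

    def test_roi_averaging_shrinks_fit_scatter(self, scheme):
        # 16-voxel ROI-averaged fits should scatter ~4x less than voxel fits
        rng = np.random.default_rng(17)
        roi_f, vox_f = [], []
        roi = np.ones((4, 4), dtype=bool)
        for _ in range(40):
            stack = make_noisy_stack(GM, scheme, (4, 4), 0.01, rng)
            roi_f.append(iv.fit_roi(stack, scheme, roi).params.f)
            curve = iv.SignalCurve(scheme, np.clip(stack[0, 0] / stack[0, 0, 0], 1e-6, None))
            vox_f.append(iv.fit_ivim(curve).params.f)
        assert np.std(roi_f) < 0.5 * np.std(vox_f)

    def test_mixed_roi_fits_between_tissue_truths(self, scheme):
        wm = iv.IVIMParameters(f=0.0417, D=0.723e-3, Dstar=9.58e-3)
        gm_clean = iv.ivim_signal(GM, scheme.b_values)
        wm_clean = iv.ivim_signal(wm, scheme.b_values)
        stack = np.empty((2, 4, scheme.n_b))
        stack[0] = gm_clean
        stack[1] = wm_clean
        res = iv.fit_roi(stack, scheme, np.ones((2, 4), dtype=bool))
        assert min(GM.Dstar, wm.Dstar) < res.params.Dstar < max(GM.Dstar, wm.Dstar)
        assert min(GM.D, wm.D) < res.params.D < max(GM.D, wm.D)
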