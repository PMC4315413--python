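import numpy as np
import pandas as pd
import pytest

import ivimfun as iv
from ivimfun.fitting import ParameterMaps


def const_maps(value, shape=(4, 4), valid=None):
    valid = np.ones(shape, dtype=bool) if valid is None else valid
    grids = {}
    for name in ("f", "D", "Dstar", "fDstar"):
        g = np.full(shape, float(value))
        g[~valid] = np.nan
        grids[name] = g
    return ParameterMaps(valid=valid, **grids)


class TestBuildRoiSet:
    def test_recovers_phantom_ground_truth_masks(self, tiny_study):
        rois = iv.build_roi_set(
            tiny_study.t_map, 5.0, tiny_study.gm_prob, tiny_study.wm_prob
        )
        for name in ("visual_gm", "visual_wm", "nonvisual_gm", "nonvisual_wm"):
            assert np.array_equal(rois[name], tiny_study.tissue_mask(name))

    def test_threshold_above_max_t_gives_named_error(self, tiny_study):
        with pytest.raises(ValueError, match="visual"):
            iv.build_roi_set(
                tiny_study.t_map, tiny_study.t_map.max() + 1,
                tiny_study.gm_prob, tiny_study.wm_prob,
            )

    def test_sub_floor_probability_voxels_dropped(self):
        t = np.zeros((2, 4))
        t[0, :] = 10.0  # top row activated
        gm = np.array([[0.9, 0.2, 0.9, 0.2], [0.9, 0.2, 0.4, 0.1]])
        wm = np.array([[0.1, 0.8, 0.1, 0.8], [0.1, 0.8, 0.4, 0.1]])
        rois = iv.build_roi_set(t, 5.0, gm, wm, prob_floor=0.5)
        assigned = np.zeros((2, 4), dtype=bool)
        for name in rois.masks:
            assigned |= rois[name]
        # ambiguous 0.4/0.4 voxel and sub-floor 0.1/0.1 voxel assigned to neither
        assert not assigned[1, 2] and not assigned[1, 3]
        assert assigned[0].all() and assigned[1, 0] and assigned[1, 1]

    def test_exclusion_mask_removed_everywhere(self, tiny_study):
        excl = np.zeros_like(tiny_study.t_map, dtype=bool)
        gm_mask = tiny_study.tissue_mask("visual_gm")
        iy, ix = np.argwhere(gm_mask)[0]
        excl[iy, ix] = True
        rois = iv.build_roi_set(
            tiny_study.t_map, 5.0, tiny_study.gm_prob, tiny_study.wm_prob,
            exclusion_mask=excl,
        )
        assert not rois["visual_gm"][iy, ix]


class TestMapAlgebra:
    def test_single_map_average_is_identity(self):
        m = const_maps(1.5)
        out = iv.average_maps([m])
        assert np.array_equal(out.f, m.f)

    def test_mean_of_constant_maps(self):
        out = iv.average_maps([const_maps(1.0), const_maps(3.0)])
        assert np.allclose(out.fDstar, 2.0)

    def test_disjoint_validity_gives_union_coverage(self):
        v1 = np.zeros((4, 4), dtype=bool)
        v1[:2] = True
        v2 = ~v1
        out = iv.average_maps([const_maps(1.0, valid=v1), const_maps(3.0, valid=v2)])
        assert out.valid.all()
        assert np.allclose(out.f[:2], 1.0) and np.allclose(out.f[2:], 3.0)

    def test_subtraction_of_identical_maps_is_zero(self):
        m = const_maps(0.8)
        diff = iv.subtraction_map(m, m)
        assert np.allclose(diff.fDstar, 0.0)

    def test_subtraction_matches_group_effect_arithmetic(self):
        diff = iv.subtraction_map(const_maps(1.61e-3), const_maps(0.59e-3))
        assert np.allclose(diff.fDstar, 1.02e-3)

    def test_invalid_voxel_in_either_input_propagates(self):
        v = np.ones((4, 4), dtype=bool)
        v[0, 0] = False
        diff = iv.subtraction_map(const_maps(2.0, valid=v), const_maps(1.0))
        assert not diff.valid[0, 0] and np.isnan(diff.f[0, 0])

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            iv.subtraction_map(const_maps(1.0, shape=(3, 3)), const_maps(1.0))


class TestPercentVariation:
    @pytest.mark.parametrize(
        "base,stim,expected",
        [(0.59, 1.61, 172.881), (17.27, 30.50, 76.607), (2.0, 2.0, 0.0)],
    )
    def test_worked_examples(self, base, stim, expected):
        assert iv.percent_variation(base, stim) == pytest.approx(expected, abs=1e-3)

    def test_invariant_to_common_rescaling(self):
        assert iv.percent_variation(0.59, 1.61) == pytest.approx(
            iv.percent_variation(5.9, 16.1)
        )

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(ValueError):
            iv.percent_variation(0.0, 1.0)


class TestPairedT:
    def test_closed_form_example(self):
        # differences (1,2,3): t = 2*sqrt(3) with 2 df, one-tailed
        p = iv.paired_one_tailed_t([0, 0, 0], [1, 2, 3], "increase")
        assert p == pytest.approx(0.03709, abs=5e-5)

    def test_all_zero_differences_give_half(self):
        assert iv.paired_one_tailed_t([1.0, 2.0], [1.0, 2.0]) == 0.5

    def test_direction_reversal_complements_p(self):
        base, stim = [0.1, 0.5, 0.2, 0.9], [0.3, 0.4, 0.6, 1.0]
        p_inc = iv.paired_one_tailed_t(base, stim, "increase")
        p_dec = iv.paired_one_tailed_t(base, stim, "decrease")
        assert p_inc + p_dec == pytest.approx(1.0)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            iv.paired_one_tailed_t([1.0], [2.0])
        with pytest.raises(ValueError):
            iv.paired_one_tailed_t([0.0, 0.0], [1.0, 1.0])  # nonzero constant diff


def _per_subject_table(n_subjects=6, effect=2.0, rng=None):
    rng = rng or np.random.default_rng(0)
    rows = []
    for s in range(n_subjects):
        for roi in ("visual_gm", "visual_wm", "nonvisual_gm", "nonvisual_wm"):
            base_f = 0.04 + 0.002 * rng.standard_normal()
            base_ds = 15e-3 + 1e-3 * rng.standard_normal()
            for cond, scale in (("baseline", 1.0), ("stimulation", effect if "visual" in roi and "non" not in roi else 1.0)):
                f = base_f * scale
                ds = base_ds * scale
                rows.append(dict(subject=s, condition=cond, roi=roi,
                                 f=f, D=0.7e-3, Dstar=ds, fDstar=f * ds))
    return pd.DataFrame(rows)


class TestSummarizeGroup:
    def test_group_table_layout_and_effect_direction(self):
        res = iv.summarize_group(_per_subject_table())
        assert len(res.summary) == 16  # 4 ROIs x 4 parameters
        gm_fd = res.summary[
            (res.summary.roi == "visual_gm") & (res.summary.parameter == "fDstar")
        ].iloc[0]
        assert gm_fd.variation_pct > 100
        assert gm_fd.p_value < 0.05
        assert set(res.perfusion_summary.parameter) == {"CBF", "CBV"}

    def test_display_units_are_percent_and_milli(self):
        res = iv.summarize_group(_per_subject_table())
        f_row = res.summary[
            (res.summary.roi == "visual_wm") & (res.summary.parameter == "f")
        ].iloc[0]
        assert 1.0 < f_row.baseline_mean < 10.0  # percent, not fraction

    def test_single_subject_rejected(self):
        table = _per_subject_table(n_subjects=1)
        with pytest.raises(ValueError):
            iv.summarize_group(table)

    def test_missing_condition_rejected(self):
        table = _per_subject_table()
        table = table[~((table.subject == 2) & (table.condition == "baseline")
                        & (table.roi == "visual_gm"))]
        with pytest.raises(ValueError, match="baseline"):
            iv.summarize_group(table)

    def test_tissue_contrast_reported_per_condition(self):
        res = iv.summarize_group(_per_subject_table())
        assert len(res.tissue_contrast) == 16  # 2 regions x 4 params x 2 conditions
        assert ((res.tissue_contrast.p_value > 0) & (res.tissue_contrast.p_value < 1)).all()
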