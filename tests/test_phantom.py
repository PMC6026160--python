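"""Phantom construction and forward rendering of the paired exposures."""

import numpy as np
import pytest

from duohct.config import (
    BloodPanelConfig,
    HeterogeneityConfig,
    PhantomConfig,
    RegionSpec,
)
from duohct.isotopes import DEFAULT_EXP1, DEFAULT_EXP2, I125, TC99M, window_ratio
from duohct.phantom import (
    apply_rigid_offset,
    expected_psl,
    make_blood_panel,
    make_layout,
    make_phantom,
    render_exposures,
    PSLImage,
)
from duohct.pipeline import simulate_scene

from conftest import small_config


def one_region_config(vv=3.0, thct=0.29, heterogeneity=False):
    return PhantomConfig(
        shape_rc=(60, 60),
        regions=[RegionSpec(name="tissue", label=1, shape="disk",
                            center_rc=(30.0, 30.0), radius_px=15.0,
                            vv_pct=vv, thct_frac=thct)],
        heterogeneity=HeterogeneityConfig() if heterogeneity
        else HeterogeneityConfig(vv_rel_sd=0.0, thct_abs_sd=0.0),
    )


class TestMakePhantom:
    def test_single_region_truth_arithmetic(self):
        truth = make_phantom(one_region_config(vv=3.0, thct=0.29), seed=0)
        m = truth.labels == 1
        assert np.allclose(truth.vrbc_pct[m], 0.87)
        assert np.allclose(truth.vp_pct[m], 2.13)
        assert np.allclose(truth.vv_pct[m], 3.0)

    def test_empty_region_list_gives_blank_phantom(self):
        truth = make_phantom(PhantomConfig(shape_rc=(20, 20), regions=[]), seed=0)
        assert not truth.labels.any()
        assert not truth.vv_pct.any() and not truth.thct_frac.any()

    def test_truth_identity_vrbc_plus_vp_equals_vv(self):
        truth = make_phantom(small_config(seed=3).phantom, seed=3)
        assert np.array_equal(truth.vrbc_pct + truth.vp_pct, truth.vv_pct)

    def test_control_brain_regional_ordering(self):
        # cortex > striatum > white matter in tissue hematocrit
        truth = make_phantom(small_config(seed=5).phantom, seed=5)
        means = {lab: truth.thct_frac[truth.labels == lab].mean() for lab in (1, 2, 3)}
        assert means[1] > means[3] > means[2]
        assert means[1] == pytest.approx(0.296, abs=0.004)
        assert means[3] == pytest.approx(0.288, abs=0.004)
        assert means[2] == pytest.approx(0.280, abs=0.004)

    def test_deterministic_given_seed(self):
        cfg = small_config(seed=9).phantom
        a = make_phantom(cfg, seed=11)
        b = make_phantom(cfg, seed=11)
        assert np.array_equal(a.vv_pct, b.vv_pct)
        assert np.array_equal(a.thct_frac, b.thct_frac)

    def test_overlapping_base_regions_rejected(self):
        cfg = one_region_config()
        cfg.regions.append(RegionSpec(
            name="clash", label=2, shape="disk", center_rc=(32.0, 30.0),
            radius_px=10.0, vv_pct=1.0, thct_frac=0.3))
        with pytest.raises(ValueError, match="overlap"):
            make_phantom(cfg, seed=0)

    def test_vessel_overlay_inherits_local_hematocrit(self):
        cfg = one_region_config(vv=3.0, thct=0.29)
        cfg.regions.append(RegionSpec(
            name="vessel", label=21, shape="disk", center_rc=(30.0, 30.0),
            radius_px=2.0, vv_pct=30.0, thct_frac=None, overlay=True))
        truth = make_phantom(cfg, seed=0)
        vessel = truth.labels == 21
        assert np.allclose(truth.vv_pct[vessel], 30.0)
        assert np.allclose(truth.thct_frac[vessel], 0.29)


class TestBloodPanel:
    def test_fraction_concentrations_from_whole_blood(self):
        panel = make_blood_panel(BloodPanelConfig(
            c_tc_blood_mbq_g=0.8, c_i_blood_mbq_g=0.06, bhct_capillary=0.40))
        assert panel.c_tc_rbc == pytest.approx(2.0)
        assert panel.c_i_plasma == pytest.approx(0.1)

    def test_symmetric_split_at_half_hematocrit(self):
        panel = make_blood_panel(BloodPanelConfig(
            c_tc_blood_mbq_g=1.0, c_i_blood_mbq_g=1.0, bhct_capillary=0.5))
        assert panel.c_tc_rbc == panel.c_i_plasma == pytest.approx(2.0)

    def test_dose_scales_concentrations_linearly(self):
        base = BloodPanelConfig()
        doubled = BloodPanelConfig(
            c_tc_blood_mbq_g=2 * base.c_tc_blood_mbq_g,
            c_i_blood_mbq_g=2 * base.c_i_blood_mbq_g)
        a, b = make_blood_panel(base), make_blood_panel(doubled)
        assert b.c_tc_rbc == pytest.approx(2 * a.c_tc_rbc)
        assert b.c_i_plasma == pytest.approx(2 * a.c_i_plasma)

    def test_explicit_fraction_concentrations_win(self):
        panel = make_blood_panel(BloodPanelConfig(
            c_tc_blood_mbq_g=0.8, c_i_blood_mbq_g=0.06, bhct_capillary=0.40,
            c_tc_rbc_mbq_g=1.9, c_i_plasma_mbq_g=0.11))
        assert panel.c_tc_rbc == 1.9 and panel.c_i_plasma == 0.11

    def test_bhct_bounds_enforced(self):
        with pytest.raises(ValueError):
            BloodPanelConfig(bhct_capillary=1.0)


class TestRenderExposures:
    def test_zero_scene_is_pure_background_offset(self):
        cfg = small_config(seed=0, noise=False)
        cfg.phantom.regions = []
        cfg.panel.c_tc_blood_mbq_g = 0.0
        cfg.panel.c_i_blood_mbq_g = 0.0
        cfg.layout.pure_i_conc_mbq_g = 1e-12
        scene = simulate_scene(cfg)
        offset = cfg.noise.background_offset_psl
        assert np.allclose(scene.exp1.values[~scene.layout.pure_i_mask], offset)
        assert np.allclose(scene.exp2.values[~scene.layout.pure_i_mask], offset)

    def test_linearity_in_panel_concentrations(self, noiseless_scene):
        s = noiseless_scene
        base = expected_psl(s.truth, s.panel, s.layout, DEFAULT_EXP1)
        from dataclasses import replace
        doubled = replace(s.panel, c_tc_blood=2 * s.panel.c_tc_blood,
                          c_i_blood=2 * s.panel.c_i_blood,
                          c_tc_rbc=2 * s.panel.c_tc_rbc,
                          c_i_plasma=2 * s.panel.c_i_plasma)
        got = expected_psl(s.truth, doubled, s.layout, DEFAULT_EXP1)
        # everywhere except the pure-I-125 drop, whose stock concentration
        # is a layout property, not a blood-panel one
        outside = ~s.layout.pure_i_mask
        assert np.allclose(got[outside], 2 * base[outside], rtol=1e-12)

    def test_tc_contribution_to_exp2_negligible(self, noiseless_scene):
        s = noiseless_scene
        tc1 = expected_psl(s.truth, s.panel, s.layout, DEFAULT_EXP1, isotope=TC99M)
        tc2 = expected_psl(s.truth, s.panel, s.layout, DEFAULT_EXP2, isotope=TC99M)
        signal = tc1 > 0
        assert (tc2[signal] / tc1[signal]).max() < 1e-6

    def test_pure_spot_ratio_equals_window_ratio(self, noiseless_scene):
        s = noiseless_scene
        offset = s.config.noise.background_offset_psl
        e1 = s.exp1.values - offset
        e2 = s.exp2.values - offset
        ratio = e2[s.layout.pure_i_mask] / e1[s.layout.pure_i_mask]
        want = window_ratio(I125, DEFAULT_EXP1, DEFAULT_EXP2)
        assert np.allclose(ratio, want, rtol=1e-9)

    def test_noise_deterministic_given_seed(self):
        cfg = small_config(seed=4, noise=True)
        a = simulate_scene(cfg)
        b = simulate_scene(cfg)
        assert np.array_equal(a.exp1.values, b.exp1.values)
        assert np.array_equal(a.exp2.values, b.exp2.values)

    def test_layout_overlap_rejected(self):
        cfg = small_config(seed=0)
        cfg.layout.blood_spot.center_rc = (50.0, 45.0)  # on the tissue
        truth = make_phantom(cfg.phantom, seed=0)
        with pytest.raises(ValueError, match="overlap"):
            make_layout(cfg.layout, truth)


class TestApplyRigidOffset:
    def test_zero_transform_is_bit_identical(self, noiseless_scene):
        img = noiseless_scene.exp1
        moved = apply_rigid_offset(img, 0.0, 0.0, 0.0)
        assert np.array_equal(moved.values, img.values)

    def test_integer_translation_is_exact(self, noiseless_scene):
        img = noiseless_scene.exp1
        moved = apply_rigid_offset(img, 3.0, -2.0, 0.0)
        # content moves +3 columns, -2 rows: moved[r, c] == img[r + 2, c - 3]
        assert np.array_equal(moved.values[:98, 3:], img.values[2:, :137])

    def test_round_trip_recovers_smooth_image(self, rng):
        from scipy.ndimage import gaussian_filter

        smooth = gaussian_filter(rng.standard_normal((100, 140)), 5.0)
        smooth -= smooth.min()
        img = PSLImage(smooth, DEFAULT_EXP1)
        fwd = apply_rigid_offset(img, 3.2, -1.7, 0.5)
        back = apply_rigid_offset(fwd, -3.2, 1.7, -0.5)
        interior = np.zeros_like(smooth, dtype=bool)
        interior[8:-8, 8:-8] = True
        err = np.abs(back.values - smooth)[interior].max()
        assert err < 0.01 * np.ptp(smooth)

    def test_offset_bounds_enforced(self, noiseless_scene):
        with pytest.raises(ValueError):
            apply_rigid_offset(noiseless_scene.exp1, 25.0, 0.0, 0.0)
        with pytest.raises(ValueError):
            apply_rigid_offset(noiseless_scene.exp1, 0.0, 0.0, 6.0)
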