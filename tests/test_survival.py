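"""Forward survival model: proportional thinning and the survival grid."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rodcone import (
    EtdrsGrid,
    InvalidArgumentError,
    SurvivalParams,
    proportional_thickness,
    simulate_thickness,
    survival_grid,
)
from rodcone.etdrs import regional_mean

from conftest import make_reference

unit = st.floats(0.0, 1.0)


class TestProportionalThickness:
    def test_full_survival_is_one(self):
        for p in (0.0, 0.3, 1.0):
            assert proportional_thickness(p, SurvivalParams(1.0, 1.0)) == 1.0

    def test_pure_cone_location_reduces_to_s_cones(self):
        assert proportional_thickness(0.0, SurvivalParams(0.4, 0.9)) == pytest.approx(0.4)

    def test_hand_evaluation(self):
        # 0.2·0.5 + 0.8·0.25 = 0.3
        assert proportional_thickness(0.8, SurvivalParams(0.5, 0.25)) == pytest.approx(0.3)

    @given(p=unit, sc=unit, sr=unit)
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_bounded_by_survival_pair(self, p, sc, sr):
        v = proportional_thickness(p, SurvivalParams(sc, sr))
        assert min(sc, sr) - 1e-12 <= v <= max(sc, sr) + 1e-12

    def test_out_of_range_composition_rejected(self):
        with pytest.raises(InvalidArgumentError):
            proportional_thickness(1.2, SurvivalParams(1.0, 1.0))

    def test_out_of_range_survival_rejected(self):
        with pytest.raises(InvalidArgumentError):
            SurvivalParams(1.3, 0.5)
        with pytest.raises(InvalidArgumentError):
            SurvivalParams(0.5, -0.1)


class TestSimulateThickness:
    def test_full_survival_reproduces_normal_bitwise(self, ref_iso):
        t = simulate_thickness(ref_iso, SurvivalParams(1.0, 1.0))
        ok = ~ref_iso.missing_mask
        assert np.array_equal(t.values[ok], ref_iso.normal_thickness[ok])
        assert t.kind == "simulated"
        assert t.metadata["s_cones"] == 1.0

    def test_total_loss_gives_zero_map(self, ref_iso):
        t = simulate_thickness(ref_iso, SurvivalParams(0.0, 0.0))
        ok = ~ref_iso.missing_mask
        assert (t.values[ok] == 0).all()

    def test_cone_loss_thins_center_more_rod_loss_thins_ring_more(self, ref_iso, iso_masks):
        normal_c = regional_mean(ref_iso.normal_thickness, iso_masks.center & ~ref_iso.missing_mask)
        normal_o = regional_mean(ref_iso.normal_thickness, iso_masks.outer_ring & ~ref_iso.missing_mask)
        cones_only = simulate_thickness(ref_iso, SurvivalParams(0.0, 1.0))
        rods_only = simulate_thickness(ref_iso, SurvivalParams(1.0, 0.0))
        c_loss_center = 1 - regional_mean(cones_only, iso_masks.center) / normal_c
        c_loss_outer = 1 - regional_mean(cones_only, iso_masks.outer_ring) / normal_o
        r_loss_center = 1 - regional_mean(rods_only, iso_masks.center) / normal_c
        r_loss_outer = 1 - regional_mean(rods_only, iso_masks.outer_ring) / normal_o
        assert c_loss_center > c_loss_outer
        assert r_loss_outer > r_loss_center

    def test_missing_composition_propagates(self, cfg_iso):
        p = np.full((65, 65), 0.5)
        p[0, 0] = np.nan
        ref = make_reference(cfg_iso.geometry, np.full((65, 65), 100.0), p)
        t = simulate_thickness(ref, SurvivalParams(0.5, 0.5))
        assert np.isnan(t.values[0, 0])
        assert t.values[1, 1] == pytest.approx(50.0)

    @given(sc=unit, sr=unit, lam=unit)
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_affine_in_survival(self, ref_iso, sc, sr, lam):
        """T(λ·s1 + (1-λ)·s2) = λ·T(s1) + (1-λ)·T(s2) at every pixel."""
        s1 = SurvivalParams(sc, sr)
        s2 = SurvivalParams(1.0 - sc, sr * 0.5)
        mid = SurvivalParams(
            lam * s1.s_cones + (1 - lam) * s2.s_cones,
            lam * s1.s_rods + (1 - lam) * s2.s_rods,
        )
        t1 = simulate_thickness(ref_iso, s1).values
        t2 = simulate_thickness(ref_iso, s2).values
        tm = simulate_thickness(ref_iso, mid).values
        ok = ~ref_iso.missing_mask
        np.testing.assert_allclose(tm[ok], lam * t1[ok] + (1 - lam) * t2[ok], atol=1e-9)

    @given(sc=unit, sr=unit)
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_bounded_by_normal(self, ref_iso, sc, sr):
        t = simulate_thickness(ref_iso, SurvivalParams(sc, sr)).values
        ok = ~ref_iso.missing_mask
        assert (t[ok] >= -1e-12).all()
        assert (t[ok] <= ref_iso.normal_thickness[ok] + 1e-9).all()


class TestSurvivalGrid:
    def test_shape_corners_and_monotonicity(self, ref_iso, iso_masks):
        sg = survival_grid(ref_iso, iso_masks, step=0.25)
        assert sg.center_mean.shape == (5, 5)
        assert sg.center_mean[0, 0] == 0.0 and sg.outer_mean[0, 0] == 0.0
        normal_c = regional_mean(ref_iso.normal_thickness, iso_masks.center & ~ref_iso.missing_mask)
        assert sg.center_mean[-1, -1] == pytest.approx(normal_c, abs=1e-9)
        # non-decreasing along both survival axes; strictly along s_cones
        assert (np.diff(sg.center_mean, axis=0) > 0).all()
        assert (np.diff(sg.center_mean, axis=1) >= 0).all()
        assert (np.diff(sg.outer_mean, axis=0) >= 0).all()
        assert (np.diff(sg.outer_mean, axis=1) > 0).all()

    def test_pure_compositions_give_axis_aligned_rectangle(self, cfg_iso, iso_masks):
        p = np.where(iso_masks.outer_ring, 1.0, 0.0)  # cones in center, rods outside
        ref = make_reference(cfg_iso.geometry, np.full((65, 65), 100.0), p)
        sg = survival_grid(ref, iso_masks, step=0.5)
        # center mean depends only on s_cones; outer mean only on s_rods
        assert np.ptp(sg.center_mean, axis=1) == pytest.approx(0.0, abs=1e-12)
        assert np.ptp(sg.outer_mean, axis=0) == pytest.approx(0.0, abs=1e-12)

    def test_mixed_compositions_give_skewed_parallelogram(self, ref_iso, iso_masks):
        sg = survival_grid(ref_iso, iso_masks, step=0.5)
        # edge vectors of the mapped square: (0,0)->(1,0) and (0,0)->(0,1)
        u = np.array([sg.center_mean[-1, 0], sg.outer_mean[-1, 0]])
        v = np.array([sg.center_mean[0, -1], sg.outer_mean[0, -1]])
        # both regions are mixtures, so neither edge is axis-aligned
        assert u[0] > 0 and u[1] > 0 and v[0] > 0 and v[1] > 0
        # and the far corner is the vector sum (parallelogram closure)
        far = np.array([sg.center_mean[-1, -1], sg.outer_mean[-1, -1]])
        np.testing.assert_allclose(far, u + v, atol=1e-9)

    def test_grid_frame_round_trip(self, ref_iso, iso_masks):
        from rodcone.survival import SurvivalGrid

        sg = survival_grid(ref_iso, iso_masks, step=0.5)
        back = SurvivalGrid.from_frame(sg.to_frame())
        np.testing.assert_allclose(back.center_mean, sg.center_mean)
        np.testing.assert_allclose(back.outer_mean, sg.outer_mean)

    def test_bad_step_rejected(self, ref_iso, iso_masks):
        with pytest.raises(InvalidArgumentError):
            survival_grid(ref_iso, iso_masks, step=0.0)
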