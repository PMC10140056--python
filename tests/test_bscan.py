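"""Voxel-level A-scan editing and volume simulation."""

import numpy as np
import pytest
from scipy import stats

from rodcone import (
    InvalidArgumentError,
    NoCompensationLayerError,
    SegmentedVolume,
    SurvivalParams,
    resize_segmented_ascan,
    simulate_volume,
)
from rodcone.bscan import column_rng, round_half_away


def _column(vit=20, inner=10, onl=10, outer=8, tail=12, seed=0):
    rng = np.random.default_rng(seed)
    col = np.concatenate([
        rng.normal(10, 1, vit), rng.normal(120, 1, inner),
        rng.normal(60, 1, onl), rng.normal(150, 1, outer),
        rng.normal(90, 1, tail),
    ])
    bounds = np.array([vit, vit + inner, vit + inner + onl, vit + inner + onl + outer])
    return col, bounds


class TestRoundHalfAway:
    def test_ties_away_from_zero(self):
        np.testing.assert_array_equal(
            round_half_away([0.5, 1.5, 2.4, 2.6, -0.5]), [1, 2, 2, 3, -1]
        )


class TestResizeColumn:
    def test_identity_when_target_equals_current(self):
        col, b = _column()
        out, b2 = resize_segmented_ascan(col, b, 2, 10, np.random.default_rng(0))
        np.testing.assert_array_equal(out, col)
        np.testing.assert_array_equal(b2, b)

    def test_total_loss_moves_layer_into_vitreous(self):
        col, b = _column(vit=20, onl=10)
        out, b2 = resize_segmented_ascan(col, b, 2, 0, np.random.default_rng(1))
        assert len(out) == len(col)
        assert b2[1] - b2[0] == 10  # inner retina untouched
        assert b2[2] - b2[1] == 0  # ONL gone
        assert b2[0] == 30  # vitreous grew by the layer's former length
        # content below the edited layer is untouched
        np.testing.assert_array_equal(out[b2[2]:], col[b[2]:])

    def test_removed_voxels_come_from_the_layer(self):
        col, b = _column()
        out, b2 = resize_segmented_ascan(col, b, 2, 6, np.random.default_rng(2))
        kept = out[b2[1]:b2[2]]
        original = col[b[1]:b[2]]
        # surviving voxels are an order-preserving subsequence of the layer
        idx = 0
        for v in kept:
            while idx < len(original) and original[idx] != v:
                idx += 1
            assert idx < len(original)
            idx += 1

    def test_inserted_vitreous_intensities_resampled_from_vitreous(self):
        col, b = _column()
        out, b2 = resize_segmented_ascan(col, b, 2, 4, np.random.default_rng(3))
        assert set(np.round(out[: b2[0]], 6)).issubset(set(np.round(col[: b[0]], 6)))

    def test_seeded_determinism(self):
        col, b = _column()
        a1, _ = resize_segmented_ascan(col, b, 2, 6, np.random.default_rng(42))
        a2, _ = resize_segmented_ascan(col, b, 2, 6, np.random.default_rng(42))
        a3, _ = resize_segmented_ascan(col, b, 2, 6, np.random.default_rng(43))
        np.testing.assert_array_equal(a1, a2)
        assert not np.array_equal(a1, a3)
        assert len(a3) == len(col)

    def test_invalid_targets(self):
        col, b = _column()
        rng = np.random.default_rng(0)
        with pytest.raises(InvalidArgumentError):
            resize_segmented_ascan(col, b, 2, -1, rng)
        with pytest.raises(InvalidArgumentError):
            resize_segmented_ascan(col, b, 2, 11, rng)

    def test_empty_vitreous_raises(self):
        col, b = _column(vit=0)
        with pytest.raises(NoCompensationLayerError):
            resize_segmented_ascan(col, b, 2, 5, np.random.default_rng(0))

    def test_removal_positions_are_uniform(self):
        """Chi-square goodness of fit of removal counts per depth over many
        seeds on a 10-voxel layer shrunk to 6."""
        col, b = _column(onl=10)
        layer = col[b[1]:b[2]]
        counts = np.zeros(10)
        n_rep = 3000
        for seed in range(n_rep):
            out, b2 = resize_segmented_ascan(col, b, 2, 6, np.random.default_rng(seed))
            kept = out[b2[1]:b2[2]]
            removed_mask = np.ones(10, bool)
            idx = 0
            for v in kept:
                while layer[idx] != v:
                    idx += 1
                removed_mask[idx] = False
                idx += 1
            counts += removed_mask
        p = stats.chisquare(counts).pvalue  # uniform expectation
        assert p > 0.001


class TestSimulateVolume:
    def test_full_survival_is_identity(self, vol_and_map, ref_vol):
        vol, _ = vol_and_map
        sim = simulate_volume(vol, ref_vol, SurvivalParams(1.0, 1.0), seed=5)
        np.testing.assert_array_equal(sim.voxels, vol.voxels)
        np.testing.assert_array_equal(sim.surfaces, np.round(vol.surfaces))

    def test_total_loss_removes_onl_and_conserves_columns(self, vol_and_map, ref_vol):
        vol, _ = vol_and_map
        sim = simulate_volume(vol, ref_vol, SurvivalParams(0.0, 0.0), seed=5)
        assert (sim.layer_thickness_voxels("ONL") == 0).all()
        assert sim.voxels.shape == vol.voxels.shape
        assert np.all(np.diff(sim.surfaces, axis=0) >= 0)

    def test_half_survival_hits_rounded_target_exactly(self, vol_and_map, ref_vol):
        vol, _ = vol_and_map
        sim = simulate_volume(vol, ref_vol, SurvivalParams(0.5, 0.5), seed=9)
        normal_vox = vol.layer_thickness_voxels("ONL")
        target = round_half_away(0.5 * normal_vox * vol.dz_um / vol.dz_um)
        np.testing.assert_array_equal(sim.layer_thickness_voxels("ONL"), target)

    def test_seeded_determinism_and_seed_sensitivity(self, vol_and_map, ref_vol):
        vol, _ = vol_and_map
        a = simulate_volume(vol, ref_vol, SurvivalParams(0.3, 0.7), seed=1)
        b = simulate_volume(vol, ref_vol, SurvivalParams(0.3, 0.7), seed=1)
        c = simulate_volume(vol, ref_vol, SurvivalParams(0.3, 0.7), seed=2)
        np.testing.assert_array_equal(a.voxels, b.voxels)
        assert not np.array_equal(a.voxels, c.voxels)

    def test_geometry_mismatch_rejected(self, vol_and_map, ref_iso):
        vol, _ = vol_and_map
        with pytest.raises(InvalidArgumentError):
            simulate_volume(vol, ref_iso, SurvivalParams(0.5, 0.5), seed=0)

    def test_column_substreams_are_independent_of_order(self):
        r1 = column_rng(3, 2, 5).integers(0, 1 << 30, 4)
        r2 = column_rng(3, 2, 5).integers(0, 1 << 30, 4)
        r3 = column_rng(3, 5, 2).integers(0, 1 << 30, 4)
        np.testing.assert_array_equal(r1, r2)
        assert not np.array_equal(r1, r3)


class TestSegmentedVolumeInvariants:
    def test_disordered_surfaces_rejected(self, cfg_vol):
        g = cfg_vol.geometry
        vox = np.zeros((g.n_rows, 50, g.n_cols))
        s = np.stack([np.full((g.n_rows, g.n_cols), v) for v in (30.0, 20.0, 35.0, 40.0)])
        with pytest.raises(InvalidArgumentError):
            SegmentedVolume(vox, s, 3.87, g)

    def test_layer_thickness_map_matches_surfaces(self, vol_and_map, cfg_vol):
        vol, tmap = vol_and_map
        um = vol.thickness_map_um("ONL")
        assert np.abs(um - tmap.values).max() <= cfg_vol.dz_um
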