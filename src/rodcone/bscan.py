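"""Simulate degenerated OCT volumes by voxel-level column editing.

Given a segmented healthy volume and a target ONL thickness per A-scan
(from the forward survival model), each A-scan column is edited in place:
the target voxel count is the simulated thickness rounded to the nearest
integer number of voxels, the surplus voxels are removed from the layer
at uniformly random depths, and the same number of voxels is inserted
into the vitreous at random depths with intensities resampled (with
replacement) from that column's own vitreous — so every column keeps its
exact original length and the retina appears to sink as the ONL thins.

Randomness is reproducible: a master seed spawns an independent
substream per (B-scan, A-scan) column, so edits are order-independent
and parallelizable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidArgumentError, NoCompensationLayerError
from .geometry import GridGeometry
from .reference import ReferenceModel
from .survival import SurvivalParams, proportional_thickness

DEFAULT_LAYER_NAMES = ("vitreous", "inner_retina", "ONL", "outer_retina", "choroid")


def round_half_away(x):
    """Round to nearest integer, ties away from zero (0.5 → 1, -0.5 → -1)."""
    x = np.asarray(x, dtype=float)
    out = np.sign(x) * np.floor(np.abs(x) + 0.5)
    return out.astype(int)


@dataclass
class SegmentedVolume:
    """An OCT voxel volume with ordered layer-boundary surfaces.

    ``voxels`` is (n_bscans, depth, n_ascans); ``surfaces`` is
    (n_surfaces, n_bscans, n_ascans) fractional-pixel depths, one per
    segmented interface, depth-ordered at every A-scan.  Layer ``k`` of
    ``layer_names`` spans [surfaces[k-1], surfaces[k]) with layer 0 (the
    vitreous) above the first interface and the last layer below the
    final one, so ``len(layer_names) == n_surfaces + 1``.
    """

    voxels: np.ndarray
    surfaces: np.ndarray
    dz_um: float
    geometry: GridGeometry
    layer_names: tuple = DEFAULT_LAYER_NAMES
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        self.surfaces = np.asarray(self.surfaces, dtype=float)
        nb, depth, na = self.voxels.shape
        if (nb, na) != (self.geometry.n_rows, self.geometry.n_cols):
            raise InvalidArgumentError("voxel grid does not match geometry")
        if self.surfaces.shape[1:] != (nb, na):
            raise InvalidArgumentError("surfaces do not match voxel grid")
        if len(self.layer_names) != self.surfaces.shape[0] + 1:
            raise InvalidArgumentError("need one layer name per inter-surface slab")
        if not self.dz_um > 0:
            raise InvalidArgumentError("axial spacing must be positive")
        if np.any(self.surfaces < 0) or np.any(self.surfaces > depth):
            raise InvalidArgumentError("surface heights must lie within [0, depth]")
        if np.any(np.diff(self.surfaces, axis=0) < 0):
            raise InvalidArgumentError("surfaces must be depth-ordered at every A-scan")

    @property
    def depth(self) -> int:
        return self.voxels.shape[1]

    def layer_index(self, name: str) -> int:
        try:
            return self.layer_names.index(name) if isinstance(self.layer_names, list) \
                else list(self.layer_names).index(name)
        except ValueError:
            raise InvalidArgumentError(f"no layer named {name!r}") from None

    def layer_thickness_voxels(self, name: str) -> np.ndarray:
        """Per-A-scan voxel count of a named layer, (n_bscans, n_ascans)."""
        k = self.layer_index(name)
        top = np.zeros(self.voxels.shape[::2]) if k == 0 else self.surfaces[k - 1]
        bottom = (
            np.full(top.shape, float(self.depth))
            if k == len(list(self.layer_names)) - 1
            else self.surfaces[k]
        )
        return bottom - top

    def thickness_map_um(self, name: str) -> np.ndarray:
        return self.layer_thickness_voxels(name) * self.dz_um


def resize_segmented_ascan(
    column: np.ndarray,
    boundaries: np.ndarray,
    layer_index: int,
    target_len: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Shrink one layer of an A-scan column to ``target_len`` voxels.

    ``boundaries`` are integer interface depths; layer ``layer_index``
    (≥ 1, the vitreous itself cannot shrink) spans
    ``[boundaries[layer_index-1], boundaries[layer_index])``.  Exactly
    ``current - target`` voxels are removed at uniformly random depths
    within the layer, and the same number of voxels — intensities drawn
    with replacement from the column's vitreous — are inserted at
    uniformly random depths in the vitreous, conserving total length.
    Boundaries above the shrunk layer shift down (deeper) by the removed
    count; boundaries at and below its lower interface are unchanged.
    """
    column = np.asarray(column)
    b = np.asarray(boundaries, dtype=int).copy()
    if layer_index < 1 or layer_index >= len(b) + 1:
        raise InvalidArgumentError("layer_index must address a sub-vitreal layer")
    top = int(b[layer_index - 1])
    bottom = int(b[layer_index]) if layer_index < len(b) else len(column)
    current = bottom - top
    if target_len < 0 or target_len > current:
        raise InvalidArgumentError(
            f"target length {target_len} outside [0, {current}] for this layer"
        )
    n = current - target_len
    if n == 0:
        return column.copy(), b
    vitreous = column[: b[0]]
    if len(vitreous) == 0:
        raise NoCompensationLayerError("vitreous is empty; cannot conserve column length")

    remove = rng.choice(current, size=n, replace=False)
    keep = np.ones(current, dtype=bool)
    keep[remove] = False
    kept_layer = column[top:bottom][keep]

    new_vit = np.empty(len(vitreous) + n, dtype=column.dtype)
    insert_at = rng.choice(len(new_vit), size=n, replace=False)
    fill = np.ones(len(new_vit), dtype=bool)
    fill[insert_at] = False
    new_vit[insert_at] = rng.choice(vitreous, size=n, replace=True)
    new_vit[fill] = vitreous

    out = np.concatenate([new_vit, column[b[0]:top], kept_layer, column[bottom:]])
    assert len(out) == len(column)
    b[: layer_index] += n  # vitreous grew; interfaces above the layer sink
    return out, b


def column_rng(seed: int, row: int, col: int) -> np.random.Generator:
    """The per-column random substream used by :func:`simulate_volume`."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(row), int(col)]))


def simulate_volume(
    vol: SegmentedVolume,
    ref: ReferenceModel,
    s: SurvivalParams,
    seed: int,
    layer: str = "ONL",
) -> SegmentedVolume:
    """Simulate photoreceptor loss in a segmented volume.

    Per A-scan the target ONL voxel count is
    ``round(T_normal * P_simulated / dz_um)`` (nearest integer, ties away
    from zero), capped at the column's current count; columns whose
    composition is missing in the reference are left unedited.  Interface
    depths are rounded to integers for editing.  Deterministic under a
    fixed seed.
    """
    if (vol.geometry.n_rows, vol.geometry.n_cols) != (
        ref.geometry.n_rows,
        ref.geometry.n_cols,
    ):
        raise InvalidArgumentError("volume and reference geometries differ")
    li = vol.layer_index(layer)
    if li < 1:
        raise InvalidArgumentError("cannot shrink the vitreous itself")
    p = np.where(ref.missing_mask, np.nan, ref.p_rods.p_rods)
    t_sim = ref.normal_thickness * proportional_thickness(p, s)
    targets = np.where(np.isnan(t_sim), -1, round_half_away(np.nan_to_num(t_sim) / vol.dz_um))

    bounds = round_half_away(vol.surfaces)  # (n_surf, nb, na) int
    new_vox = np.array(vol.voxels, copy=True)
    new_bounds = bounds.copy().astype(float)
    nb, _, na = vol.voxels.shape
    for r in range(nb):
        for c in range(na):
            tgt = int(targets[r, c])
            if tgt < 0:
                continue  # missing composition: leave column as-is
            colb = bounds[:, r, c]
            top, bottom = int(colb[li - 1]), (
                int(colb[li]) if li < len(colb) else vol.depth
            )
            cur = bottom - top
            tgt = min(tgt, cur)
            if tgt == cur:
                continue
            out, b2 = resize_segmented_ascan(
                vol.voxels[r, :, c], colb, li, tgt, column_rng(seed, r, c)
            )
            new_vox[r, :, c] = out
            new_bounds[:, r, c] = b2
    meta = dict(vol.metadata)
    meta.update({"s_cones": s.s_cones, "s_rods": s.s_rods, "seed": int(seed),
                 "resized_layer": layer})
    return SegmentedVolume(
        voxels=new_vox,
        surfaces=new_bounds,
        dz_um=vol.dz_um,
        geometry=vol.geometry,
        layer_names=tuple(vol.layer_names),
        metadata=meta,
    )
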