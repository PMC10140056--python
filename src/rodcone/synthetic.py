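"""Synthetic retinas: density fields, healthy volumes, and patient cohorts.

Everything downstream — registration, the forward survival model, the
inversion and the B-scan simulator — is exercised on synthetic eyes that
reproduce the qualitative topography of human photoreceptors: cone
density peaks sharply at the fovea and decays with eccentricity, rods
are absent from the foveal center and peak in a ring at mid-peripheral
eccentricity, and the healthy ONL (HFL + ONL + myoid zone) is thickest
at the fovea.  The functional forms are simple parametric stand-ins for
measured histology:

    cones(e) = floor + (peak - floor) * exp(-e / decay)
    rods(e)  = peak_r * exp(-(e - ring)^2 / (2 w^2))   for e > rod-free radius,
               0 otherwise
    onl(e)   = floor_t + (peak_t - floor_t) * exp(-(e / sigma)^2)

with eccentricity ``e`` in mm from the fovea.  Samples are laid out on a
Fermat spiral (uniform areal coverage, like the spiral sampling schemes
used in histology) with a small seeded jitter, plus a point at the
foveal center and a tight rod-free ring around it so that interpolated
rod density at the fovea is exactly zero.

All generators are deterministic under their configured seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .bscan import DEFAULT_LAYER_NAMES, SegmentedVolume, round_half_away
from .errors import InvalidArgumentError
from .etdrs import CENTER, OUTER_RING, EtdrsGrid, region_masks, regional_mean
from .geometry import DEFAULT_RETINAL_RADIUS_MM, GridGeometry
from .maps import ThicknessMap
from .reference import DensitySample, ReferenceModel
from .survival import SurvivalParams, simulate_thickness

GOLDEN_ANGLE_RAD = np.pi * (3.0 - np.sqrt(5.0))


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic eye and cohort.

    Scan shape and spacing default to a 61-B-scan macular volume
    (61 × 512 A-scans at 0.06 × 0.012 mm, 496 voxels deep); density and
    thickness magnitudes default to values of the order reported for
    human retina (peak cone density ~190k cells/mm² at the fovea, rod
    peak ~160k in a ring at ~4 mm, foveal ONL ~110 µm thinning to
    ~60 µm peripherally).
    """

    seed: int = 0
    # scan raster
    n_rows: int = 61
    n_cols: int = 512
    dx_mm: float = 0.012
    dy_mm: float = 0.06
    fovea_rc: tuple = (30.0, 255.5)
    nerve_rc: tuple = (25.0, 638.8)  # outside the raster, as in macular scans
    laterality: str = "OS"
    # axial sampling
    n_depth: int = 496
    dz_um: float = 3.87
    # cone profile (cells/mm²; mm)
    cone_peak: float = 190_000.0
    cone_decay_mm: float = 0.6
    cone_floor: float = 4_000.0
    # rod profile
    rod_peak: float = 160_000.0
    rod_ring_ecc_mm: float = 4.0
    rod_ring_width_mm: float = 1.8
    rod_free_radius_mm: float = 0.2
    # healthy ONL profile (µm; mm)
    onl_peak_um: float = 110.0
    onl_floor_um: float = 60.0
    onl_sigma_mm: float = 1.2
    # sampling pattern
    n_samples: int = 400
    max_ecc_mm: float = 10.0
    retinal_radius_mm: float = DEFAULT_RETINAL_RADIUS_MM
    # cohort
    n_patients: int = 50
    n_controls: int = 40
    noise_sd_um: float = 2.0
    s_cones_range: tuple = (0.0, 1.0)
    s_rods_range: tuple = (0.0, 1.0)

    def __post_init__(self) -> None:
        for name in ("cone_peak", "cone_decay_mm", "cone_floor", "rod_peak",
                     "rod_ring_ecc_mm", "rod_ring_width_mm", "rod_free_radius_mm",
                     "onl_peak_um", "onl_floor_um", "onl_sigma_mm", "noise_sd_um"):
            if getattr(self, name) < 0:
                raise InvalidArgumentError(f"{name} must be >= 0")
        if not self.rod_free_radius_mm < self.rod_ring_ecc_mm:
            raise InvalidArgumentError("rod-free radius must be below the rod-ring eccentricity")

    @property
    def geometry(self) -> GridGeometry:
        return GridGeometry(
            n_rows=self.n_rows, n_cols=self.n_cols,
            dx_mm=self.dx_mm, dy_mm=self.dy_mm,
            fovea_rc=tuple(self.fovea_rc), nerve_rc=tuple(self.nerve_rc),
            laterality=self.laterality,
        )

    # radial profiles -----------------------------------------------------
    def cone_density(self, ecc_mm):
        e = np.asarray(ecc_mm, dtype=float)
        return self.cone_floor + (self.cone_peak - self.cone_floor) * np.exp(
            -e / self.cone_decay_mm
        )

    def rod_density(self, ecc_mm):
        e = np.asarray(ecc_mm, dtype=float)
        ring = self.rod_peak * np.exp(
            -((e - self.rod_ring_ecc_mm) ** 2) / (2.0 * self.rod_ring_width_mm**2)
        )
        return np.where(e > self.rod_free_radius_mm, ring, 0.0)

    def onl_thickness_um(self, ecc_mm):
        e = np.asarray(ecc_mm, dtype=float)
        return self.onl_floor_um + (self.onl_peak_um - self.onl_floor_um) * np.exp(
            -((e / self.onl_sigma_mm) ** 2)
        )


def _spiral_planar_points(cfg: SynthConfig) -> np.ndarray:
    """Deterministic scattered sampling pattern in canonical planar mm:
    the foveal center, a tight rod-free octagon, then a jittered Fermat
    spiral out to ``max_ecc_mm``."""
    rng = np.random.default_rng(cfg.seed)
    pts = [(0.0, 0.0)]
    for k in range(8):
        a = 2 * np.pi * k / 8
        pts.append((0.1 * np.cos(a), 0.1 * np.sin(a)))
    n = cfg.n_samples
    k = np.arange(1, n + 1)
    r = cfg.max_ecc_mm * np.sqrt(k / n)
    theta = k * GOLDEN_ANGLE_RAD + rng.uniform(-0.05, 0.05, size=n)
    pts.extend(zip(r * np.cos(theta), r * np.sin(theta)))
    return np.asarray(pts)


def synth_density_samples(cfg: SynthConfig) -> list[DensitySample]:
    """Scattered rod/cone density samples in spherical retinal coordinates."""
    xy = _spiral_planar_points(cfg)
    ecc = np.hypot(xy[:, 0], xy[:, 1])
    lon = np.degrees(np.arctan2(xy[:, 1], xy[:, 0]))
    colat = np.degrees(ecc / cfg.retinal_radius_mm)
    rods = cfg.rod_density(ecc)
    cones = cfg.cone_density(ecc)
    return [
        DensitySample(
            longitude_deg=float(lo), colatitude_deg=float(co),
            rods=float(r), cones=float(c),
        )
        for lo, co, r, c in zip(lon, colat, rods, cones)
    ]


def synth_healthy_thickness(cfg: SynthConfig) -> ThicknessMap:
    """Healthy ONL thickness map from the configured radial profile."""
    g = cfg.geometry
    values = cfg.onl_thickness_um(g.eccentricity_mm())
    return ThicknessMap(g, values, kind="normal")


_LAYER_INTENSITY = {"vitreous": 10.0, "inner_retina": 120.0, "ONL": 60.0,
                    "outer_retina": 150.0, "choroid": 90.0}
_INNER_RETINA_VOX = 40
_OUTER_RETINA_VOX = 30
_VITREOUS_MIN_VOX = 40


def synth_healthy_volume(cfg: SynthConfig) -> tuple[SegmentedVolume, ThicknessMap]:
    """A segmented healthy voxel volume plus its (smooth) ONL thickness map.

    Layers other than the ONL have constant voxel thickness; the ONL
    voxel count is the radial profile rounded to whole voxels, so the map
    and the surfaces agree within one voxel.  Voxel intensities are
    piecewise-constant per layer with seeded Gaussian noise.  The retina
    is anchored near the bottom of the column so the vitreous above it
    can absorb inserted voxels.
    """
    g = cfg.geometry
    tmap = synth_healthy_thickness(cfg)
    onl_vox = round_half_away(tmap.values / cfg.dz_um)

    depth = cfg.n_depth
    bottom = depth - 60  # fixed base of the outer retina stack
    s3 = np.full((g.n_rows, g.n_cols), float(bottom))  # outer_retina/choroid
    s2 = s3 - _OUTER_RETINA_VOX                        # ONL/outer_retina
    s1 = s2 - onl_vox                                  # inner_retina/ONL
    s0 = s1 - _INNER_RETINA_VOX                        # vitreous/inner_retina
    if np.any(s0 < _VITREOUS_MIN_VOX):
        raise InvalidArgumentError("scan depth too shallow for the configured retina")
    surfaces = np.stack([s0, s1, s2, s3])

    rng = np.random.default_rng(cfg.seed + 1)
    depth_idx = np.arange(depth)[None, :, None]
    vox = np.full((g.n_rows, depth, g.n_cols), _LAYER_INTENSITY["vitreous"], dtype=float)
    slabs = [surfaces[i][:, None, :] for i in range(4)]
    names = list(DEFAULT_LAYER_NAMES)
    for k, name in enumerate(names[1:], start=1):
        top = slabs[k - 1]
        bot = slabs[k] if k < 4 else np.full_like(top, depth)
        vox = np.where((depth_idx >= top) & (depth_idx < bot), _LAYER_INTENSITY[name], vox)
    vox = np.clip(vox + rng.normal(0.0, 5.0, size=vox.shape), 0.0, None)

    volume = SegmentedVolume(
        voxels=vox.astype(np.float32),
        surfaces=surfaces,
        dz_um=cfg.dz_um,
        geometry=g,
        layer_names=tuple(names),
        metadata={"synthetic": True, "seed": cfg.seed},
    )
    return volume, tmap


def synth_cohort(
    cfg: SynthConfig,
    ref: ReferenceModel,
    grid: EtdrsGrid | None = None,
) -> pd.DataFrame:
    """Simulated patient table with known ground-truth survival.

    Patients draw (S_cones, S_rods) uniformly from the configured ranges;
    controls are fixed at full survival (1, 1).  Regional mean ONL
    thicknesses come from the forward model with additive Gaussian noise
    of sd ``noise_sd_um``.  Columns: patient_id, group, s_cones_true,
    s_rods_true, t_center_um, t_outer_um.
    """
    rng = np.random.default_rng(cfg.seed + 2)
    if grid is None:
        grid = EtdrsGrid()
    masks = region_masks(grid, ref.geometry)
    rows = []
    truths = [
        (f"P{i + 1:03d}", "patient",
         rng.uniform(*cfg.s_cones_range), rng.uniform(*cfg.s_rods_range))
        for i in range(cfg.n_patients)
    ] + [(f"C{i + 1:03d}", "control", 1.0, 1.0) for i in range(cfg.n_controls)]
    for pid, group, sc, sr in truths:
        t = simulate_thickness(ref, SurvivalParams(sc, sr))
        tc = regional_mean(t, masks[CENTER])
        to = regional_mean(t, masks[OUTER_RING])
        tc = max(0.0, tc + rng.normal(0.0, cfg.noise_sd_um))
        to = max(0.0, to + rng.normal(0.0, cfg.noise_sd_um))
        rows.append(
            {"patient_id": pid, "group": group, "s_cones_true": sc,
             "s_rods_true": sr, "t_center_um": tc, "t_outer_um": to}
        )
    return pd.DataFrame(rows)


def synth_reference(cfg: SynthConfig, method: str = "linear") -> ReferenceModel:
    """Full synthetic reference model: generated densities registered and
    interpolated onto the generated healthy thickness map."""
    from .reference import build_reference  # local import avoids cycle at import time

    samples = synth_density_samples(cfg)
    tmap = synth_healthy_thickness(cfg)
    return build_reference(
        tmap, samples, retinal_radius_mm=cfg.retinal_radius_mm, method=method
    )
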