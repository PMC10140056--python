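"""Build the density-registered reference model of the healthy eye.

The reference model couples a healthy ONL thickness map (ONL here always
means the combined Henle fiber layer + outer nuclear layer + myoid zone)
with the expected local composition of photoreceptors.  Tabulated rod and
cone densities, sampled in spherical retinal coordinates by histology,
are projected to planar mm, registered onto the scan raster through the
fovea and optic-nerve landmarks, interpolated at every A-scan position,
and converted to the rod proportion

    P_rods = rods / (rods + cones),        P_cones = 1 - P_rods.

Interpolation is piecewise-linear on a Delaunay triangulation by default
(exact at the sampling points, reproduces affine fields); a C1-smooth
variant is selectable.  Positions outside the convex hull of the samples
are marked invalid rather than extrapolated, and any negative
interpolated density is clamped to zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CloughTocher2DInterpolator, LinearNDInterpolator
from scipy.spatial import QhullError

from .errors import InsufficientSupportError, InvalidArgumentError
from .geometry import (
    DEFAULT_RETINAL_RADIUS_MM,
    GridGeometry,
    register_landmarks,
    source_nerve_xy_mm,
    spherical_to_planar,
)
from .maps import ThicknessMap

logger = logging.getLogger(__name__)

INTERP_METHODS = ("linear", "smooth")


@dataclass(frozen=True)
class DensitySample:
    """One histologic sampling point: spherical retinal coordinates plus
    rod and cone densities in cells/mm²."""

    longitude_deg: float
    colatitude_deg: float
    rods: float
    cones: float

    def __post_init__(self) -> None:
        if self.colatitude_deg < 0:
            raise InvalidArgumentError("colatitude must be >= 0")
        if self.rods < 0 or self.cones < 0:
            raise InvalidArgumentError("densities must be >= 0")


@dataclass
class DensityField:
    """Rod and cone densities interpolated at every A-scan position."""

    geometry: GridGeometry
    rod_density: np.ndarray
    cone_density: np.ndarray
    valid_mask: np.ndarray

    def __post_init__(self) -> None:
        shape = (self.geometry.n_rows, self.geometry.n_cols)
        for name in ("rod_density", "cone_density", "valid_mask"):
            arr = np.asarray(getattr(self, name))
            if arr.shape != shape:
                raise InvalidArgumentError(f"{name} shape {arr.shape} != geometry {shape}")
            setattr(self, name, arr)
        self.valid_mask = self.valid_mask.astype(bool)
        for arr in (self.rod_density, self.cone_density):
            if np.any(arr[self.valid_mask] < 0):
                raise InvalidArgumentError("densities must be >= 0 where valid")


@dataclass
class ProportionMap:
    """Per-A-scan expected rod proportion; cones are implicitly 1 - P_rods."""

    geometry: GridGeometry
    p_rods: np.ndarray
    missing_mask: np.ndarray

    def __post_init__(self) -> None:
        shape = (self.geometry.n_rows, self.geometry.n_cols)
        self.p_rods = np.asarray(self.p_rods, dtype=float)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if self.p_rods.shape != shape or self.missing_mask.shape != shape:
            raise InvalidArgumentError("proportion map shape does not match geometry")
        ok = ~self.missing_mask
        if np.any((self.p_rods[ok] < 0) | (self.p_rods[ok] > 1)):
            raise InvalidArgumentError("p_rods must lie in [0, 1] where not missing")

    @property
    def p_cones(self) -> np.ndarray:
        return 1.0 - self.p_rods


@dataclass
class ReferenceModel:
    """The healthy-eye bundle: normal ONL thickness + rod-proportion map."""

    geometry: GridGeometry
    normal_thickness: np.ndarray  # µm
    p_rods: ProportionMap

    def __post_init__(self) -> None:
        shape = (self.geometry.n_rows, self.geometry.n_cols)
        self.normal_thickness = np.asarray(self.normal_thickness, dtype=float)
        if self.normal_thickness.shape != shape:
            raise InvalidArgumentError("normal_thickness shape does not match geometry")
        if np.any(self.normal_thickness < 0):
            raise InvalidArgumentError("normal_thickness must be >= 0")
        if self.p_rods.geometry.to_dict() != self.geometry.to_dict():
            raise InvalidArgumentError("proportion map geometry differs from reference")

    @property
    def missing_mask(self) -> np.ndarray:
        return self.p_rods.missing_mask

    @property
    def normal_map(self) -> ThicknessMap:
        return ThicknessMap(self.geometry, self.normal_thickness.copy(), kind="normal")

    def mirrored(self) -> "ReferenceModel":
        g = self.geometry.mirrored()
        return ReferenceModel(
            geometry=g,
            normal_thickness=self.normal_thickness[:, ::-1].copy(),
            p_rods=ProportionMap(
                g,
                self.p_rods.p_rods[:, ::-1].copy(),
                self.p_rods.missing_mask[:, ::-1].copy(),
            ),
        )


def _make_interpolant(points_xy: np.ndarray, values: np.ndarray, method: str):
    if method not in INTERP_METHODS:
        raise InvalidArgumentError(f"method must be one of {INTERP_METHODS}")
    points_xy = np.asarray(points_xy, dtype=float)
    values = np.asarray(values, dtype=float)
    if points_xy.ndim != 2 or points_xy.shape[1] != 2 or len(points_xy) != len(values):
        raise InvalidArgumentError("expected (N, 2) points and matching (N,) values")
    if len(points_xy) < 3:
        raise InsufficientSupportError("need at least 3 scattered samples")
    cls = LinearNDInterpolator if method == "linear" else CloughTocher2DInterpolator
    try:
        return cls(points_xy, values)
    except QhullError as exc:
        raise InsufficientSupportError(
            "scattered samples are collinear; no triangulation exists"
        ) from exc


def interpolate_density(
    points_xy: np.ndarray,
    values: np.ndarray,
    geometry: GridGeometry,
    method: str = "linear",
) -> tuple[np.ndarray, np.ndarray, int]:
    """Interpolate one scattered density channel onto every A-scan position.

    Parameters
    ----------
    points_xy : (N, 2) array
        Sample positions in absolute scan mm (x = col·dx, y = row·dy).
    values : (N,) array
        Channel values (cells/mm²) at the samples.
    geometry : GridGeometry
        Target raster; the channel is evaluated at every pixel center.
    method : {"linear", "smooth"}
        Piecewise-linear Delaunay interpolation (default) or the C1-smooth
        Clough–Tocher variant.  Both are exact at the sample positions and
        reproduce affine fields inside the convex hull.

    Returns
    -------
    grid : (n_rows, n_cols) float array, NaN outside the convex hull.
    valid_mask : boolean array, True inside the interpolation support.
    n_clamped : number of pixels whose (small) negative interpolated value
        was clamped to zero; densities are physical.
    """
    interp = _make_interpolant(points_xy, values, method)
    x, y = geometry.pixel_centers_mm()
    grid = interp(np.column_stack([x.ravel(), y.ravel()])).reshape(x.shape)
    valid = ~np.isnan(grid)
    neg = valid & (grid < 0)
    n_clamped = int(neg.sum())
    if n_clamped:
        logger.info("clamped %d negative interpolated values to 0", n_clamped)
        grid[neg] = 0.0
    return grid, valid, n_clamped


def compute_proportions(field: DensityField) -> ProportionMap:
    """Rod proportion per A-scan: rods / (rods + cones).

    Positions with zero total density or outside the interpolation support
    become missing; NaN is never silently propagated.
    """
    total = field.rod_density + field.cone_density
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(total > 0, field.rod_density / np.where(total > 0, total, 1.0), np.nan)
    missing = ~field.valid_mask | ~(total > 0)
    p = np.where(missing, np.nan, p)
    return ProportionMap(field.geometry, np.where(missing, 0.0, p), missing)


def samples_to_planar(
    samples: list[DensitySample],
    retinal_radius_mm: float = DEFAULT_RETINAL_RADIUS_MM,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Project density samples to canonical planar mm.

    Returns (xy (N,2), rods (N,), cones (N,)).
    """
    lon = np.array([s.longitude_deg for s in samples])
    colat = np.array([s.colatitude_deg for s in samples])
    x, y = spherical_to_planar(lon, colat, retinal_radius_mm)
    rods = np.array([s.rods for s in samples])
    cones = np.array([s.cones for s in samples])
    return np.column_stack([x, y]), rods, cones


def build_density_field(
    samples: list[DensitySample],
    geometry: GridGeometry,
    retinal_radius_mm: float = DEFAULT_RETINAL_RADIUS_MM,
    nerve_colatitude_deg: float | None = None,
    method: str = "linear",
) -> DensityField:
    """Project, register and interpolate density samples onto a scan raster."""
    xy, rods, cones = samples_to_planar(samples, retinal_radius_mm)
    src_nerve = (
        source_nerve_xy_mm(retinal_radius_mm)
        if nerve_colatitude_deg is None
        else spherical_to_planar(0.0, nerve_colatitude_deg, retinal_radius_mm)
    )
    rc = register_landmarks(xy, geometry, src_fovea=(0.0, 0.0), src_nerve=src_nerve)
    x_mm, y_mm = geometry.rc_to_mm(rc[:, 0], rc[:, 1])
    pts = np.column_stack([x_mm, y_mm])
    rod_grid, valid_r, _ = interpolate_density(pts, rods, geometry, method)
    cone_grid, valid_c, _ = interpolate_density(pts, cones, geometry, method)
    valid = valid_r & valid_c
    return DensityField(
        geometry=geometry,
        rod_density=np.where(valid, rod_grid, np.nan),
        cone_density=np.where(valid, cone_grid, np.nan),
        valid_mask=valid,
    )


def build_reference(
    thickness: ThicknessMap,
    samples: list[DensitySample],
    retinal_radius_mm: float = DEFAULT_RETINAL_RADIUS_MM,
    nerve_colatitude_deg: float | None = None,
    method: str = "linear",
) -> ReferenceModel:
    """Assemble the reference model for one eye.

    Chains projection → landmark registration → interpolation → proportions
    and bundles the result with the healthy ONL thickness map, whose
    geometry (including fovea/nerve landmarks and laterality) drives the
    registration.
    """
    field = build_density_field(
        samples,
        thickness.geometry,
        retinal_radius_mm=retinal_radius_mm,
        nerve_colatitude_deg=nerve_colatitude_deg,
        method=method,
    )
    props = compute_proportions(field)
    values = np.asarray(thickness.values, dtype=float)
    # a pixel with no measured normal thickness is missing for all purposes
    missing = props.missing_mask | np.isnan(values)
    props = ProportionMap(thickness.geometry, np.where(missing, 0.0, props.p_rods), missing)
    return ReferenceModel(
        geometry=thickness.geometry,
        normal_thickness=np.where(np.isnan(values), 0.0, values),
        p_rods=props,
    )
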