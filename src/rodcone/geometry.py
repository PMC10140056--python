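"""Scan geometry, retinal coordinate projection, and landmark registration.

The en face frame of an OCT volume is a raster of A-scan positions: row =
slow axis (B-scan index), col = fast axis (A-scan index), with physical
spacing ``dy_mm`` × ``dx_mm`` and 0-based, pixel-center indexing.  Planar
retinal coordinates are fovea-centered millimetres in a canonical left-eye
(OS) frame with +x toward the optic-nerve side; right-eye (OD) data are
mirrored across the vertical axis on ingest.

Histologic photoreceptor densities are tabulated in spherical retinal
coordinates (longitude and colatitude centered on the foveal pole).  They
are flattened with an azimuthal-equidistant projection about the fovea:
the radial arc length is preserved along every meridian,

    r  = R * colatitude [rad]
    x  = r * cos(longitude),   y = r * sin(longitude)

with ``R`` the retinal radius of the model eye (default 12 mm).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np

from .errors import DegenerateLandmarkError, InvalidArgumentError

#: Default retinal radius (mm) of the idealized model eye used to convert
#: spherical retinal coordinates to planar millimetres.
DEFAULT_RETINAL_RADIUS_MM = 12.0

#: Default colatitude (degrees) of the optic-nerve center in the canonical
#: source frame; with the 12 mm radius this puts the disc 4.6 mm from the
#: fovea on the horizontal meridian, matching anatomic norms.
DEFAULT_NERVE_COLATITUDE_DEG = 22.0

LATERALITIES = ("OD", "OS")


@dataclass(frozen=True)
class GridGeometry:
    """En face raster geometry of an OCT volume with its two landmarks.

    Parameters
    ----------
    n_rows, n_cols : int
        Slow-axis (B-scan) and fast-axis (A-scan) extents.
    dx_mm, dy_mm : float
        Pixel spacing along columns (x) and rows (y), mm/pixel.
    fovea_rc, nerve_rc : (float, float)
        Fractional-pixel (row, col) positions of the fovea and the center
        of the optic nerve.  Either may fall outside the scan raster (the
        optic nerve usually does in macular volumes); such landmarks are
        flagged, not rejected.
    laterality : {"OD", "OS"}
        Right or left eye.
    """

    n_rows: int
    n_cols: int
    dx_mm: float
    dy_mm: float
    fovea_rc: tuple[float, float]
    nerve_rc: tuple[float, float]
    laterality: str = "OS"

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise InvalidArgumentError("grid dimensions must be positive")
        if not (self.dx_mm > 0 and self.dy_mm > 0):
            raise InvalidArgumentError("pixel spacing must be positive")
        if self.laterality not in LATERALITIES:
            raise InvalidArgumentError(
                f"laterality must be one of {LATERALITIES}, got {self.laterality!r}"
            )
        if tuple(self.fovea_rc) == tuple(self.nerve_rc):
            raise DegenerateLandmarkError("fovea and optic-nerve landmarks coincide")
        object.__setattr__(self, "fovea_rc", tuple(float(v) for v in self.fovea_rc))
        object.__setattr__(self, "nerve_rc", tuple(float(v) for v in self.nerve_rc))

    # -- pixel <-> mm -----------------------------------------------------
    def rc_to_mm(self, rows, cols) -> tuple[np.ndarray, np.ndarray]:
        """Pixel (row, col) to absolute scan mm (x, y); pixel-center convention."""
        return np.asarray(cols, float) * self.dx_mm, np.asarray(rows, float) * self.dy_mm

    def mm_to_rc(self, x_mm, y_mm) -> tuple[np.ndarray, np.ndarray]:
        """Absolute scan mm (x, y) back to fractional pixel (row, col)."""
        return np.asarray(y_mm, float) / self.dy_mm, np.asarray(x_mm, float) / self.dx_mm

    @property
    def fovea_mm(self) -> tuple[float, float]:
        x, y = self.rc_to_mm(self.fovea_rc[0], self.fovea_rc[1])
        return float(x), float(y)

    @property
    def nerve_mm(self) -> tuple[float, float]:
        x, y = self.rc_to_mm(self.nerve_rc[0], self.nerve_rc[1])
        return float(x), float(y)

    def contains_rc(self, row: float, col: float) -> bool:
        return 0 <= row < self.n_rows and 0 <= col < self.n_cols

    @property
    def fovea_inside(self) -> bool:
        return self.contains_rc(*self.fovea_rc)

    @property
    def nerve_inside(self) -> bool:
        return self.contains_rc(*self.nerve_rc)

    def pixel_centers_mm(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) mm coordinate arrays of every pixel center, each (n_rows, n_cols)."""
        cols, rows = np.meshgrid(np.arange(self.n_cols), np.arange(self.n_rows))
        return self.rc_to_mm(rows, cols)

    def eccentricity_mm(self, center_rc: tuple[float, float] | None = None) -> np.ndarray:
        """Radial distance (mm) of every pixel center from ``center_rc``
        (default: the fovea), respecting anisotropic spacing."""
        if center_rc is None:
            center_rc = self.fovea_rc
        x, y = self.pixel_centers_mm()
        cx, cy = self.rc_to_mm(center_rc[0], center_rc[1])
        return np.hypot(x - cx, y - cy)

    def mirrored(self) -> "GridGeometry":
        """The same raster viewed from the fellow eye: columns reversed,
        landmarks mirrored about the vertical axis, laterality swapped."""
        flip = lambda rc: (rc[0], (self.n_cols - 1) - rc[1])  # noqa: E731
        return replace(
            self,
            fovea_rc=flip(self.fovea_rc),
            nerve_rc=flip(self.nerve_rc),
            laterality="OD" if self.laterality == "OS" else "OS",
        )

    # -- (de)serialisation ------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "n_rows": self.n_rows,
            "n_cols": self.n_cols,
            "dx_mm": self.dx_mm,
            "dy_mm": self.dy_mm,
            "fovea_rc": list(self.fovea_rc),
            "nerve_rc": list(self.nerve_rc),
            "laterality": self.laterality,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GridGeometry":
        return cls(
            n_rows=int(d["n_rows"]),
            n_cols=int(d["n_cols"]),
            dx_mm=float(d["dx_mm"]),
            dy_mm=float(d["dy_mm"]),
            fovea_rc=tuple(d["fovea_rc"]),
            nerve_rc=tuple(d["nerve_rc"]),
            laterality=str(d["laterality"]),
        )


def spherical_to_planar(
    longitude_deg,
    colatitude_deg,
    retinal_radius_mm: float = DEFAULT_RETINAL_RADIUS_MM,
) -> tuple[np.ndarray, np.ndarray]:
    """Project spherical retinal coordinates to fovea-centered planar mm.

    Azimuthal-equidistant projection about the foveal pole: the radial
    arc length ``r = R * colatitude`` is preserved along every meridian.
    Returns ``(x_mm, y_mm)`` in the canonical (left-eye) frame.  Scalar
    inputs give scalar outputs.
    """
    lon = np.asarray(longitude_deg, dtype=float)
    colat = np.asarray(colatitude_deg, dtype=float)
    if np.any(colat < 0):
        raise InvalidArgumentError("colatitude must be >= 0")
    if not retinal_radius_mm > 0:
        raise InvalidArgumentError("retinal radius must be positive")
    r = retinal_radius_mm * np.deg2rad(colat)
    x = r * np.cos(np.deg2rad(lon))
    y = r * np.sin(np.deg2rad(lon))
    if np.isscalar(longitude_deg) and np.isscalar(colatitude_deg):
        return float(x), float(y)
    return x, y


def source_nerve_xy_mm(
    retinal_radius_mm: float = DEFAULT_RETINAL_RADIUS_MM,
    nerve_colatitude_deg: float = DEFAULT_NERVE_COLATITUDE_DEG,
) -> tuple[float, float]:
    """Planar position of the optic-nerve center in the canonical source
    frame (on the horizontal meridian at the configured colatitude)."""
    return spherical_to_planar(0.0, nerve_colatitude_deg, retinal_radius_mm)


@dataclass(frozen=True)
class LandmarkTransform:
    """Two-landmark similarity transform between planar mm frames.

    Optionally mirrors the source across the vertical axis through its
    fovea first (right-eye targets), then applies the unique direct
    similarity (rotation + isotropic scale + translation) taking the
    source fovea and nerve exactly onto the target fovea and nerve.
    Implemented as a complex-affine map ``w = a*z + b``.
    """

    a: complex
    b: complex
    mirror: bool
    mirror_x: float  # vertical axis (x = const) used for the source mirror

    @classmethod
    def from_landmarks(
        cls,
        src_fovea: tuple[float, float],
        src_nerve: tuple[float, float],
        tgt_fovea: tuple[float, float],
        tgt_nerve: tuple[float, float],
        mirror: bool = False,
    ) -> "LandmarkTransform":
        zf, zn = complex(*src_fovea), complex(*src_nerve)
        wf, wn = complex(*tgt_fovea), complex(*tgt_nerve)
        if zf == zn or wf == wn:
            raise DegenerateLandmarkError(
                "fovea and nerve coincide; similarity transform undefined"
            )
        mx = src_fovea[0]
        if mirror:
            zn = complex(2 * mx - zn.real, zn.imag)
        a = (wn - wf) / (zn - zf)
        b = wf - a * zf
        return cls(a=a, b=b, mirror=mirror, mirror_x=mx)

    @property
    def scale(self) -> float:
        return abs(self.a)

    @property
    def rotation_deg(self) -> float:
        return math.degrees(math.atan2(self.a.imag, self.a.real))

    def apply(self, points_xy: np.ndarray) -> np.ndarray:
        """Map an (N, 2) array of source (x, y) mm points into the target frame."""
        p = np.atleast_2d(np.asarray(points_xy, dtype=float))
        x = p[:, 0]
        if self.mirror:
            x = 2 * self.mirror_x - x
        z = x + 1j * p[:, 1]
        w = self.a * z + self.b
        return np.column_stack([w.real, w.imag])

    def invert(self, points_xy: np.ndarray) -> np.ndarray:
        """Map target-frame points back to the source frame (exact inverse)."""
        p = np.atleast_2d(np.asarray(points_xy, dtype=float))
        z = (p[:, 0] + 1j * p[:, 1] - self.b) / self.a
        x = z.real
        if self.mirror:
            x = 2 * self.mirror_x - x
        return np.column_stack([x, z.imag])


def register_landmarks(
    points_xy: np.ndarray,
    target: GridGeometry,
    src_fovea: tuple[float, float] = (0.0, 0.0),
    src_nerve: tuple[float, float] | None = None,
) -> np.ndarray:
    """Register canonical-frame planar points onto a target scan raster.

    Source points are fovea-centered mm in the canonical left-eye frame
    (see module docstring); ``src_nerve`` defaults to the model-eye disc
    position.  For OD targets the source is mirrored across the vertical
    axis first.  Returns an (N, 2) array of fractional (row, col) pixel
    positions; points landing outside the raster are retained (callers
    mask them, they are not clipped).
    """
    if src_nerve is None:
        src_nerve = source_nerve_xy_mm()
    t = LandmarkTransform.from_landmarks(
        src_fovea,
        src_nerve,
        target.fovea_mm,
        target.nerve_mm,
        mirror=(target.laterality == "OD"),
    )
    xy = t.apply(points_xy)
    rows, cols = target.mm_to_rc(xy[:, 0], xy[:, 1])
    return np.column_stack([rows, cols])
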