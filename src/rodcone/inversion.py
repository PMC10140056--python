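"""Invert the two-region linear system for global rod/cone survival.

A single region's mean thickness is one linear equation in the two
survival fractions, so it cannot identify them.  Two regions with
different rod/cone compositions — here the ETDRS center subfield
(cone-dominated) and outer ring (rod-dominated) — give a 2×2 linear
system with a unique solution:

    [ t_center ]   [ a_cones_center  a_rods_center ] [ S_cones ]
    [ t_outer  ] = [ a_cones_outer   a_rods_outer  ] [ S_rods  ]

where the region coefficients are the mean, over the region, of the
normal thickness attributed to each cell class:

    a_cones = <T_normal * (1 - P_rods)>,   a_rods = <T_normal * P_rods>,

so a_cones + a_rods equals the region's normal mean thickness.  Exact
solutions outside the physical box [0, 1]² are replaced by the
box-constrained least-squares solution (smallest squared thickness
residual), flagged per parameter, with the residual reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import lsq_linear

from .errors import EmptyRegionError, InvalidArgumentError, NonIdentifiableError
from .etdrs import CENTER, OUTER_RING, EtdrsGrid, RegionMasks, region_masks
from .reference import ReferenceModel
from .survival import SurvivalGrid, SurvivalParams

#: Conservative guard for the uniqueness requirement: condition numbers
#: above this mean the two regions have effectively identical composition.
DEFAULT_COND_THRESHOLD = 1e6

_BOX_EPS = 1e-9  # slack before the box-constrained fallback engages


@dataclass(frozen=True)
class RegionCoefficients:
    """Thickness (µm) contributed by full cone / full rod survival in a region."""

    a_cones: float
    a_rods: float

    def __post_init__(self) -> None:
        if self.a_cones < 0 or self.a_rods < 0:
            raise InvalidArgumentError("region coefficients must be >= 0")

    @property
    def normal_mean(self) -> float:
        return self.a_cones + self.a_rods


@dataclass(frozen=True)
class SurvivalEstimate:
    """A fitted survival pair with clamping flags and per-region residuals."""

    s: SurvivalParams
    clamped: tuple[bool, bool]  # (cones, rods)
    residual_um: tuple[float, float]  # (center, outer)
    method: str  # "linear" or "grid_lookup"

    @property
    def max_residual_um(self) -> float:
        return max(abs(r) for r in self.residual_um)


def region_coefficients(ref: ReferenceModel, mask: np.ndarray) -> RegionCoefficients:
    """Mean thickness attributable to cones and to rods over a region mask.

    Missing pixels are excluded; the two coefficients sum to the regional
    normal mean thickness by construction.
    """
    mask = np.asarray(mask, bool)
    ok = mask & ~ref.missing_mask
    if not ok.any():
        raise EmptyRegionError("no valid pixels in region")
    t = ref.normal_thickness[ok]
    p = ref.p_rods.p_rods[ok]
    return RegionCoefficients(
        a_cones=float(np.mean(t * (1.0 - p))),
        a_rods=float(np.mean(t * p)),
    )


def design_matrix(
    ref: ReferenceModel, grid: EtdrsGrid | RegionMasks | None = None
) -> np.ndarray:
    """The 2×2 coefficient matrix [[a_cones, a_rods] per region] for the
    center subfield (row 0) and outer ring (row 1)."""
    if grid is None:
        grid = EtdrsGrid()
    masks = grid if isinstance(grid, RegionMasks) else region_masks(grid, ref.geometry)
    c = region_coefficients(ref, masks[CENTER])
    o = region_coefficients(ref, masks[OUTER_RING])
    return np.array([[c.a_cones, c.a_rods], [o.a_cones, o.a_rods]])


def _solve_box(A: np.ndarray, t: np.ndarray, cond_threshold: float, method: str) -> SurvivalEstimate:
    if np.any(t < 0):
        raise InvalidArgumentError("regional thicknesses must be >= 0")
    cond = np.linalg.cond(A)
    if not np.isfinite(cond) or cond > cond_threshold:
        raise NonIdentifiableError(
            "the two regions have effectively identical rod/cone composition "
            f"(condition number {cond:.3g}); the survival pair is not identifiable"
        )
    s = np.linalg.solve(A, t)
    clamped = (False, False)
    if np.any(s < -_BOX_EPS) or np.any(s > 1 + _BOX_EPS):
        s_box = lsq_linear(A, t, bounds=(0.0, 1.0), method="bvls").x
        # a parameter is "clamped" if the box constraint moved it
        clamped = tuple(bool(abs(b - f) > 1e-9) for b, f in zip(s_box, s))
        s = s_box
    s = np.clip(s, 0.0, 1.0)
    residual = A @ s - t
    return SurvivalEstimate(
        s=SurvivalParams(float(s[0]), float(s[1])),
        clamped=clamped,
        residual_um=(float(residual[0]), float(residual[1])),
        method=method,
    )


def estimate_survival(
    ref: ReferenceModel,
    grid: EtdrsGrid | RegionMasks | None,
    t_center: float,
    t_outer: float,
    cond_threshold: float = DEFAULT_COND_THRESHOLD,
) -> SurvivalEstimate:
    """Estimate (S_cones, S_rods) from observed regional mean thicknesses.

    Solves the exact 2×2 system; if the solution leaves [0, 1]² it is
    replaced by the box-constrained least-squares fit and flagged.  A
    near-singular system — both regions with the same composition —
    raises :class:`NonIdentifiableError`, mirroring the uniqueness
    condition of the two-region model.
    """
    A = design_matrix(ref, grid)
    return _solve_box(A, np.array([t_center, t_outer], float), cond_threshold, "linear")


def grid_design_matrix(sg: SurvivalGrid) -> np.ndarray:
    """Recover the 2×2 coefficient matrix from a survival-grid lookup table.

    Both regional-mean surfaces are exactly affine in (S_cones, S_rods)
    with zero intercept, so a least-squares affine fit over all lattice
    points reproduces the coefficients to floating point; inverting it is
    equivalent to exact bilinear inverse interpolation within any cell.
    """
    sc, sr = np.meshgrid(sg.s_values, sg.s_values, indexing="ij")
    X = np.column_stack([sc.ravel(), sr.ravel()])
    coef_c, *_ = np.linalg.lstsq(X, sg.center_mean.ravel(), rcond=None)
    coef_o, *_ = np.linalg.lstsq(X, sg.outer_mean.ravel(), rcond=None)
    return np.array([coef_c, coef_o])


def estimate_survival_from_grid(
    sg: SurvivalGrid,
    t_center: float,
    t_outer: float,
    cond_threshold: float = DEFAULT_COND_THRESHOLD,
) -> SurvivalEstimate:
    """Estimate survival by inverting the simulated survival-grid surface.

    Agrees with :func:`estimate_survival` to floating point wherever both
    are unclamped; targets outside the attainable parallelogram are
    clamped to the box with flags set.
    """
    A = grid_design_matrix(sg)
    return _solve_box(A, np.array([t_center, t_outer], float), cond_threshold, "grid_lookup")
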