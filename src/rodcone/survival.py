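"""Forward model: ONL thickness under proportional rod/cone survival.

The model assumes rod and cone somata contribute equally to ONL thickness
at each location, so thinning is linear in the survival fractions.  At an
A-scan whose expected rod proportion is P_rods, the fraction of normal
thickness remaining under survival fractions (S_cones, S_rods) is

    P_simulated = (1 - P_rods) * S_cones + P_rods * S_rods

and the simulated thickness is

    T_simulated = T_normal * P_simulated.

With full survival (1, 1) the normal thickness is reproduced exactly;
with total loss (0, 0) the layer vanishes.  Sweeping both survival
fractions over [0, 1] maps the unit square onto a parallelogram in
(center-subfield mean, outer-ring mean) thickness space — skewed, not
rectangular, because both ETDRS regions are mixtures of the two cell
classes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError
from .etdrs import CENTER, OUTER_RING, EtdrsGrid, RegionMasks, region_masks, regional_mean
from .maps import ThicknessMap
from .reference import ReferenceModel


@dataclass(frozen=True)
class SurvivalParams:
    """Global survival fractions for cones and rods, each in [0, 1]."""

    s_cones: float
    s_rods: float

    def __post_init__(self) -> None:
        for name in ("s_cones", "s_rods"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise InvalidArgumentError(f"{name} must lie in [0, 1], got {v}")

    def as_array(self) -> np.ndarray:
        return np.array([self.s_cones, self.s_rods], dtype=float)


def proportional_thickness(p_rods, s: SurvivalParams):
    """Fraction of normal ONL thickness remaining at composition ``p_rods``.

    Accepts scalars or arrays; NaNs (missing composition) propagate.
    """
    p = np.asarray(p_rods, dtype=float)
    with np.errstate(invalid="ignore"):
        if np.any((p < 0) | (p > 1)):
            raise InvalidArgumentError("p_rods must lie in [0, 1]")
    out = (1.0 - p) * s.s_cones + p * s.s_rods
    return float(out) if np.isscalar(p_rods) else out


def simulate_thickness(ref: ReferenceModel, s: SurvivalParams) -> ThicknessMap:
    """Simulated ONL thickness map under survival ``s``.

    Missing composition positions stay missing (NaN).  With s = (1, 1)
    the result equals the normal thickness bit-for-bit.
    """
    p = np.where(ref.missing_mask, np.nan, ref.p_rods.p_rods)
    if s.s_cones == 1.0 and s.s_rods == 1.0:
        values = np.where(ref.missing_mask, np.nan, ref.normal_thickness)
    else:
        values = ref.normal_thickness * proportional_thickness(p, s)
    return ThicknessMap(
        ref.geometry,
        values,
        kind="simulated",
        metadata={"s_cones": s.s_cones, "s_rods": s.s_rods},
    )


@dataclass
class SurvivalGrid:
    """Regional mean thickness over a lattice of survival pairs.

    ``center_mean[i, j]`` and ``outer_mean[i, j]`` are the ETDRS
    center-subfield and outer-ring mean thicknesses (µm) simulated with
    S_cones = s_values[i], S_rods = s_values[j].
    """

    s_values: np.ndarray
    center_mean: np.ndarray
    outer_mean: np.ndarray

    def __post_init__(self) -> None:
        self.s_values = np.asarray(self.s_values, dtype=float)
        n = len(self.s_values)
        for name in ("center_mean", "outer_mean"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n, n):
                raise InvalidArgumentError(f"{name} must be {n}×{n}")
            setattr(self, name, arr)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: s_cones, s_rods, center_mean_um, outer_mean_um."""
        sc, sr = np.meshgrid(self.s_values, self.s_values, indexing="ij")
        return pd.DataFrame(
            {
                "s_cones": sc.ravel(),
                "s_rods": sr.ravel(),
                "center_mean_um": self.center_mean.ravel(),
                "outer_mean_um": self.outer_mean.ravel(),
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SurvivalGrid":
        s_values = np.unique(df["s_cones"].to_numpy())
        n = len(s_values)
        order = np.lexsort((df["s_rods"].to_numpy(), df["s_cones"].to_numpy()))
        center = df["center_mean_um"].to_numpy()[order].reshape(n, n)
        outer = df["outer_mean_um"].to_numpy()[order].reshape(n, n)
        return cls(s_values, center, outer)


def survival_grid(
    ref: ReferenceModel,
    grid: EtdrsGrid | RegionMasks | None = None,
    step: float = 0.25,
) -> SurvivalGrid:
    """Sweep both survival fractions over {0, step, …, 1}² and record the
    simulated regional means.

    The (1, 1) lattice corner reproduces the observed normal regional
    means; the (0, 0) corner is zero thickness.
    """
    if not (0 < step <= 1):
        raise InvalidArgumentError("step must lie in (0, 1]")
    if grid is None:
        grid = EtdrsGrid()
    masks = grid if isinstance(grid, RegionMasks) else region_masks(grid, ref.geometry)
    n = int(round(1.0 / step))
    s_values = np.linspace(0.0, 1.0, n + 1)
    center = np.empty((n + 1, n + 1))
    outer = np.empty((n + 1, n + 1))
    for i, sc in enumerate(s_values):
        for j, sr in enumerate(s_values):
            t = simulate_thickness(ref, SurvivalParams(sc, sr))
            center[i, j] = regional_mean(t, masks[CENTER])
            outer[i, j] = regional_mean(t, masks[OUTER_RING])
    return SurvivalGrid(s_values, center, outer)
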