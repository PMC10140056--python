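"""Model/Results front end for survival estimation.

:class:`SurvivalModel` bundles a reference model with an ETDRS grid and
exposes the whole workflow the way statistical modelling packages do:
construct from data, call :meth:`fit` with the observed regional
thicknesses, and receive a :class:`SurvivalResults` carrying the
estimates, clamping diagnostics, residuals and a ``summary()`` table.
Forward simulation (thickness maps, survival grids, B-scan volumes) and
plotting hang off the same two objects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bscan import SegmentedVolume, simulate_volume
from .etdrs import CENTER, OUTER_RING, EtdrsGrid, RegionMasks, region_masks, regional_mean
from .inversion import (
    DEFAULT_COND_THRESHOLD,
    SurvivalEstimate,
    design_matrix,
    estimate_survival_from_grid,
    _solve_box,
)
from .maps import ThicknessMap
from .reference import ReferenceModel
from .survival import SurvivalGrid, SurvivalParams, simulate_thickness, survival_grid


class SurvivalModel:
    """Two-region linear survival model over a healthy reference eye.

    Parameters
    ----------
    reference : ReferenceModel
        Density-registered healthy eye (normal ONL thickness + rod
        proportions).
    grid : EtdrsGrid, optional
        ETDRS grid (defaults to the 1/3/6 mm convention centered on the
        reference fovea).
    cond_threshold : float
        Condition-number guard on the 2×2 design matrix; above it the
        two regions are declared non-identifiable.

    Examples
    --------
    >>> model = SurvivalModel(reference)            # doctest: +SKIP
    >>> res = model.fit(t_center=65.2, t_outer=58.1)
    >>> res.params                                   # (s_cones, s_rods)
    >>> print(res.summary())
    """

    def __init__(
        self,
        reference: ReferenceModel,
        grid: EtdrsGrid | None = None,
        cond_threshold: float = DEFAULT_COND_THRESHOLD,
    ) -> None:
        self.reference = reference
        self.grid = grid if grid is not None else EtdrsGrid()
        self.cond_threshold = cond_threshold
        self.masks: RegionMasks = region_masks(self.grid, reference.geometry)
        #: 2×2 design matrix: rows (center, outer), cols (cones, rods), µm.
        self.design = design_matrix(reference, self.masks)

    @classmethod
    def from_synthetic(cls, cfg=None, **kwargs) -> "SurvivalModel":
        """Convenience constructor over the synthetic reference eye."""
        from .synthetic import SynthConfig, synth_reference

        return cls(synth_reference(cfg if cfg is not None else SynthConfig()), **kwargs)

    # -- diagnostics ------------------------------------------------------
    @property
    def normal_means_um(self) -> tuple[float, float]:
        """Healthy (center, outer-ring) mean thicknesses implied by the design."""
        return float(self.design[0].sum()), float(self.design[1].sum())

    @property
    def condition_number(self) -> float:
        return float(np.linalg.cond(self.design))

    # -- fitting ----------------------------------------------------------
    def fit(self, t_center: float, t_outer: float, method: str = "linear") -> "SurvivalResults":
        """Fit the survival pair to observed regional mean thicknesses (µm).

        ``method`` is "linear" (exact 2×2 solve, the default) or "grid"
        (inverse lookup of a simulated survival grid — a cross-check that
        agrees with the linear solve to floating point).
        """
        if method == "linear":
            est = _solve_box(
                self.design,
                np.array([t_center, t_outer], float),
                self.cond_threshold,
                "linear",
            )
        elif method == "grid":
            est = estimate_survival_from_grid(
                self.survival_grid(), t_center, t_outer, self.cond_threshold
            )
        else:
            raise ValueError("method must be 'linear' or 'grid'")
        return SurvivalResults(self, est, (float(t_center), float(t_outer)))

    def fit_table(self, measurements: pd.DataFrame, method: str = "linear") -> pd.DataFrame:
        """Fit every row of a (patient_id, t_center_um, t_outer_um) table.

        Returns the estimate table written by the CLI: patient_id,
        s_cones, s_rods, clamped_cones, clamped_rods, residual_um.
        """
        rows = []
        for rec in measurements.itertuples(index=False):
            res = self.fit(rec.t_center_um, rec.t_outer_um, method=method)
            rows.append(
                {
                    "patient_id": rec.patient_id,
                    "s_cones": res.params.s_cones,
                    "s_rods": res.params.s_rods,
                    "clamped_cones": res.estimate.clamped[0],
                    "clamped_rods": res.estimate.clamped[1],
                    "residual_um": res.estimate.max_residual_um,
                }
            )
        return pd.DataFrame(rows)

    # -- forward simulation ----------------------------------------------
    def simulate_thickness(self, s: SurvivalParams) -> ThicknessMap:
        return simulate_thickness(self.reference, s)

    def survival_grid(self, step: float = 0.25) -> SurvivalGrid:
        return survival_grid(self.reference, self.masks, step=step)

    def regional_means(self, thickness: ThicknessMap) -> tuple[float, float]:
        return (
            regional_mean(thickness, self.masks[CENTER]),
            regional_mean(thickness, self.masks[OUTER_RING]),
        )


@dataclass
class SurvivalResults:
    """Fitted survival fractions with diagnostics.

    Attributes
    ----------
    model : SurvivalModel
    estimate : SurvivalEstimate
        Raw estimate (params, clamped flags, per-region residuals, method).
    observed_um : (float, float)
        The (center, outer) thicknesses that were fitted.
    """

    model: SurvivalModel
    estimate: SurvivalEstimate
    observed_um: tuple[float, float]

    @property
    def params(self) -> SurvivalParams:
        return self.estimate.s

    @property
    def fitted_um(self) -> tuple[float, float]:
        t = self.model.design @ self.params.as_array()
        return float(t[0]), float(t[1])

    def simulate_thickness(self) -> ThicknessMap:
        """Thickness map the fitted survival pair implies."""
        return self.model.simulate_thickness(self.params)

    def simulate_volume(self, volume: SegmentedVolume, seed: int) -> SegmentedVolume:
        """B-scan volume rendered at the fitted survival pair."""
        return simulate_volume(volume, self.model.reference, self.params, seed)

    def summary(self) -> str:
        est = self.estimate
        a = self.model.design
        lines = [
            "            Photoreceptor Survival Estimate",
            "=" * 56,
            f"Method:            {est.method}",
            f"Condition number:  {self.model.condition_number:.4g}",
            "-" * 56,
            "param     estimate   clamped",
            f"S_cones   {self.params.s_cones:8.4f}   {est.clamped[0]}",
            f"S_rods    {self.params.s_rods:8.4f}   {est.clamped[1]}",
            "-" * 56,
            "region    observed(µm)  fitted(µm)  residual(µm)  a_cones  a_rods",
        ]
        fitted = self.fitted_um
        for i, name in enumerate(("center", "outer")):
            lines.append(
                f"{name:8s}  {self.observed_um[i]:11.2f}  {fitted[i]:9.2f}"
                f"  {est.residual_um[i]:11.3g}  {a[i, 0]:7.2f}  {a[i, 1]:7.2f}"
            )
        lines.append("=" * 56)
        return "\n".join(lines)

    # -- plotting ---------------------------------------------------------
    def plot_survival_plane(self, step: float = 0.25, ax=None):
        """The survival lattice in (center, outer) thickness space with the
        observed point and the fitted estimate marked (the lookup view)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        sg = self.model.survival_grid(step)
        ax.plot(sg.center_mean.ravel(), sg.outer_mean.ravel(), "o", ms=3,
                color="0.6", label="simulated survival lattice")
        ax.plot(*self.observed_um, "rx", ms=9, label="observed")
        ax.plot(*self.fitted_um, "b+", ms=9, label="fitted")
        ax.set_xlabel("center subfield mean ONL thickness (µm)")
        ax.set_ylabel("outer ring mean ONL thickness (µm)")
        ax.legend(frameon=False)
        return ax
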