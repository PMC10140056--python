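"""En face thickness maps.

A :class:`ThicknessMap` is a 2D raster of layer thickness in micrometres
tied to a :class:`~rodcone.geometry.GridGeometry`.  Missing positions
(outside interpolation support, or propagated from a missing rod
proportion) are stored as NaN and excluded from all regional statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidArgumentError
from .geometry import GridGeometry

KINDS = ("observed", "normal", "simulated")


@dataclass
class ThicknessMap:
    geometry: GridGeometry
    values: np.ndarray  # (n_rows, n_cols) float, µm; NaN = missing
    kind: str = "observed"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.geometry.n_rows, self.geometry.n_cols):
            raise InvalidArgumentError(
                f"values shape {self.values.shape} does not match geometry "
                f"({self.geometry.n_rows}, {self.geometry.n_cols})"
            )
        if self.kind not in KINDS:
            raise InvalidArgumentError(f"kind must be one of {KINDS}, got {self.kind!r}")
        with np.errstate(invalid="ignore"):
            if np.any(self.values < 0):
                raise InvalidArgumentError("thickness values must be >= 0")

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.values)

    def mirrored(self) -> "ThicknessMap":
        """Fellow-eye view: columns reversed, geometry mirrored."""
        return ThicknessMap(
            geometry=self.geometry.mirrored(),
            values=self.values[:, ::-1].copy(),
            kind=self.kind,
            metadata=dict(self.metadata),
        )
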