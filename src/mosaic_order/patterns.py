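"""Planar point patterns on a rectangular observation window.

All coordinates are in micrometres, with the origin at the top-left corner
of the field, x increasing rightward and y increasing downward (matching
image row/column indexing). The window is half-open: a point lies in
``[0, width) x [0, height)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

#: Photoreceptor subtype labels recognised throughout the package.
SUBTYPES = ("UV", "blue", "green", "red", "rod", "other")


class DegenerateInputError(ValueError):
    """Raised when an operation receives geometrically degenerate input."""


@dataclass(frozen=True)
class Field:
    """Rectangular observation window (μm)."""

    width: float
    height: float

    def __post_init__(self) -> None:
        if not (self.width > 0 and self.height > 0):
            raise ValueError("field dimensions must be positive")

    @property
    def area(self) -> float:
        """Window area in μm² (the quantity R in Ripley's K)."""
        return self.width * self.height

    def contains(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float).reshape(-1, 2)
        return (
            (pts[:, 0] >= 0.0)
            & (pts[:, 0] < self.width)
            & (pts[:, 1] >= 0.0)
            & (pts[:, 1] < self.height)
        )


@dataclass(frozen=True)
class PointPattern:
    """Cell-centre coordinates of one photoreceptor subtype in a field."""

    points: np.ndarray
    field: Field
    subtype: str = "other"

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float).reshape(-1, 2)
        object.__setattr__(self, "points", pts)
        if self.subtype not in SUBTYPES:
            raise ValueError(f"unknown subtype {self.subtype!r}; expected one of {SUBTYPES}")
        if pts.size and not self.field.contains(pts).all():
            raise ValueError("all points must lie inside [0, width) x [0, height)")
        if pts.shape[0] > 1 and np.unique(pts, axis=0).shape[0] != pts.shape[0]:
            raise ValueError("duplicate points are not allowed in a point pattern")

    @property
    def n(self) -> int:
        return int(self.points.shape[0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"x_um": self.points[:, 0], "y_um": self.points[:, 1], "subtype": self.subtype}
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, field: Field, subtype: str | None = None) -> "PointPattern":
        df = pd.read_csv(path)
        label = subtype or (str(df["subtype"].iloc[0]) if len(df) else "other")
        return cls(df[["x_um", "y_um"]].to_numpy(dtype=float), field, label)
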