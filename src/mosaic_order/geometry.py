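"""Delaunay triangulation and window-clipped Voronoi tessellation.

The Voronoi cells are clipped to the rectangular observation window, so the
clipped cells tile the field exactly; cells touching the window boundary are
flagged so that downstream regularity statistics can restrict themselves to
interior cells, whose areas are not censored by the window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely
from scipy.spatial import Delaunay, cKDTree
from scipy.spatial import QhullError
from shapely.geometry import MultiPoint, Polygon, box

from .patterns import DegenerateInputError, Field, PointPattern

_BOUNDARY_TOL = 1e-9


@dataclass(frozen=True)
class DelaunayResult:
    """Undirected Delaunay edge set with Euclidean edge lengths (μm)."""

    edges: np.ndarray  # (m, 2) int, i < j
    lengths: np.ndarray  # (m,) float


@dataclass(frozen=True)
class VoronoiTessellation:
    """Per-point Voronoi polygons, areas (μm²) and interior flags."""

    polygons: list
    areas: np.ndarray
    is_interior: np.ndarray
    field: Field

    def interior_areas(self) -> np.ndarray:
        return self.areas[self.is_interior]


def delaunay_edges(pattern: PointPattern) -> DelaunayResult:
    """Delaunay triangulation edges; raises on degenerate input."""
    pts = pattern.points
    if pts.shape[0] < 3:
        raise DegenerateInputError("Delaunay triangulation needs at least 3 points")
    try:
        tri = Delaunay(pts)
    except QhullError as exc:  # all-collinear input
        raise DegenerateInputError("points are degenerate (collinear?)") from exc
    if tri.simplices.size == 0:
        raise DegenerateInputError("points are degenerate (collinear?)")
    pairs = np.concatenate(
        [tri.simplices[:, [0, 1]], tri.simplices[:, [1, 2]], tri.simplices[:, [0, 2]]]
    )
    pairs = np.unique(np.sort(pairs, axis=1), axis=0)
    lengths = np.linalg.norm(pts[pairs[:, 0]] - pts[pairs[:, 1]], axis=1)
    return DelaunayResult(pairs, lengths)


def voronoi_cells(pattern: PointPattern, clip: bool = True) -> VoronoiTessellation:
    """Voronoi tessellation of the pattern, clipped to the field rectangle.

    With ``clip=False`` the cells are still bounded — unbounded cells are
    truncated at an envelope one field-diagonal beyond the window — since a
    polygon area is needed for every cell; such border areas are arbitrary
    and the corresponding cells are flagged non-interior either way.
    """
    pts = pattern.points
    if pts.shape[0] < 2:
        raise DegenerateInputError("Voronoi tessellation needs at least 2 points")
    f = pattern.field
    window = box(0.0, 0.0, f.width, f.height)
    diag = float(np.hypot(f.width, f.height))
    envelope = box(-diag, -diag, f.width + diag, f.height + diag)
    raw = shapely.voronoi_polygons(MultiPoint(pts), extend_to=envelope)
    # voronoi_polygons returns cells in arbitrary order; each cell contains
    # exactly one generating point, so match by containment.
    cells: list[Polygon | None] = [None] * pts.shape[0]
    tree = cKDTree(pts)
    for poly in raw.geoms:
        c = poly.point_on_surface()
        # nearest generator to any interior point of a Voronoi cell is its seed
        _, idx = tree.query([c.x, c.y])
        cells[int(idx)] = poly
    if any(c is None for c in cells):  # pragma: no cover - defensive
        raise RuntimeError("failed to match Voronoi cells to generating points")
    if clip:
        cells = [c.intersection(window) for c in cells]
    areas = np.array([c.area for c in cells])
    boundary = window.exterior
    is_interior = np.array([c.distance(boundary) > _BOUNDARY_TOL for c in cells])
    return VoronoiTessellation(cells, areas, is_interior, f)


def min_same_type_distance(pattern: PointPattern) -> float:
    """Smallest pairwise distance between cells of the pattern's subtype."""
    if pattern.n < 2:
        raise DegenerateInputError("need at least 2 points for a pairwise distance")
    tree = cKDTree(pattern.points)
    d, _ = tree.query(pattern.points, k=2)
    return float(d[:, 1].min())


def tessellation_to_frame(tess: VoronoiTessellation) -> "pd.DataFrame":  # noqa: F821
    import pandas as pd

    return pd.DataFrame(
        {
            "cell_id": np.arange(len(tess.areas)),
            "area_um2": tess.areas,
            "is_interior": tess.is_interior,
        }
    )
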