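"""Cell-centre extraction from spot images.

The manual-correction step of a typical centroid workflow is replaced by a
fully parameterised procedure: threshold (Otsu or fixed) → morphological
opening → connected components → area filter → unweighted centroids. All
knobs live in :class:`DetectionParams` so a detection run is reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops
from skimage.morphology import disk, opening

from .patterns import Field, PointPattern
from .synthetic import SpotImage


@dataclass(frozen=True)
class DetectionParams:
    """Binarisation and component-filter settings.

    ``threshold_method`` is ``"otsu"`` (between-class-variance maximisation
    over the observed intensity levels; foreground strictly above the
    returned threshold) or ``"fixed"`` (foreground at or above
    ``fixed_threshold``). Components with pixel area outside
    ``[min_area, max_area]`` are discarded. ``connectivity`` is 2 for
    8-connected components (default) or 1 for 4-connected.
    """

    threshold_method: str = "otsu"
    fixed_threshold: float | None = None
    min_area: int = 1
    max_area: int = 10_000
    open_radius: int = 0
    connectivity: int = 2

    def __post_init__(self) -> None:
        if self.threshold_method not in ("otsu", "fixed"):
            raise ValueError("threshold_method must be 'otsu' or 'fixed'")
        if self.threshold_method == "fixed" and self.fixed_threshold is None:
            raise ValueError("fixed threshold method requires fixed_threshold")
        if self.min_area > self.max_area:
            raise ValueError("min_area must not exceed max_area")
        if self.open_radius < 0:
            raise ValueError("open_radius must be non-negative")
        if self.connectivity not in (1, 2):
            raise ValueError("connectivity must be 1 (4-conn) or 2 (8-conn)")


def _pixels(image) -> np.ndarray:
    return image.pixels if isinstance(image, SpotImage) else np.asarray(image, dtype=float)


def otsu_threshold(pixels: np.ndarray) -> float:
    """Otsu threshold computed on the exact histogram of observed levels.

    Foreground is ``pixels > threshold``. Using the observed levels as
    histogram bins (rather than a fixed 256-bin grid) makes the result
    identical to an exhaustive between-class-variance search.
    """
    values, counts = np.unique(pixels.ravel(), return_counts=True)
    if values.size < 2:
        raise ValueError("Otsu threshold undefined for a constant image")
    return float(threshold_otsu(hist=(counts, values)))


def binarize(image, params: DetectionParams) -> np.ndarray:
    """Threshold a spot image and apply morphological opening."""
    px = _pixels(image)
    if px.size == 0:
        raise ValueError("image is empty")
    if params.threshold_method == "otsu":
        mask = px > otsu_threshold(px)
    else:
        mask = px >= params.fixed_threshold
    if params.open_radius > 0:
        mask = opening(mask, disk(params.open_radius))
    return mask


def extract_centroids(
    mask: np.ndarray,
    params: DetectionParams,
    pixel_size: float,
) -> PointPattern:
    """Area-filtered connected-component centroids in μm.

    Pixel (i, j) has its centre at ((j+0.5)·pixel_size, (i+0.5)·pixel_size);
    centroids are unweighted means of component pixel centres.
    """
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    mask = np.asarray(mask, dtype=bool)
    labelled = label(mask, connectivity=params.connectivity)
    pts = []
    for region in regionprops(labelled):
        if params.min_area <= region.area <= params.max_area:
            cy, cx = region.centroid
            pts.append(((cx + 0.5) * pixel_size, (cy + 0.5) * pixel_size))
    field = Field(mask.shape[1] * pixel_size, mask.shape[0] * pixel_size)
    return PointPattern(np.asarray(pts, dtype=float).reshape(-1, 2), field)


def detect(image: SpotImage, params: DetectionParams) -> PointPattern:
    """binarize + extract_centroids in one call."""
    return extract_centroids(binarize(image, params), params, image.pixel_size)


def crop_to_count(pattern: PointPattern, target_n: int) -> PointPattern:
    """Shrink a centred window until it holds at most ``target_n`` points.

    The window is shrunk in equal-area steps of 1% preserving the aspect
    ratio; the first (largest) window containing ≤ target_n points is
    returned with coordinates re-origined to its top-left corner. Patterns
    already at or below the target are returned unchanged.
    """
    if target_n < 1:
        raise ValueError("target_n must be at least 1")
    if pattern.n <= target_n:
        return pattern
    f = pattern.field
    pts = pattern.points
    shrink = math.sqrt(0.99)
    scale = 1.0
    while True:
        scale *= shrink
        w, h = f.width * scale, f.height * scale
        x0, y0 = (f.width - w) / 2.0, (f.height - h) / 2.0
        inside = (
            (pts[:, 0] >= x0)
            & (pts[:, 0] < x0 + w)
            & (pts[:, 1] >= y0)
            & (pts[:, 1] < y0 + h)
        )
        if inside.sum() <= target_n:
            return PointPattern(pts[inside] - [x0, y0], Field(w, h), pattern.subtype)


def match_to_ground_truth(
    detected: PointPattern,
    truth: PointPattern,
    max_dist: float,
) -> float:
    """Fraction of ground-truth points greedily matched within ``max_dist``.

    Greedy nearest matching: candidate pairs within ``max_dist`` are taken
    in order of increasing distance, each point used at most once.
    """
    if truth.n == 0:
        return 1.0
    if detected.n == 0:
        return 0.0
    tree = cKDTree(detected.points)
    pairs = []
    for ti, p in enumerate(truth.points):
        for di in tree.query_ball_point(p, max_dist):
            d = np.linalg.norm(detected.points[di] - p)
            pairs.append((d, ti, di))
    pairs.sort()
    used_t: set[int] = set()
    used_d: set[int] = set()
    matched = 0
    for _, ti, di in pairs:
        if ti in used_t or di in used_d:
            continue
        used_t.add(ti)
        used_d.add(di)
        matched += 1
    return matched / truth.n
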