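"""Retinal-layer morphometry on labelled cross-section masks.

Thickness is measured along the radial (row) axis of a cross-section mask at
the high-acuity area and at a fixed lateral offset towards the dorsal and
ventral retina, in three subregions per region. Region ratios
(HAA/dorsal, HAA/ventral) are tested for exceeding 1 with an exact one-sided
binomial test. The thickness heatmap follows the classical image route:
edge-preserving Kuwahara smoothing, Gaussian blur, thresholding, then a
medial-axis skeleton whose distance-transform values give the local
half-thickness of the tissue band.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.stats import binomtest
from skimage.measure import label as cc_label
from skimage.morphology import medial_axis

from .detection import otsu_threshold
from .synthetic import LAYER_LABELS

THICKNESS_COLUMNS = [
    "timepoint",
    "retina_id",
    "region",
    "layer",
    "sub1_um",
    "sub2_um",
    "sub3_um",
    "mean_um",
]


class MissingLayerError(ValueError):
    """A required layer label is absent at a measurement column."""


def measure_thickness(
    mask: np.ndarray,
    pixel_size: float,
    haa_x: float,
    offset: float = 750.0,
    subregion_spacing: float = 25.0,
    layer_labels: dict = LAYER_LABELS,
    timepoint: str = "E18",
    retina_id: str = "retina1",
) -> pd.DataFrame:
    """Per-layer thickness at the HAA and at ±offset, three subregions each.

    At each measurement column the thickness of a layer is the pixel count
    carrying its label times ``pixel_size``; 'total' is the sum over layers.
    """
    mask = np.asarray(mask)
    ncols = mask.shape[1]
    region_x = {"HAA": haa_x, "dorsal": haa_x - offset, "ventral": haa_x + offset}
    rows = []
    for region, xc in region_x.items():
        subs: dict[str, list[float]] = {layer: [] for layer in layer_labels}
        subs["total"] = []
        for x in (xc - subregion_spacing, xc, xc + subregion_spacing):
            j = int(x / pixel_size)
            if not 0 <= j < ncols:
                raise ValueError(f"measurement position {x:g} μm outside the section")
            col = mask[:, j]
            total = 0.0
            for layer, lab in layer_labels.items():
                t = float(np.count_nonzero(col == lab)) * pixel_size
                if t == 0.0:
                    raise MissingLayerError(
                        f"layer {layer!r} missing at x={x:g} μm ({region})"
                    )
                subs[layer].append(t)
                total += t
            subs["total"].append(total)
        for layer, vals in subs.items():
            rows.append((timepoint, retina_id, region, layer, *vals, float(np.mean(vals))))
    return pd.DataFrame(rows, columns=THICKNESS_COLUMNS)


def thickness_ratios(table: pd.DataFrame) -> pd.DataFrame:
    """HAA/dorsal and HAA/ventral mean-thickness ratios per layer."""
    out = []
    for (tp, rid, layer), grp in table.groupby(["timepoint", "retina_id", "layer"], sort=False):
        means = grp.set_index("region")["mean_um"]
        for region in ("HAA", "dorsal", "ventral"):
            if region not in means.index:
                raise ValueError(f"region {region!r} missing for layer {layer!r}")
        out.append(
            (tp, rid, layer, means["HAA"] / means["dorsal"], means["HAA"] / means["ventral"])
        )
    return pd.DataFrame(
        out, columns=["timepoint", "retina_id", "layer", "ratio_dorsal", "ratio_ventral"]
    )


def binomial_ratio_test(ratios) -> float:
    """Exact one-sided binomial p for thickness ratios exceeding 1.

    p = P(X ≥ k | n, ½) with k the number of ratios above 1 and n the
    number of ratios after dropping exact ties at 1 (ties are rare in
    continuous data and are discarded with a warning).
    """
    ratios = np.asarray(ratios, dtype=float)
    if ratios.size == 0:
        raise ValueError("need at least one ratio")
    ties = ratios == 1.0
    if ties.any():
        warnings.warn(f"dropping {int(ties.sum())} tie ratio(s) equal to 1", stacklevel=2)
        ratios = ratios[~ties]
    if ratios.size == 0:
        raise ValueError("no ratios remain after dropping ties")
    k = int(np.sum(ratios > 1.0))
    return float(binomtest(k, ratios.size, 0.5, alternative="greater").pvalue)


def kuwahara_filter(image: np.ndarray, window_radius: int = 2) -> np.ndarray:
    """Edge-preserving Kuwahara smoothing.

    Each output pixel takes the mean of whichever of its four overlapping
    (radius+1)² corner subwindows has the smallest variance; edges are
    handled by reflection padding. Ties keep the first (top-left) window.
    """
    if window_radius < 1:
        raise ValueError("window_radius must be at least 1")
    img = np.asarray(image, dtype=float)
    r = window_radius
    pad = np.pad(img, r, mode="reflect")
    # window sums over all (r+1)x(r+1) windows via integral images
    ii = np.zeros((pad.shape[0] + 1, pad.shape[1] + 1))
    ii2 = np.zeros_like(ii)
    np.cumsum(np.cumsum(pad, axis=0), axis=1, out=ii[1:, 1:])
    np.cumsum(np.cumsum(pad * pad, axis=0), axis=1, out=ii2[1:, 1:])
    w = r + 1

    def win(s: np.ndarray) -> np.ndarray:
        # sum over windows with top-left at every padded position
        return s[w:, w:] - s[:-w, w:] - s[w:, :-w] + s[:-w, :-w]

    sums, sums2 = win(ii), win(ii2)  # shape (pad-r, pad-r) = (H+r, W+r)
    means = sums / w**2
    variances = sums2 / w**2 - means**2
    h, wid = img.shape
    # for output pixel (i, j): candidate windows have top-left (i, j)+q,
    # q in {0, r}² in the padded/window-sum coordinate system
    cand_mean = np.stack([means[qi : qi + h, qj : qj + wid] for qi in (0, r) for qj in (0, r)])
    cand_var = np.stack(
        [variances[qi : qi + h, qj : qj + wid] for qi in (0, r) for qj in (0, r)]
    )
    choice = np.argmin(cand_var, axis=0)
    return np.take_along_axis(cand_mean, choice[None], axis=0)[0]


@dataclass(frozen=True)
class DistanceMapResult:
    """Skeleton half-thickness map (μm) plus the pipeline intermediates."""

    half_thickness_map: np.ndarray
    filtered: np.ndarray
    blurred: np.ndarray
    mask: np.ndarray
    skeleton: np.ndarray
    pixel_size: float


def thickness_heatmap(
    image: np.ndarray,
    blur_sd: float = 2.0,
    threshold_method: str = "otsu",
    fixed_threshold: float | None = None,
    kuwahara_radius: int = 2,
    pixel_size: float = 1.0,
) -> DistanceMapResult:
    """Half-thickness map of a tissue band via medial-axis skeletonisation.

    Pipeline: Kuwahara filter → Gaussian blur → threshold → largest
    connected component → medial axis with distance transform. Skeleton
    pixels carry their Euclidean distance to the band edge (× pixel_size),
    i.e. the local half-thickness; all other pixels are zero.
    """
    img = np.asarray(image, dtype=float)
    if img.size == 0 or not np.any(img):
        raise ValueError("empty image")
    filtered = kuwahara_filter(img, kuwahara_radius)
    blurred = gaussian_filter(filtered, blur_sd) if blur_sd > 0 else filtered
    if threshold_method == "otsu":
        thr = otsu_threshold(blurred)
    elif threshold_method == "fixed":
        if fixed_threshold is None:
            raise ValueError("fixed threshold method requires fixed_threshold")
        thr = fixed_threshold
    else:
        raise ValueError("threshold_method must be 'otsu' or 'fixed'")
    mask = blurred > thr
    if not mask.any():
        raise ValueError("thresholding produced an empty mask")
    labelled = cc_label(mask, connectivity=2)
    largest = np.argmax(np.bincount(labelled.ravel())[1:]) + 1
    mask = labelled == largest
    skeleton, dist = medial_axis(mask, return_distance=True)
    half = np.where(skeleton, dist * pixel_size, 0.0)
    return DistanceMapResult(half, filtered, blurred, mask, skeleton, pixel_size)


def locate_peak_thickness(result: DistanceMapResult, tol_px: float = 0.5) -> tuple[float, float]:
    """Lateral position (column, px) and value (μm) of the thickest point.

    The half-thickness profile of a smooth band is flat near its peak at
    pixel resolution, so the peak is reported as the centroid of all
    columns whose maximum skeleton distance is within ``tol_px`` pixels of
    the global maximum.
    """
    colmax = result.half_thickness_map.max(axis=0)
    peak = colmax.max()
    if peak <= 0:
        raise ValueError("distance map has no skeleton pixels")
    near = np.nonzero(colmax >= peak - tol_px * result.pixel_size)[0]
    return float(near.mean()), float(peak)
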