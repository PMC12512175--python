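"""Spatial-order statistics for photoreceptor mosaics.

Three complementary readouts of mosaic regularity:

* **Voronoi-area variance resampling** — for a set of N Voronoi cell areas,
  the sampling distribution of the (unbiased) variance of random subsets of
  size ⌊fraction·N⌋ (default ¾N, 10,000 draws without replacement). More
  regular mosaics have tighter cell-area distributions and hence lower
  sampled variances.
* **Exclusion-zone null comparison** — the observed interior cell-area
  variance against the same statistic on matched hard-core null patterns
  (same n, same window, minimum spacing set to the smallest observed
  same-subtype distance), with an add-one-corrected one-sided Monte-Carlo
  p-value for "more ordered than the null".
* **Ripley's K** — K(d) = (R/n²)·Σ_{i≠j} I(d_ij ≤ d)·w_ij with R the window
  area, compared against pointwise envelopes from simulated CSR patterns;
  K below the envelope indicates dispersion (regularity), above indicates
  clustering. The default edge correction is the translation correction
  w_ij = R / ((W−|Δx|)(H−|Δy|)), which makes the estimator unbiased for
  πd² under CSR; ``correction="none"`` (w_ij = 1) is exact for oracle
  comparisons but biased low near the window edge.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import min_same_type_distance, voronoi_cells
from .patterns import Field, PointPattern
from .synthetic import generate_csr, generate_hardcore

DEFAULT_SAMPLE_FRACTION = 0.75
DEFAULT_N_SAMPLES = 10_000
DEFAULT_N_ITERATIONS = 100
DEFAULT_ENVELOPE_LEVEL = (2.5, 97.5)


@dataclass(frozen=True)
class VarianceDistribution:
    """Resampled Voronoi cell-area variances (μm⁴) for one mosaic."""

    samples: np.ndarray
    sample_fraction: float
    n_samples: int
    source_label: str
    mean_area: float

    def median(self, normalized: bool = False) -> float:
        med = float(np.median(self.samples))
        if normalized:
            med /= self.mean_area**2
        return med


@dataclass(frozen=True)
class RipleyCurve:
    distances: np.ndarray
    k_values: np.ndarray
    n_points: int
    field_area: float
    correction: str


@dataclass(frozen=True)
class CsrEnvelope:
    distances: np.ndarray
    mean: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    n_iterations: int
    level: tuple
    correction: str


def variance_resample(
    areas,
    fraction: float = DEFAULT_SAMPLE_FRACTION,
    n_samples: int = DEFAULT_N_SAMPLES,
    seed: int = 0,
    label: str = "random",
) -> VarianceDistribution:
    """Sampling distribution of the subset variance of cell areas.

    Each sample is the unbiased (n−1 denominator) variance of
    ⌊fraction·N⌋ areas drawn uniformly without replacement.
    """
    areas = np.asarray(areas, dtype=float)
    n = areas.size
    if n < 4:
        raise ValueError("need at least 4 areas to resample")
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    m = int(np.floor(fraction * n))
    if m < 2:
        raise ValueError("sample size after flooring is below 2")
    rng = np.random.default_rng(seed)
    if m == n:
        samples = np.full(n_samples, areas.var(ddof=1))
    else:
        # without-replacement subsets via row-wise random permutation
        idx = np.argsort(rng.random((n_samples, n)), axis=1)[:, :m]
        samples = areas[idx].var(axis=1, ddof=1)
    return VarianceDistribution(samples, fraction, n_samples, label, float(areas.mean()))


def matched_null_pattern(
    pattern: PointPattern, seed: int, max_attempts: int = 1_000_000
) -> PointPattern:
    """Exclusion-zone null: same n and window, hard core at the smallest
    observed same-subtype spacing."""
    if pattern.n < 2:
        raise ValueError("need at least 2 points to build a matched null")
    r_min = min_same_type_distance(pattern)
    return generate_hardcore(
        pattern.n, r_min, pattern.field, seed, max_attempts=max_attempts, subtype=pattern.subtype
    )


def variance_vs_null(
    pattern: PointPattern,
    n_null: int = 99,
    seed: int = 0,
    interior_only: bool = True,
    max_attempts: int = 1_000_000,
) -> tuple[float, np.ndarray, float]:
    """Observed Voronoi-area variance against matched exclusion-zone nulls.

    Returns ``(observed_variance, null_variances, empirical_p)`` with
    ``empirical_p = (1 + #{null ≤ observed}) / (n_null + 1)``, one-sided for
    "more ordered (lower variance) than the null".
    """
    if n_null < 19:
        raise ValueError("n_null must be at least 19 for a p-value at the 5% level")

    def _variance(p: PointPattern) -> float:
        tess = voronoi_cells(p, clip=True)
        areas = tess.interior_areas() if interior_only else tess.areas
        if areas.size < 2:
            raise ValueError("too few Voronoi cells to compute a variance")
        return float(np.var(areas, ddof=1))

    observed = _variance(pattern)
    child = np.random.SeedSequence(seed).generate_state(n_null, dtype=np.uint64) % (2**31)
    null_vars = np.array(
        [_variance(matched_null_pattern(pattern, int(s), max_attempts)) for s in child]
    )
    p = (1.0 + np.sum(null_vars <= observed)) / (n_null + 1.0)
    return observed, null_vars, float(p)


def ripley_k(
    pattern: PointPattern,
    distances,
    correction: str = "translation",
) -> RipleyCurve:
    """Ripley's K(d) = (R/n²)·Σ_{i≠j} I(d_ij ≤ d)·w_ij over a distance grid."""
    if pattern.n < 2:
        raise ValueError("Ripley's K needs at least 2 points")
    distances = np.asarray(distances, dtype=float)
    if distances.size == 0 or np.any(distances <= 0) or np.any(np.diff(distances) <= 0):
        raise ValueError("distances must be positive and strictly increasing")
    if correction not in ("none", "translation"):
        raise ValueError("correction must be 'none' or 'translation'")
    f = pattern.field
    if correction == "translation" and distances.max() >= min(f.width, f.height):
        raise ValueError(
            "translation weights are undefined for distances >= min(field dimensions)"
        )
    pts = pattern.points
    n = pattern.n
    area = f.area
    dx = np.abs(pts[:, 0, None] - pts[None, :, 0])
    dy = np.abs(pts[:, 1, None] - pts[None, :, 1])
    iu = np.triu_indices(n, k=1)
    dxu, dyu = dx[iu], dy[iu]
    d_pairs = np.hypot(dxu, dyu)
    if correction == "translation":
        w = area / ((f.width - dxu) * (f.height - dyu))
    else:
        w = np.ones_like(d_pairs)
    order = np.argsort(d_pairs)
    d_sorted = d_pairs[order]
    cumw = np.concatenate([[0.0], np.cumsum(w[order])])
    idx = np.searchsorted(d_sorted, distances, side="right")
    k = (area / n**2) * 2.0 * cumw[idx]
    return RipleyCurve(distances, k, n, area, correction)


def csr_envelope(
    n: int,
    field: Field,
    distances,
    n_iterations: int = DEFAULT_N_ITERATIONS,
    level: tuple = DEFAULT_ENVELOPE_LEVEL,
    seed: int = 0,
    correction: str = "translation",
) -> CsrEnvelope:
    """Pointwise mean and quantile envelope of K under CSR with matched n."""
    if n < 2:
        raise ValueError("need at least 2 points")
    if n_iterations < 2:
        raise ValueError("need at least 2 envelope iterations")
    lo, hi = level
    if not 0 <= lo < hi <= 100:
        raise ValueError("level must be an increasing percentile pair in [0, 100]")
    distances = np.asarray(distances, dtype=float)
    child = np.random.SeedSequence(seed).generate_state(n_iterations, dtype=np.uint64) % (2**31)
    ks = np.empty((n_iterations, distances.size))
    for i, s in enumerate(child):
        pat = generate_csr(n, field, int(s))
        ks[i] = ripley_k(pat, distances, correction).k_values
    return CsrEnvelope(
        distances,
        ks.mean(axis=0),
        np.percentile(ks, lo, axis=0),
        np.percentile(ks, hi, axis=0),
        n_iterations,
        (lo, hi),
        correction,
    )


def classify_dispersion(
    curve: RipleyCurve,
    envelope: CsrEnvelope,
    d_range: tuple,
) -> tuple[list, str]:
    """Per-distance dispersion labels plus a majority call within d_range.

    Below the lower envelope → "dispersed" (more ordered than CSR), above
    the upper → "clustered", inside → "random". Majority ties resolve to
    "random" (the conservative call).
    """
    if curve.distances.shape != envelope.distances.shape or not np.allclose(
        curve.distances, envelope.distances
    ):
        raise ValueError("curve and envelope must share the same distance grid")
    labels = np.where(
        curve.k_values < envelope.lower,
        "dispersed",
        np.where(curve.k_values > envelope.upper, "clustered", "random"),
    )
    lo, hi = d_range
    sel = (curve.distances >= lo) & (curve.distances <= hi)
    if not sel.any():
        raise ValueError("d_range contains no grid distances")
    votes = {lab: int(np.sum(labels[sel] == lab)) for lab in ("dispersed", "random", "clustered")}
    best = max(votes.values())
    winners = [lab for lab, v in votes.items() if v == best]
    overall = winners[0] if len(winners) == 1 else "random"
    return labels.tolist(), overall


def rank_regularity(
    distributions: list,
    areas_normalized: bool = False,
) -> list:
    """Labels ordered from most to least regular (ascending median variance).

    With ``areas_normalized=True`` each median is divided by the squared
    mean cell area of its source mosaic, making mosaics of different density
    comparable. Ties keep input order (stable sort).
    """
    if len(distributions) < 1:
        raise ValueError("need at least one distribution")
    meds = np.array([d.median(normalized=areas_normalized) for d in distributions])
    order = np.argsort(meds, kind="stable")
    return [distributions[i].source_label for i in order]
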