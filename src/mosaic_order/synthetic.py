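"""Synthetic ground-truth generators.

Everything downstream (detection, tessellation, spatial order, morphometry,
composition) is exercised on data produced here, so each generator carries an
explicit ground truth: point coordinates for rendered images, analytic layer
thickness profiles for cross-sections, and the multinomial composition used
to draw opsin counts.

Point-pattern models
--------------------
``generate_csr``
    Homogeneous binomial process (n i.i.d. uniform points) — the CSR null.
``generate_hardcore``
    Simple sequential inhibition (RSA): uniform proposals, rejected when
    closer than ``r_min`` to an accepted point. This is the exclusion-zone
    null used to mimic photoreceptor minimum spacing. Note that RSA
    saturates near a disk area fraction of ~0.547, well below the
    triangular-lattice optimum, so sufficiently dense/regular target
    patterns have no feasible matched null (an error is raised).
``generate_jittered_lattice``
    Triangular lattice with isotropic Gaussian positional noise; the jitter
    standard deviation is a single scalar controlling mosaic regularity.
``generate_thomas``
    Thomas cluster process (Poisson parents, Gaussian offspring) — the
    clustered reference pattern for Ripley's K classification.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .patterns import Field, PointPattern


class PackingInfeasibleError(RuntimeError):
    """Sequential inhibition could not place the requested points."""


# ---------------------------------------------------------------------------
# point patterns
# ---------------------------------------------------------------------------

def generate_csr(n: int, field: Field, seed: int, subtype: str = "other") -> PointPattern:
    """n points of complete spatial randomness (uniform, independent)."""
    if n < 0:
        raise ValueError("n must be non-negative")
    rng = np.random.default_rng(seed)
    pts = rng.uniform((0.0, 0.0), (field.width, field.height), size=(n, 2))
    return PointPattern(pts, field, subtype)


def generate_hardcore(
    n: int,
    r_min: float,
    field: Field,
    seed: int,
    max_attempts: int = 1_000_000,
    subtype: str = "other",
) -> PointPattern:
    """Hard-core pattern by simple sequential inhibition.

    Uniform proposals are accepted only when at least ``r_min`` away from
    every previously accepted point. Raises :class:`PackingInfeasibleError`
    when ``n`` points cannot be placed within ``max_attempts`` proposals.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    if r_min < 0:
        raise ValueError("r_min must be non-negative")
    rng = np.random.default_rng(seed)
    if r_min == 0.0:
        pts = rng.uniform((0.0, 0.0), (field.width, field.height), size=(n, 2))
        return PointPattern(pts, field, subtype)

    # coarse grid so each proposal only checks the 9 neighbouring bins
    cell = max(r_min, 1e-9)
    nx = max(1, int(math.ceil(field.width / cell)))
    ny = max(1, int(math.ceil(field.height / cell)))
    grid: dict[tuple[int, int], list[int]] = {}
    accepted = np.empty((n, 2), dtype=float)
    placed = 0
    attempts = 0
    r2 = r_min * r_min
    while placed < n:
        if attempts >= max_attempts:
            raise PackingInfeasibleError(
                f"placed only {placed}/{n} points with r_min={r_min:g} "
                f"after {max_attempts} proposals; packing too dense for "
                "sequential inhibition"
            )
        attempts += 1
        p = rng.uniform((0.0, 0.0), (field.width, field.height))
        gx, gy = min(int(p[0] / cell), nx - 1), min(int(p[1] / cell), ny - 1)
        ok = True
        for ix in range(max(0, gx - 1), min(nx, gx + 2)):
            for iy in range(max(0, gy - 1), min(ny, gy + 2)):
                for k in grid.get((ix, iy), ()):
                    d = accepted[k] - p
                    if d[0] * d[0] + d[1] * d[1] < r2:
                        ok = False
                        break
                if not ok:
                    break
            if not ok:
                break
        if ok:
            accepted[placed] = p
            grid.setdefault((gx, gy), []).append(placed)
            placed += 1
    return PointPattern(accepted[:n], field, subtype)


def generate_jittered_lattice(
    spacing: float,
    jitter_sd: float,
    field: Field,
    seed: int,
    subtype: str = "other",
) -> PointPattern:
    """Triangular lattice with Gaussian positional jitter.

    The unjittered lattice has nearest-neighbour distance ``spacing``; each
    point is then displaced by isotropic Gaussian noise of standard
    deviation ``jitter_sd`` per axis. Points jittered outside the field are
    dropped.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if jitter_sd < 0:
        raise ValueError("jitter_sd must be non-negative")
    if spacing > min(field.width, field.height):
        raise ValueError("spacing exceeds the field dimensions")
    rng = np.random.default_rng(seed)
    row_h = spacing * math.sqrt(3.0) / 2.0
    margin = spacing + 5.0 * jitter_sd
    ys = np.arange(-margin, field.height + margin, row_h)
    pts = []
    for i, y in enumerate(ys):
        xoff = 0.5 * spacing if i % 2 else 0.0
        xs = np.arange(-margin + xoff, field.width + margin, spacing)
        pts.append(np.column_stack([xs, np.full_like(xs, y)]))
    lattice = np.concatenate(pts, axis=0)
    if jitter_sd > 0:
        lattice = lattice + rng.normal(0.0, jitter_sd, size=lattice.shape)
    keep = field.contains(lattice)
    return PointPattern(lattice[keep], field, subtype)


def generate_thomas(
    parent_intensity: float,
    mean_offspring: float,
    offspring_sd: float,
    field: Field,
    seed: int,
    subtype: str = "other",
) -> PointPattern:
    """Thomas cluster process: Poisson parents, Gaussian offspring.

    ``parent_intensity`` is the expected number of parents per μm²; parents
    are drawn on the field expanded by 4 offspring standard deviations to
    avoid edge bias, and offspring falling outside the field are dropped.
    """
    if parent_intensity <= 0 or mean_offspring <= 0 or offspring_sd <= 0:
        raise ValueError("Thomas process parameters must be positive")
    rng = np.random.default_rng(seed)
    m = 4.0 * offspring_sd
    w, h = field.width + 2 * m, field.height + 2 * m
    n_parents = rng.poisson(parent_intensity * w * h)
    parents = rng.uniform((-m, -m), (field.width + m, field.height + m), size=(n_parents, 2))
    counts = rng.poisson(mean_offspring, size=n_parents)
    centres = np.repeat(parents, counts, axis=0)
    pts = centres + rng.normal(0.0, offspring_sd, size=centres.shape)
    pts = pts[field.contains(pts)]
    pts = np.unique(pts, axis=0)
    return PointPattern(pts, field, subtype)


# ---------------------------------------------------------------------------
# spot images
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpotImage:
    """2D intensity image with optional ground-truth cell centres."""

    pixels: np.ndarray
    pixel_size: float
    ground_truth: PointPattern | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        object.__setattr__(self, "pixels", px)
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.ground_truth is not None:
            f = self.ground_truth.field
            ny, nx = px.shape
            if not (
                math.isclose(nx * self.pixel_size, f.width, rel_tol=1e-9)
                and math.isclose(ny * self.pixel_size, f.height, rel_tol=1e-9)
            ):
                raise ValueError("image extent does not match the ground-truth field")


def render_spots(
    pattern: PointPattern,
    spot_sd: float,
    amplitude: float,
    background: float,
    noise_sd: float,
    pixel_size: float,
    seed: int,
) -> SpotImage:
    """Render a pattern as a sum of isotropic 2D Gaussians plus noise.

    The image is ``background + Σ amplitude·exp(-r²/(2·spot_sd²))`` sampled
    at pixel centres, plus i.i.d. Gaussian noise, clipped at zero.
    """
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    if spot_sd <= 0:
        raise ValueError("spot_sd must be positive")
    f = pattern.field
    nx = int(round(f.width / pixel_size))
    ny = int(round(f.height / pixel_size))
    if not (
        math.isclose(nx * pixel_size, f.width, rel_tol=1e-9)
        and math.isclose(ny * pixel_size, f.height, rel_tol=1e-9)
    ):
        raise ValueError("field dimensions must be integer multiples of pixel_size")
    img = np.full((ny, nx), float(background))
    halo = int(math.ceil(5.0 * spot_sd / pixel_size))
    sd_px = spot_sd / pixel_size
    for x_um, y_um in pattern.points:
        # pixel (i, j) has its centre at ((j+0.5)·p, (i+0.5)·p)
        cx = x_um / pixel_size - 0.5
        cy = y_um / pixel_size - 0.5
        j0, j1 = max(0, int(cx) - halo), min(nx, int(cx) + halo + 2)
        i0, i1 = max(0, int(cy) - halo), min(ny, int(cy) + halo + 2)
        if j0 >= j1 or i0 >= i1:
            continue
        jj = np.arange(j0, j1)
        ii = np.arange(i0, i1)
        gx = np.exp(-((jj - cx) ** 2) / (2.0 * sd_px**2))
        gy = np.exp(-((ii - cy) ** 2) / (2.0 * sd_px**2))
        img[i0:i1, j0:j1] += amplitude * np.outer(gy, gx)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    return SpotImage(np.clip(img, 0.0, None), pixel_size, pattern)


# ---------------------------------------------------------------------------
# opsin count tables
# ---------------------------------------------------------------------------

def _normalized(comp: dict) -> dict:
    total = sum(comp.values())
    return {k: v / total for k, v in comp.items()}


#: Cone compositions reported for the rod-free zone, used as generator
#: defaults for the two study timepoints (fractions of the total cone
#: count). The published percentages carry two-decimal rounding, so they
#: are renormalised here to sum exactly to 1.
E18_COMPOSITION = _normalized({"UV": 0.1001, "blue": 0.1429, "green": 0.2854, "red": 0.4715})
ADULT_COMPOSITION = _normalized({"UV": 0.0707, "blue": 0.1153, "green": 0.1829, "red": 0.6312})

REGIONS = ("RFZ", "dorsal", "ventral", "nasal", "temporal")


@dataclass(frozen=True)
class SyntheticCountSpec:
    """Study design for a synthetic opsin-count cohort.

    ``composition`` gives the cone-subtype proportions (must sum to 1);
    ``mean_total_density`` is the expected total cone count per 10,000 μm²;
    ``dispersion`` is the between-animal coefficient of variation of that
    density (lognormal animal effects); ``rod_to_cone_ratio`` sets the rod
    density relative to cones everywhere except ``rod_free_regions``.
    """

    composition: dict = dc_field(default_factory=lambda: dict(E18_COMPOSITION))
    mean_total_density: float = 250.0
    dispersion: float = 0.1
    n_animals: int = 3
    regions: tuple = REGIONS
    n_subregions: int = 3
    subregion_area_range: tuple = (9_000.0, 16_000.0)
    rod_to_cone_ratio: float = 0.5
    rod_free_regions: tuple = ("RFZ",)
    region_density_scale: dict = dc_field(default_factory=dict)
    timepoint: str = "E18"

    def __post_init__(self) -> None:
        total = sum(self.composition.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError("composition proportions must sum to 1")
        if any(p < 0 or p > 1 for p in self.composition.values()):
            raise ValueError("composition proportions must lie in [0, 1]")
        lo, hi = self.subregion_area_range
        if not (0 < lo <= hi):
            raise ValueError("invalid subregion area range")
        if self.dispersion < 0:
            raise ValueError("dispersion must be non-negative")


def generate_opsin_counts(spec: SyntheticCountSpec, seed: int) -> pd.DataFrame:
    """Draw an opsin count table (one row per animal/region/subtype/subregion).

    Per animal a lognormal density factor with unit mean and CV
    ``spec.dispersion`` is drawn; per subregion the area is uniform over
    ``subregion_area_range``, the total cone count is Poisson at the
    perturbed density, and subtype counts are multinomial at
    ``spec.composition``. Rod counts are Poisson at ``rod_to_cone_ratio``
    times the cone density, zero in rod-free regions.
    """
    rng = np.random.default_rng(seed)
    subtypes = list(spec.composition)
    probs = np.array([spec.composition[s] for s in subtypes])
    sigma = math.sqrt(math.log(1.0 + spec.dispersion**2)) if spec.dispersion > 0 else 0.0
    rows = []
    for a in range(1, spec.n_animals + 1):
        animal = f"animal{a}"
        factor = math.exp(rng.normal(-0.5 * sigma**2, sigma)) if sigma > 0 else 1.0
        for region in spec.regions:
            scale = spec.region_density_scale.get(region, 1.0)
            dens = spec.mean_total_density * factor * scale  # per 10,000 μm²
            for sub in range(1, spec.n_subregions + 1):
                area = rng.uniform(*spec.subregion_area_range)
                expected = dens * area / 10_000.0
                total = int(rng.poisson(expected))
                counts = rng.multinomial(total, probs)
                for s, c in zip(subtypes, counts):
                    rows.append((animal, spec.timepoint, region, s, sub, area, int(c)))
                rod = 0
                if region not in spec.rod_free_regions and spec.rod_to_cone_ratio > 0:
                    rod = int(rng.poisson(spec.rod_to_cone_ratio * expected))
                rows.append((animal, spec.timepoint, region, "rod", sub, area, rod))
    return pd.DataFrame(
        rows,
        columns=["animal_id", "timepoint", "region", "subtype", "subregion_index", "area_um2", "count"],
    )


# ---------------------------------------------------------------------------
# cross-sections
# ---------------------------------------------------------------------------

LAYERS = ("GCL", "IPL", "INL", "ONL")
DEFAULT_BASELINES = {"GCL": 30.0, "IPL": 50.0, "INL": 60.0, "ONL": 40.0}


@dataclass(frozen=True)
class CrossSectionSpec:
    """Geometry of a synthetic dorsal–HAA–ventral cross-section.

    Each layer band has thickness ``baseline·(1 + amplitude·g(x))`` where
    ``g`` is a Gaussian bump of width ``haa_sigma`` centred at
    ``haa_position`` along the section.
    """

    layer_order: tuple = LAYERS
    baseline_thickness: dict = dc_field(default_factory=lambda: dict(DEFAULT_BASELINES))
    haa_position: float = 1000.0
    haa_amplitude: dict = dc_field(default_factory=lambda: {l: 0.0 for l in LAYERS})
    haa_sigma: float = 300.0
    section_length: float = 2000.0
    neighbor_offset: float = 750.0
    subregion_spacing: float = 25.0

    def __post_init__(self) -> None:
        for layer in self.layer_order:
            if self.baseline_thickness.get(layer, 0.0) <= 0:
                raise ValueError(f"baseline thickness for {layer} must be positive")
        if not 0 <= self.haa_position <= self.section_length:
            raise ValueError("haa_position must lie within the section")
        if self.haa_sigma <= 0:
            raise ValueError("haa_sigma must be positive")

    def bump(self, x: float) -> float:
        return math.exp(-((x - self.haa_position) ** 2) / (2.0 * self.haa_sigma**2))

    def thickness(self, layer: str, x: float) -> float:
        amp = self.haa_amplitude.get(layer, 0.0)
        t = self.baseline_thickness[layer] * (1.0 + amp * self.bump(x))
        if t <= 0:
            raise ValueError(f"amplitude for {layer} yields non-positive thickness")
        return t


#: Integer labels used in rasterised cross-section masks (0 = background).
LAYER_LABELS = {layer: i + 1 for i, layer in enumerate(LAYERS)}


def generate_cross_section(
    spec: CrossSectionSpec,
    pixel_size: float,
    seed: int = 0,
    timepoint: str = "E18",
    retina_id: str = "retina1",
    top_margin: float = 20.0,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Rasterise a cross-section mask and return its analytic thickness table.

    Returns ``(mask, table)``: an integer-labelled image (rows = radial
    axis, columns = lateral position along the section) and the ground-truth
    thickness table evaluated analytically at the HAA and at
    ``±neighbor_offset``, in the same layout as measured tables. ``seed`` is
    accepted for interface uniformity; the section itself is deterministic.
    """
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    ncols = int(round(spec.section_length / pixel_size))
    peak_total = sum(
        spec.baseline_thickness[l] * (1.0 + max(spec.haa_amplitude.get(l, 0.0), 0.0))
        for l in spec.layer_order
    )
    nrows = int(math.ceil((peak_total + 2 * top_margin) / pixel_size))
    mask = np.zeros((nrows, ncols), dtype=np.uint8)
    top_px = top_margin / pixel_size
    for j in range(ncols):
        x = (j + 0.5) * pixel_size
        cum = top_px
        for layer in spec.layer_order:
            t_px = spec.thickness(layer, x) / pixel_size
            r0 = int(round(cum))
            r1 = int(round(cum + t_px))
            mask[r0:r1, j] = LAYER_LABELS[layer]
            cum += t_px

    rows = []
    region_x = {
        "HAA": spec.haa_position,
        "dorsal": spec.haa_position - spec.neighbor_offset,
        "ventral": spec.haa_position + spec.neighbor_offset,
    }
    for region, xc in region_x.items():
        xs = [xc - spec.subregion_spacing, xc, xc + spec.subregion_spacing]
        per_layer = {l: [spec.thickness(l, x) for x in xs] for l in spec.layer_order}
        per_layer["total"] = [sum(per_layer[l][k] for l in spec.layer_order) for k in range(3)]
        for layer, vals in per_layer.items():
            rows.append((timepoint, retina_id, region, layer, *vals, float(np.mean(vals))))
    table = pd.DataFrame(
        rows,
        columns=["timepoint", "retina_id", "region", "layer", "sub1_um", "sub2_um", "sub3_um", "mean_um"],
    )
    return mask, table
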