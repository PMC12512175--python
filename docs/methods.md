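# Methods

This note documents the models behind `mosaic_order`, the parameter
defaults and why they were chosen, what the synthetic generators do and do
not emulate, and the numerical decisions a maintainer should know about.

## Coordinate and window conventions

All coordinates are micrometres with the origin at the top-left corner of
the observation window, x rightward and y downward, matching image
row/column indexing. Windows are half-open, `[0, W) × [0, H)`. Pixel
`(i, j)` of an image with pixel size `p` has its centre at
`((j+0.5)·p, (i+0.5)·p)`. Duplicate points are rejected at pattern
construction because they produce degenerate tessellations.

## Point-pattern models

- **CSR** — n i.i.d. uniform points (binomial process); the null for all
  order statistics, with E[K(d)] = πd².
- **Hard core** — simple sequential inhibition (random sequential
  adsorption): uniform proposals, rejected within `r_min` of an accepted
  point, with a `max_attempts` cap. SSI saturates near a disk area
  fraction of 0.547, i.e. at a minimum spacing of ≈0.78× the spacing of a
  triangular lattice of equal density; denser requests raise
  `PackingInfeasibleError`. This matters for the exclusion-zone null
  (below).
- **Jittered triangular lattice** — the regularity ground truth. A
  triangular lattice with nearest-neighbour spacing `s` has hexagonal
  Voronoi cells of area (√3/2)s²; each point is displaced by isotropic
  Gaussian noise of standard deviation `jitter_sd` per axis. A single
  scalar thus orders mosaics from crystalline to nearly random, mirroring
  the observed subtype ordering of real cone mosaics.
- **Thomas process** — Poisson parents (drawn on the window expanded by
  4 offspring SDs to avoid edge bias), Poisson-many Gaussian offspring;
  the clustered reference for Ripley classification. Defaults in the
  calibration runs: 20 parents per 500×500 μm window, 10 offspring per
  parent, offspring SD 10 μm.

## Spatial-order statistics

**Variance resampling.** For N cell areas, each of `n_samples = 10,000`
draws takes ⌊¾N⌋ areas uniformly *without replacement* (each sample is a
genuine subsample of observed cells) and records the unbiased
(n−1-denominator) variance. Only *interior* Voronoi cells enter by
default: border cells are censored by the window and have no natural
area. Cells are clipped to the window (clipped areas tile it exactly;
verified to 1e-6 relative), and a cell is interior when its polygon does
not touch the window boundary.

**Exclusion-zone null.** The null for "is this mosaic more ordered than
random?" is a hard-core pattern with the same n and window, with `r_min`
set to the smallest observed same-subtype distance. The comparison is an
add-one-corrected one-sided Monte-Carlo p-value over `n_null = 99` nulls;
calibration under the null is uniform-to-conservative (verified by a
one-sided KS check). Two caveats are inherent to this design: (i) for
extremely regular patterns (lattice jitter ≲0.05×spacing) the observed
minimum spacing exceeds the SSI saturation limit and no null can be
generated — the comparison raises rather than silently degrading; (ii)
just below saturation, SSI is slow (rejection-dominated). Real mosaics,
whose minimum spacing sits well below the mean spacing, are unaffected.

**Ripley's K.** K(d) = (R/n²)·Σ_{i≠j} 1(d_ij ≤ d)·w_ij. The default edge
correction is the translation correction
w_ij = R/((W−|Δx|)(H−|Δy|)), which is exactly unbiased for πd² under CSR
for d < min(W, H) (verified to <3% over 200 simulations at n = 500);
`correction="none"` (w_ij = 1) exists for brute-force comparison and is
biased low near the window edge. Envelopes are pointwise 2.5/97.5
percentiles (a config-exposed default; the confidence level of the
original procedure is unstated) over 100 CSR simulations with matched n.
Classification is per-distance (below/inside/above the envelope →
dispersed/random/clustered) with a majority vote over the distance range
of interest; majority ties resolve to "random".

**Ranking.** Mosaics are ordered by median resampled variance; with
`areas_normalized=True` medians are divided by the squared mean cell area,
making the ranking invariant to uniform rescaling (verified). Ties keep
input order.

## Spot rendering and detection

Images are `background + Σ amplitude·exp(−r²/(2·spot_sd²))` at pixel
centres plus i.i.d. Gaussian noise, clipped at zero. Poisson noise is
deliberately omitted: the downstream pipeline only needs binarisable
contrast. Detection thresholds with Otsu computed on the exact histogram
of observed intensity levels (identical to exhaustive between-class
variance search; foreground strictly above the threshold) or a fixed
threshold (foreground at or above it), then opens, labels 8-connected
components (switchable to 4), filters by area, and takes unweighted
centroids. Defaults used in the round-trip checks: spot SD 2 μm, 1 μm
pixels, amplitude 100 over background 10, noise SD 10 (SNR 10), area
filter [5, 500] px².

Round-trip fixtures keep ground-truth points ≥5 spot SDs from the image
border and ≥12 μm apart: blobs clipped by the border or merged across the
exclusion distance bias the centroid, which is a property of the scene
rather than the detector. Under these conditions ≥99% of centres are
recovered within 1 px (typically 100%).

`crop_to_count` shrinks a centred window in 1% equal-area steps
(preserving aspect ratio) until at most the target number of points
remains — a deterministic stand-in for "crop until images hold comparable
cell counts".

## Morphometry

Synthetic cross-sections stack four layer bands (defaults, μm: GCL 30,
IPL 50, INL 60, ONL 40 — late-embryonic scale) whose thickness profiles
are `baseline·(1 + amplitude·exp(−(x−x_HAA)²/(2σ²)))` with σ = 300 μm over
a 2,000 μm section. Thickness is measured as the labelled pixel count
along a column; quantisation is ±1 px per boundary, so recovery checks
rasterise at 0.5 μm/px to keep quantisation well inside the 2% tolerance
(at 1 μm/px a 30 μm layer carries up to ~3% rounding error).

Ratios HAA/dorsal and HAA/ventral are tested with the exact binomial tail
P(X ≥ k | n, ½); ties at exactly 1 are dropped with a warning (they do not
occur in continuous data).

The heatmap pipeline is Kuwahara (radius 2) → Gaussian blur (SD 2 px) →
threshold → largest component → medial axis with Euclidean distance
transform; skeleton pixels carry the local half-thickness in μm.
"Skeletonisation" here means the medial axis — the standard route from a
thresholded band to a centre-to-edge distance map. The Kuwahara filter
assigns each pixel the mean of the least-variance of its four overlapping
(radius+1)² corner windows (reflection padding, ties to the top-left
window); it is idempotent on piecewise-constant regions and preserves
step edges exactly, which is why it precedes the blur. Because a smooth
band's half-thickness profile is flat near its peak at pixel resolution,
the peak is located as the centroid of all columns within half a pixel of
the maximum; on synthetic bumps this lands within ~1 px of the true HAA
position.

## Composition

Densities are count/area × 10,000 per subregion, averaged over the three
subregions of a region. Composition percentages divide each cone
subtype's density by the sum of the four cone densities — rods are
excluded from the denominator because the RFZ contains none, making the
cone total the only denominator comparable across regions. Cross-animal
summaries report mean and sample SD. Welch's t-test (Satterthwaite df)
handles unequal variances; with 2–3 animals per group it is fragile, so a
permutation test on the mean difference is provided as an alternative
(off by default). Outlier-animal exclusion is an explicit id list, never
automatic.

The synthetic cohort draws a lognormal per-animal density factor (unit
mean, CV = `dispersion`, default 0.1), uniform subregion areas in
[9,000, 16,000] μm², Poisson total cone counts at 250 per 10,000 μm²
(a plausible late-embryonic central-retina cone density; compositions are
insensitive to it), multinomial subtype splits at the published RFZ
compositions (renormalised to sum exactly to 1 — the printed two-decimal
percentages sum to 99.99/100.01), and Poisson rod counts at half the cone
density outside the rod-free region.

## What the synthetic data does and does not emulate

The generators reproduce the *statistical structure* the analyses consume:
point patterns of controllable regularity, spot images with known centres,
count tables with known composition and between-animal dispersion, and
sections with a known thickness profile. They do not emulate optics beyond
a Gaussian spot, hybridisation chemistry, double-cone morphology (red
signal is treated as one class), tissue curvature (patterns are planar),
or 3D structure. Passing tests therefore demonstrate the correctness and
calibration of the statistics, not robustness to every artefact of real
imaging — in particular, real data needs the detection parameters tuned
per channel, and red-opsin mosaics mix two cell classes whose pooled
pattern is legitimately less ordered.

## Problem sizes and reproducibility

Default analysis sizes — mosaics of ~450–750 points, 10,000 resamples,
100-iteration envelopes, 99 nulls, 200-replicate CSR calibrations,
20-seed classification/recovery sweeps — were chosen so every
distributional claim is estimated with comfortable Monte-Carlo margin
while the full suite runs in minutes on a single core. Every stochastic
step takes an explicit seed; the pipeline splits one top-level seed into
per-stage seeds via `SeedSequence` keyed on the stage name, so any stage
can be re-run independently and a rerun with the same config is
bit-identical.
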