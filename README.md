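# mosaic-order

Quantitative analyses for characterising the chick retinal **high-acuity
area (HAA)** — the bird analogue of the primate fovea, a rod-free central
region with high retinal-ganglion-cell density — built as a tested,
seed-reproducible pipeline that runs end-to-end on synthetic data with
known ground truth.

The package is aimed at retinal biologists and image analysts who quantify
photoreceptor mosaics from single-molecule FISH (HCR) whole mounts and
layer morphometry from cross-sections, and who want the statistics behind
those figures to be reproducible and testable.

## What it computes

**Photoreceptor-mosaic spatial order.** Cell centres of each opsin subtype
(UV, blue, green, red, rhodopsin) form a planar point pattern in a
rectangular window. Order is quantified three ways:

- *Voronoi-area variance resampling* — from the N Voronoi cell areas of a
  mosaic, 10,000 random subsets of size ¾N are drawn without replacement
  and the unbiased variance of each subset recorded; regular mosaics give
  tight, low-variance distributions. Mosaics are ranked by median sampled
  variance (optionally normalised by squared mean cell area to compare
  different densities).
- *Exclusion-zone null comparison* — the observed interior Voronoi-area
  variance is compared against matched hard-core null patterns (same n,
  same window, minimum spacing set to the smallest observed same-subtype
  distance, placed by simple sequential inhibition), with an
  add-one-corrected one-sided Monte-Carlo p-value:
  p = (1 + #{var_null ≤ var_obs}) / (n_null + 1).
- *Ripley's K* — K(d) = (R/n²)·Σ_{i≠j} 1(d_ij ≤ d)·w_ij with R the window
  area and translation edge-correction weights
  w_ij = R/((W−|Δx|)(H−|Δy|)), compared against pointwise envelopes from
  100 simulated CSR patterns. K below the envelope ⇒ dispersed (ordered),
  above ⇒ clustered, inside ⇒ random; under CSR, E[K(d)] = πd².

**Spot detection.** Threshold (exact-histogram Otsu or fixed) →
morphological opening → connected components → area filter → unweighted
centroids, replacing manual correction with explicit parameters, plus
centred cropping to equalise cell counts across images.

**Layer morphometry.** Per-layer thickness (GCL, IPL, INL, ONL, total) at
the HAA and 750 μm dorsal/ventral (three subregions each), HAA/neighbour
thickness ratios, exact one-sided binomial tests of P(ratio > 1 | p=½),
and a thickness heatmap: Kuwahara filter → Gaussian blur → threshold →
medial-axis skeleton whose distance-transform values give local
half-thickness.

**Opsin composition.** Densities per 10,000 μm² averaged over subregions,
rod-free-zone (RFZ) density ratios relative to the four neighbouring
regions, cone-composition percentages (rods excluded from the
denominator), Welch's unequal-variance t-test for timepoint comparisons,
and the TUNEL apoptotic index.

**Synthetic ground truth.** Jittered triangular lattices (regularity dial),
CSR, hard-core (sequential inhibition) and Thomas cluster patterns;
Gaussian-spot image rendering with noise; opsin-count cohorts drawn around
the published RFZ compositions; cross-section masks with a Gaussian
thickness bump at a designated HAA position.

## Worked example

```python
import numpy as np
from mosaic_order import *

field = Field(400.0, 400.0)
dists = np.linspace(5.0, 60.0, 12)

mosaic = generate_jittered_lattice(20.0, 1.0, field, seed=1)   # ordered mosaic
random = generate_csr(mosaic.n, field, seed=1)                 # CSR control
for label, pat in [("mosaic", mosaic), ("random", random)]:
    areas = voronoi_cells(pat).interior_areas()
    dist = variance_resample(areas, fraction=0.75, n_samples=10_000, seed=2, label=label)
    env = csr_envelope(pat.n, field, dists, n_iterations=100, seed=3)
    _, call = classify_dispersion(ripley_k(pat, dists), env, (10.0, 40.0))
    print(f"{label}  n={pat.n}  median resampled variance = "
          f"{dist.median():7.1f} um^4   Ripley: {call}")

ordered = generate_jittered_lattice(20.0, 2.0, field, seed=1)
obs, nulls, p = variance_vs_null(ordered, n_null=99, seed=4)
print(f"exclusion-zone null: observed var {obs:.0f}, "
      f"null range [{nulls.min():.0f}, {nulls.max():.0f}], empirical p = {p:.2f}")
```

prints

```
mosaic  n=460  median resampled variance =   208.5 um^4   Ripley: dispersed
random  n=460  median resampled variance = 26640.4 um^4   Ripley: random
exclusion-zone null: observed var 1020, null range [6190, 9992], empirical p = 0.01
```

The lattice mosaic has a ~130-fold lower median cell-area variance than the
CSR control of identical density, its K curve falls below the CSR envelope
at cell-spacing distances ("dispersed" = more ordered than random), and it
is significantly more ordered than its matched exclusion-zone null
(p = 0.01, the smallest value attainable with 99 nulls).

The same stages are scriptable from the shell:

```
mosaic-order simulate --model lattice --spacing 20 --jitter-sd 2 --out pattern.csv
mosaic-order tessellate pattern.csv --width 500 --height 500 --out cells.csv
mosaic-order order pattern.csv --width 500 --height 500 --out report.json
mosaic-order run --seed 1 --out full_report.json
```

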