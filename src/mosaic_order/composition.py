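"""Regional opsin density, composition and comparison statistics.

Counts per subregion are normalised to counts per 10,000 μm², averaged over
the three subregions of a region to give the regional density for each
opsin subtype and animal. From the densities the module derives total
cone/photoreceptor density ratios of the rod-free zone (RFZ) relative to
its four neighbouring regions, cone-composition percentages (rods excluded
from the denominator: the RFZ has no rods, so only the cone total is
comparable across regions), Welch's unequal-variance t-test for
cross-timepoint comparisons, and the TUNEL apoptotic index.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

CONE_SUBTYPES = ("UV", "blue", "green", "red")

COUNT_COLUMNS = [
    "animal_id",
    "timepoint",
    "region",
    "subtype",
    "subregion_index",
    "area_um2",
    "count",
]


def compute_densities(table: pd.DataFrame) -> pd.DataFrame:
    """Regional densities (count per 10,000 μm²) per animal and subtype.

    Each subregion contributes ``count / area × 10,000``; the three
    subregion densities are averaged into the regional density.
    """
    t = table.copy()
    if (t["area_um2"] <= 0).any():
        raise ValueError("subregion areas must be positive")
    t["density"] = t["count"] / t["area_um2"] * 10_000.0
    out = (
        t.groupby(["animal_id", "timepoint", "region", "subtype"], sort=False)["density"]
        .mean()
        .reset_index()
        .rename(columns={"density": "density_per_10k"})
    )
    return out


def rfz_relative_ratios(densities: pd.DataFrame, include_rods: bool = False) -> pd.DataFrame:
    """Total density in the RFZ relative to each neighbouring region.

    Totals sum the four cone subtypes, plus rods when ``include_rods``;
    one ratio per (animal, neighbour region).
    """
    subtypes = list(CONE_SUBTYPES) + (["rod"] if include_rods else [])
    d = densities[densities["subtype"].isin(subtypes)]
    totals = (
        d.groupby(["animal_id", "timepoint", "region"], sort=False)["density_per_10k"]
        .sum()
        .reset_index()
    )
    rows = []
    for (animal, tp), grp in totals.groupby(["animal_id", "timepoint"], sort=False):
        per_region = grp.set_index("region")["density_per_10k"]
        missing = [r for r in ("RFZ", "dorsal", "ventral", "nasal", "temporal") if r not in per_region.index]
        if missing:
            raise ValueError(f"animal {animal!r} is missing region(s) {missing}")
        for region in ("dorsal", "ventral", "nasal", "temporal"):
            rows.append((animal, tp, region, per_region["RFZ"] / per_region[region]))
    return pd.DataFrame(rows, columns=["animal_id", "timepoint", "region", "rfz_ratio"])


def composition_percent(densities: pd.DataFrame) -> pd.DataFrame:
    """Cone composition percentages with across-animal mean and SD.

    Per animal and region, each cone subtype's density is expressed as a
    percentage of the summed four cone densities; the table reports the
    mean and sample SD of these percentages across animals.
    """
    d = densities[densities["subtype"].isin(CONE_SUBTYPES)].copy()
    totals = d.groupby(["animal_id", "timepoint", "region"], sort=False)["density_per_10k"].transform("sum")
    if (totals <= 0).any():
        raise ValueError("zero total cone density for at least one animal/region")
    d["percent"] = d["density_per_10k"] / totals * 100.0
    agg = (
        d.groupby(["timepoint", "region", "subtype"], sort=False)["percent"]
        .agg(mean_percent="mean", sd_percent=lambda v: v.std(ddof=1) if len(v) > 1 else 0.0)
        .reset_index()
    )
    return agg


def per_animal_composition(densities: pd.DataFrame) -> pd.DataFrame:
    """Per-animal cone composition percentages (no across-animal averaging)."""
    d = densities[densities["subtype"].isin(CONE_SUBTYPES)].copy()
    totals = d.groupby(["animal_id", "timepoint", "region"], sort=False)["density_per_10k"].transform("sum")
    if (totals <= 0).any():
        raise ValueError("zero total cone density for at least one animal/region")
    d["percent"] = d["density_per_10k"] / totals * 100.0
    return d[["animal_id", "timepoint", "region", "subtype", "percent"]]


def welch_t_test(group_a, group_b) -> tuple[float, float, float]:
    """Welch's unequal-variance two-tailed t-test.

    Returns ``(t, Welch–Satterthwaite degrees of freedom, p)``.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        raise ValueError("both groups have zero variance")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def permutation_mean_test(group_a, group_b, n_permutations: int = 9_999, seed: int = 0) -> float:
    """Two-sided permutation test on the difference of means.

    Provided as a small-sample alternative to the Welch test; not used by
    default.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    res = stats.permutation_test(
        (a, b),
        lambda x, y, axis=-1: np.mean(x, axis=axis) - np.mean(y, axis=axis),
        n_resamples=n_permutations,
        alternative="two-sided",
        vectorized=True,
        rng=np.random.default_rng(seed),
    )
    return float(res.pvalue)


def tunel_index(counts, areas):
    """Apoptotic index: TUNEL⁺ cells per 10,000 μm²."""
    counts = np.asarray(counts, dtype=float)
    areas = np.asarray(areas, dtype=float)
    if np.any(areas <= 0):
        raise ValueError("areas must be positive")
    return counts / areas * 10_000.0
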