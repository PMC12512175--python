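"""End-to-end orchestration of the synthetic study.

A single :class:`RunConfig` drives simulate → detect → tessellate → order
plus the morphometry and composition stages, each independently toggleable.
One top-level seed is split into per-stage seeds through a stable scheme
(SeedSequence keyed on the stage name), so any stage can be re-run in
isolation with the seed recorded in the report.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import asdict, dataclass, field as dc_field
from pathlib import Path

import numpy as np
import yaml

from . import composition as comp
from . import detection, morphometry, spatial, synthetic
from .geometry import voronoi_cells
from .patterns import Field


def stage_seed(master: int, stage: str, index: int = 0) -> int:
    """Deterministic per-stage child seed (< 2³¹)."""
    ss = np.random.SeedSequence([int(master), zlib.crc32(stage.encode()), int(index)])
    return int(ss.generate_state(1, dtype=np.uint64)[0] % (2**31))


@dataclass
class RunConfig:
    """Parameters for one synthetic end-to-end run."""

    seed: int = 0
    # stage toggles
    run_order: bool = True
    run_detection: bool = True
    run_morpho: bool = True
    run_compose: bool = True
    # mosaic simulation
    field_um: tuple = (400.0, 400.0)
    spacing_um: float = 20.0
    jitter_fractions: tuple = (0.02, 0.10, 0.25)
    # spot rendering / detection
    spot_sd_um: float = 2.0
    amplitude: float = 100.0
    background: float = 10.0
    noise_sd: float = 5.0
    pixel_size_um: float = 1.0
    min_area_px: int = 3
    max_area_px: int = 500
    # spatial order
    n_samples: int = 10_000
    sample_fraction: float = 0.75
    n_iterations: int = 100
    envelope_level: tuple = (2.5, 97.5)
    correction: str = "translation"
    n_null: int = 0  # exclusion-zone null comparisons per mosaic (0 = skip)
    # morphometry
    gcl_amplitude: float = 0.5
    haa_sigma_um: float = 300.0
    kuwahara_radius: int = 2
    blur_sd_px: float = 2.0
    morpho_pixel_size_um: float = 1.0
    # composition
    n_animals: int = 3
    dispersion: float = 0.1
    excluded_animals: tuple = ()

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        for key in ("field_um", "jitter_fractions", "envelope_level", "excluded_animals"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)


def _order_stage(cfg: RunConfig) -> dict:
    field = Field(*cfg.field_um)
    report: dict = {"mosaics": {}, "seeds": {}}
    dists = np.linspace(2.0, 0.2 * min(cfg.field_um), 25)
    distributions = []
    for i, frac in enumerate(cfg.jitter_fractions):
        label = f"jitter_{frac:g}"
        seed = stage_seed(cfg.seed, "simulate", i)
        pattern = synthetic.generate_jittered_lattice(
            cfg.spacing_um, frac * cfg.spacing_um, field, seed
        )
        entry: dict = {"n_ground_truth": pattern.n, "jitter_sd_um": frac * cfg.spacing_um}
        if cfg.run_detection:
            image = synthetic.render_spots(
                pattern,
                cfg.spot_sd_um,
                cfg.amplitude,
                cfg.background,
                cfg.noise_sd,
                cfg.pixel_size_um,
                stage_seed(cfg.seed, "render", i),
            )
            params = detection.DetectionParams(
                min_area=cfg.min_area_px, max_area=cfg.max_area_px
            )
            pattern = detection.detect(image, params)
            entry["n_detected"] = pattern.n
        tess = voronoi_cells(pattern, clip=True)
        areas = tess.interior_areas()
        dist = spatial.variance_resample(
            areas,
            cfg.sample_fraction,
            cfg.n_samples,
            stage_seed(cfg.seed, "resample", i),
            label=label,
        )
        distributions.append(dist)
        entry["n_interior_cells"] = int(areas.size)
        entry["median_resampled_variance_um4"] = dist.median()
        curve = spatial.ripley_k(pattern, dists, cfg.correction)
        env = spatial.csr_envelope(
            pattern.n,
            pattern.field,
            dists,
            cfg.n_iterations,
            cfg.envelope_level,
            stage_seed(cfg.seed, "envelope", i),
            cfg.correction,
        )
        _, overall = spatial.classify_dispersion(
            curve, env, (cfg.spacing_um * 0.5, cfg.spacing_um * 2.0)
        )
        entry["ripley_classification"] = overall
        if cfg.n_null:
            _, _, p = spatial.variance_vs_null(
                pattern, cfg.n_null, stage_seed(cfg.seed, "null", i)
            )
            entry["empirical_p_vs_null"] = p
        report["mosaics"][label] = entry
    report["regularity_ranking"] = spatial.rank_regularity(distributions, areas_normalized=True)
    return report


def _morpho_stage(cfg: RunConfig) -> dict:
    spec = synthetic.CrossSectionSpec(
        haa_amplitude={"GCL": cfg.gcl_amplitude, "IPL": 0.1, "INL": 0.1, "ONL": 0.1},
        haa_sigma=cfg.haa_sigma_um,
    )
    mask, truth = synthetic.generate_cross_section(spec, cfg.morpho_pixel_size_um)
    measured = morphometry.measure_thickness(
        mask, cfg.morpho_pixel_size_um, spec.haa_position, spec.neighbor_offset,
        spec.subregion_spacing,
    )
    ratios = morphometry.thickness_ratios(measured)
    gcl = ratios[ratios["layer"] == "GCL"]
    heat = morphometry.thickness_heatmap(
        (mask > 0).astype(float) * 100.0,
        cfg.blur_sd_px,
        kuwahara_radius=cfg.kuwahara_radius,
        pixel_size=cfg.morpho_pixel_size_um,
    )
    peak_col, peak_half = morphometry.locate_peak_thickness(heat)
    return {
        "gcl_ratio_dorsal": float(gcl["ratio_dorsal"].iloc[0]),
        "gcl_ratio_ventral": float(gcl["ratio_ventral"].iloc[0]),
        "binomial_p_all_layers_dorsal": morphometry.binomial_ratio_test(
            ratios["ratio_dorsal"].to_numpy()
        ),
        "heatmap_peak_col_px": peak_col,
        "heatmap_peak_half_thickness_um": peak_half,
        "ground_truth_haa_col_px": spec.haa_position / cfg.morpho_pixel_size_um,
    }


def _compose_stage(cfg: RunConfig) -> dict:
    report = {}
    for tp, compo in (("E18", synthetic.E18_COMPOSITION), ("6Wks", synthetic.ADULT_COMPOSITION)):
        spec = synthetic.SyntheticCountSpec(
            composition=dict(compo),
            n_animals=cfg.n_animals,
            dispersion=cfg.dispersion,
            timepoint=tp,
        )
        counts = synthetic.generate_opsin_counts(spec, stage_seed(cfg.seed, f"counts_{tp}"))
        if cfg.excluded_animals:
            counts = counts[~counts["animal_id"].isin(cfg.excluded_animals)]
        dens = comp.compute_densities(counts)
        compo_table = comp.composition_percent(dens)
        rfz = compo_table[compo_table["region"] == "RFZ"]
        report[tp] = {
            "rfz_composition_pct": {
                row["subtype"]: round(float(row["mean_percent"]), 2)
                for _, row in rfz.iterrows()
            },
            "rfz_cone_ratio_mean": float(
                comp.rfz_relative_ratios(dens)["rfz_ratio"].mean()
            ),
        }
    return report


def run_pipeline(config: RunConfig, out_path: str | Path | None = None) -> dict:
    """Execute the toggled stages and return (optionally write) the report."""
    report: dict = {"config": asdict(config)}
    if config.run_order:
        report["order"] = _order_stage(config)
    if config.run_morpho:
        report["morphometry"] = _morpho_stage(config)
    if config.run_compose:
        report["composition"] = _compose_stage(config)
    if out_path is not None:
        Path(out_path).write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
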