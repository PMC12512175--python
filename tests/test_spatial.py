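import itertools
import math

import numpy as np
import pytest
from scipy import stats

from mosaic_order import (
    Field,
    PointPattern,
    classify_dispersion,
    csr_envelope,
    generate_csr,
    generate_hardcore,
    generate_jittered_lattice,
    generate_thomas,
    matched_null_pattern,
    min_same_type_distance,
    rank_regularity,
    ripley_k,
    variance_resample,
    variance_vs_null,
    voronoi_cells,
)
from mosaic_order.spatial import CsrEnvelope


def brute_force_ripley(pattern, distances, correction="none"):
    pts, n = pattern.points, pattern.n
    f = pattern.field
    R = f.area
    out = []
    for d in distances:
        s = 0.0
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                if np.linalg.norm(pts[i] - pts[j]) <= d:
                    if correction == "translation":
                        w = R / (
                            (f.width - abs(pts[i, 0] - pts[j, 0]))
                            * (f.height - abs(pts[i, 1] - pts[j, 1]))
                        )
                    else:
                        w = 1.0
                    s += w
        out.append(R / n**2 * s)
    return np.array(out)


class TestVarianceResample:
    def test_constant_areas_give_zero_variance(self):
        d = variance_resample([5.0] * 8, 0.75, 500, seed=0)
        assert (d.samples == 0).all()

    def test_exhaustive_subset_oracle(self):
        areas = np.array([1.0, 2.0, 3.0, 4.0])
        # enumerate all C(4,3) subsets for the exact mean sampled variance
        exact = [np.var(s, ddof=1) for s in itertools.combinations(areas, 3)]
        assert np.mean(exact) == pytest.approx(5.0 / 3.0)
        d = variance_resample(areas, 0.75, 10_000, seed=1)
        sem = np.std(exact, ddof=1) / math.sqrt(10_000)
        # Monte-Carlo error of the resampled mean
        assert abs(d.samples.mean() - 5.0 / 3.0) < 5 * np.std(d.samples) / 100.0
        assert set(np.round(np.unique(d.samples), 9)) == {1.0, round(7 / 3, 9)}

    def test_full_fraction_degenerates_to_full_set_variance(self):
        areas = np.array([2.0, 4.0, 9.0, 11.0, 30.0])
        d = variance_resample(areas, 1.0, 50, seed=0)
        np.testing.assert_allclose(d.samples, np.var(areas, ddof=1))

    def test_too_small_sample_size_rejected(self):
        with pytest.raises(ValueError):
            variance_resample([1.0, 2.0, 3.0, 4.0], 0.3, 10, seed=0)


class TestMatchedNull:
    def test_count_field_and_exclusion_conserved(self, field):
        pat = generate_csr(150, field, 3)
        null = matched_null_pattern(pat, seed=5)
        assert null.n == pat.n
        assert null.field == pat.field
        assert min_same_type_distance(null) >= min_same_type_distance(pat)

    def test_determinism(self, field):
        pat = generate_csr(80, field, 3)
        a = matched_null_pattern(pat, seed=9)
        b = matched_null_pattern(pat, seed=9)
        np.testing.assert_array_equal(a.points, b.points)


class TestVarianceVsNull:
    def test_p_bounds_and_ordered_pattern_significant(self, field):
        pat = generate_jittered_lattice(20.0, 2.0, field, 7)  # jitter 0.10·s
        obs, nulls, p = variance_vs_null(pat, n_null=99, seed=1)
        assert 1.0 / 100.0 <= p <= 1.0
        assert len(nulls) == 99
        assert p <= 0.05
        assert obs < nulls.min()

    def test_calibration_under_own_null_is_not_anticonservative(self):
        f = Field(200.0, 200.0)
        ps = []
        for s in range(60):
            pat = generate_hardcore(60, 8.0, f, 1000 + s)
            _, _, p = variance_vs_null(pat, n_null=19, seed=s)
            ps.append(p)
        ps = np.array(ps)
        # one-sided KS: reject only if p-values pile up near 0
        assert stats.kstest(ps, "uniform", alternative="greater").pvalue > 0.01
        assert ps.mean() > 0.35


class TestRipleyK:
    def test_unit_equilateral_triangle_closed_form(self):
        f = Field(10.0, 10.0)
        h = math.sqrt(3.0) / 2.0
        p = PointPattern([(4.0, 4.0), (5.0, 4.0), (4.5, 4.0 + h)], f)
        k = ripley_k(p, [0.5, 1.5], correction="none").k_values
        assert k[0] == 0.0
        assert k[1] == pytest.approx(f.area * 6.0 / 9.0)

    @pytest.mark.parametrize("correction", ["none", "translation"])
    def test_matches_brute_force_double_loop(self, correction):
        f = Field(120.0, 150.0)
        dists = np.linspace(3.0, 60.0, 10)
        for seed in range(5):
            p = generate_csr(12 + 5 * seed, f, seed)
            fast = ripley_k(p, dists, correction).k_values
            np.testing.assert_allclose(fast, brute_force_ripley(p, dists, correction), rtol=1e-12)

    def test_monotone_and_zero_at_origin(self, field):
        p = generate_csr(100, field, 0)
        k = ripley_k(p, np.linspace(1.0, 70.0, 30)).k_values
        assert (np.diff(k) >= 0).all()
        assert ripley_k(p, [1e-9]).k_values[0] == 0.0

    def test_translation_correction_distance_limit(self, field):
        p = generate_csr(10, field, 0)
        with pytest.raises(ValueError):
            ripley_k(p, [500.0], correction="translation")

    def test_translation_corrected_csr_mean_near_pi_d_squared(self):
        f = Field(500.0, 500.0)
        dists = np.linspace(10.0, 100.0, 10)
        ks = [ripley_k(generate_csr(500, f, s), dists).k_values for s in range(60)]
        rel = np.abs(np.mean(ks, axis=0) - np.pi * dists**2) / (np.pi * dists**2)
        assert rel.max() < 0.03


class TestEnvelopeAndClassification:
    def test_envelope_ordering_and_determinism(self, field):
        dists = np.linspace(2.0, 60.0, 15)
        env = csr_envelope(100, field, dists, n_iterations=30, seed=4)
        assert (env.lower <= env.mean).all() and (env.mean <= env.upper).all()
        env2 = csr_envelope(100, field, dists, n_iterations=30, seed=4)
        np.testing.assert_array_equal(env.upper, env2.upper)

    def test_fresh_csr_draw_mostly_inside_envelope(self, field):
        dists = np.linspace(5.0, 60.0, 12)
        env = csr_envelope(150, field, dists, n_iterations=100, seed=0)
        fracs = []
        for s in range(30):
            k = ripley_k(generate_csr(150, field, 2000 + s), dists).k_values
            fracs.append(np.mean((k >= env.lower) & (k <= env.upper)))
        assert np.mean(fracs) >= 0.90

    def test_curve_on_envelope_mean_is_random(self, field):
        dists = np.linspace(5.0, 50.0, 10)
        env = csr_envelope(100, field, dists, n_iterations=30, seed=1)
        curve = ripley_k(generate_csr(100, field, 0), dists)
        fake = type(curve)(dists, env.mean, 100, field.area, "translation")
        labels, overall = classify_dispersion(fake, env, (5.0, 50.0))
        assert overall == "random"
        assert all(l == "random" for l in labels)

    def test_hardcore_dispersed_and_thomas_clustered(self, field):
        dists = np.linspace(2.0, 26.0, 13)
        pat = generate_hardcore(200, 14.0, field, 3)
        env = csr_envelope(200, field, dists, n_iterations=100, seed=10)
        _, overall = classify_dispersion(ripley_k(pat, dists), env, (2.0, 26.0))
        assert overall == "dispersed"

        thomas = generate_thomas(20.0 / field.area, 10.0, 10.0, field, 6)
        dists2 = np.linspace(5.0, 40.0, 12)
        env2 = csr_envelope(thomas.n, field, dists2, n_iterations=100, seed=11)
        _, overall2 = classify_dispersion(ripley_k(thomas, dists2), env2, (5.0, 40.0))
        assert overall2 == "clustered"

    def test_mismatched_grids_rejected(self, field):
        dists = np.linspace(5.0, 50.0, 10)
        env = csr_envelope(50, field, dists, n_iterations=10, seed=0)
        curve = ripley_k(generate_csr(50, field, 0), dists * 1.01)
        with pytest.raises(ValueError):
            classify_dispersion(curve, env, (5.0, 50.0))


class TestRankRegularity:
    def test_recovers_jitter_order(self, field):
        s = 20.0
        wins = 0
        for seed in range(10):
            dists = []
            for jf in (0.25, 0.02, 0.10):  # scrambled input order
                p = generate_jittered_lattice(s, jf * s, field, seed + 31 * int(jf * 100))
                areas = voronoi_cells(p).interior_areas()
                dists.append(
                    variance_resample(areas, 0.75, 2000, seed=seed, label=f"{jf:g}")
                )
            if rank_regularity(dists) == ["0.02", "0.1", "0.25"]:
                wins += 1
        assert wins == 10

    def test_tie_break_keeps_input_order_and_singleton(self):
        d = variance_resample([1.0, 2.0, 3.0, 4.0], 0.75, 100, seed=0, label="a")
        d2 = variance_resample([1.0, 2.0, 3.0, 4.0], 0.75, 100, seed=0, label="b")
        assert rank_regularity([d, d2]) == ["a", "b"]
        assert rank_regularity([d2]) == ["b"]

    def test_normalized_ranking_scale_invariant(self, field):
        s = 20.0
        pats = [
            generate_jittered_lattice(s, jf * s, field, 3 + i)
            for i, jf in enumerate((0.02, 0.10, 0.25))
        ]
        labels = ["a", "b", "c"]

        def ranking(scale):
            dists = []
            for lab, p in zip(labels, pats):
                big = Field(field.width * scale, field.height * scale)
                q = PointPattern(p.points * scale, big, p.subtype)
                areas = voronoi_cells(q).interior_areas()
                dists.append(variance_resample(areas, 0.75, 1000, seed=7, label=lab))
            return rank_regularity(dists, areas_normalized=True)

        assert ranking(1.0) == ranking(3.0)
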