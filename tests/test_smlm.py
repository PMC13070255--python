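"""Radial distribution, randomization and cluster-relation statistics."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Polygon

from conftest import cluster_set
from efferoquant import smlm
from efferoquant import synthetic as syn


def brute_force_gr(ref, tgt, bins, roi_area, n_ref_kept=None):
    """O(N^2) pairwise-distance oracle with (lo, hi] annuli."""
    ref = np.asarray(ref, float)
    tgt = np.asarray(tgt, float)
    counts = np.zeros(len(bins) - 1)
    for r in ref:
        d = np.hypot(tgt[:, 0] - r[0], tgt[:, 1] - r[1])
        for i, (lo, hi) in enumerate(zip(bins[:-1], bins[1:])):
            counts[i] += np.sum((d > lo) & (d <= hi))
    area = np.pi * np.diff(np.asarray(bins, float) ** 2)
    density = len(tgt) / roi_area
    n = n_ref_kept if n_ref_kept is not None else len(ref)
    return counts / (n * area * density)


def square_roi(size):
    return Polygon([(0, 0), (size, 0), (size, size), (0, size)])


class TestRadialDistribution:
    def test_hand_computed_toy_example(self):
        # one reference at the centre of a 1x1 µm ROI; two targets at 50 and
        # 300 nm; bins (0,100] and (100,400]: one count each
        roi = square_roi(1000.0)
        ref = pd.DataFrame({"x_nm": [500.0], "y_nm": [500.0]})
        tgt = pd.DataFrame({"x_nm": [550.0, 800.0], "y_nm": [500.0, 500.0]})
        bins = np.array([0.0, 100.0, 400.0])
        rd = smlm.radial_distribution(ref, tgt, bins, roi)
        rho = 2 / 1_000_000.0
        expected = np.array([1 / (np.pi * 100**2 * rho),
                             1 / (np.pi * (400**2 - 100**2) * rho)])
        np.testing.assert_allclose(rd.g, expected, rtol=1e-12)

    def test_matches_brute_force_oracle(self, rng):
        roi = square_roi(4000.0)
        bins = np.arange(0.0, 401.0, 50.0)
        for _ in range(5):
            ref = rng.uniform(0, 4000, size=(120, 2))
            tgt = rng.uniform(0, 4000, size=(150, 2))
            rd = smlm.radial_distribution(ref, tgt, bins, roi)
            keep = smlm._interior_mask(ref, roi, bins[-1])
            oracle = brute_force_gr(ref[keep], tgt, bins, roi.area)
            np.testing.assert_array_equal(rd.g, oracle)

    def test_csr_mean_g_approaches_one(self):
        spec = syn.PatternSpec(mode="csr", species_densities={"A": 50.0, "B": 50.0},
                               seed=21)
        table, _ = syn.gen_point_pattern(spec)
        roi = syn.field_roi(spec)
        rd = smlm.radial_distribution(table[table.species == "A"],
                                      table[table.species == "B"],
                                      smlm.default_bins(), roi)
        assert abs(rd.g.mean() - 1.0) < 0.05

    def test_coclustered_pattern_enriched_at_short_range(self):
        spec = syn.PatternSpec(mode="coclustered", n_clusters=25, seed=13)
        table, _ = syn.gen_point_pattern(spec)
        roi = syn.field_roi(spec)
        rd = smlm.radial_distribution(table[table.species == "A"],
                                      table[table.species == "B"],
                                      smlm.default_bins(), roi)
        short = rd.g[rd.r_mid_nm < 100].mean()
        long = rd.g[rd.r_mid_nm > 300].mean()
        assert short > 10 * max(long, 1.0)
        assert rd.g_scaled.min() == 0.0 and rd.g_scaled.max() == 1.0

    def test_empty_species_rejected(self):
        roi = square_roi(1000.0)
        pts = pd.DataFrame({"x_nm": [500.0], "y_nm": [500.0]})
        empty = pd.DataFrame({"x_nm": [], "y_nm": []})
        with pytest.raises(ValueError):
            smlm.radial_distribution(empty, pts, np.array([0.0, 100.0]), roi)


class TestRandomization:
    def test_preserves_count_and_labels_and_is_deterministic(self):
        spec = syn.PatternSpec(mode="coclustered", seed=1)
        table, _ = syn.gen_point_pattern(spec)
        roi = syn.field_roi(spec)
        r1 = smlm.randomize_positions(table, roi, seed=5)
        r2 = smlm.randomize_positions(table, roi, seed=5)
        assert len(r1) == len(table)
        assert (r1.species == table.species).all()
        pd.testing.assert_frame_equal(r1, r2)

    def test_randomized_positions_are_uniform(self):
        # chi-square on quadrant counts, pooled over seeds
        roi = square_roi(1000.0)
        table = pd.DataFrame({"x_nm": np.zeros(100), "y_nm": np.zeros(100)})
        counts = np.zeros(4)
        for seed in range(20):
            r = smlm.randomize_positions(table, roi, seed=seed)
            qx = (r.x_nm > 500).astype(int)
            qy = (r.y_nm > 500).astype(int)
            for q in range(4):
                counts[q] += np.sum((qx + 2 * qy) == q)
        total = counts.sum()
        chi2 = np.sum((counts - total / 4) ** 2 / (total / 4))
        assert chi2 < 11.35  # chi2_{3, 0.01}

    def test_empty_table_passthrough(self):
        roi = square_roi(100.0)
        empty = pd.DataFrame({"x_nm": [], "y_nm": []})
        assert len(smlm.randomize_positions(empty, roi, 0)) == 0


class TestEnvelope:
    def test_too_few_reps_rejected(self):
        roi = square_roi(1000.0)
        t = pd.DataFrame({"x_nm": [500.0], "y_nm": [500.0]})
        with pytest.raises(ValueError):
            smlm.mc_envelope(t, t, np.array([0.0, 100.0]), roi, n_reps=1)

    def test_coclustered_signal_exceeds_envelope_at_short_range(self):
        spec = syn.PatternSpec(mode="coclustered", n_clusters=25, seed=17)
        table, _ = syn.gen_point_pattern(spec)
        roi = syn.field_roi(spec)
        bins = smlm.default_bins(300.0, 20.0)
        a = table[table.species == "A"]
        b = table[table.species == "B"]
        rd = smlm.radial_distribution(a, b, bins, roi)
        low, high = smlm.mc_envelope(a, b, bins, roi, n_reps=40, seed=3)
        short = rd.r_mid_nm < 100
        assert np.all(rd.g[short] > high[short])


class TestClusters:
    def test_two_separated_blobs_recovered(self, rng):
        blob1 = rng.normal([1000, 1000], 20, size=(10, 2))
        blob2 = rng.normal([5000, 5000], 20, size=(10, 2))
        pts = np.vstack([blob1, blob2])
        cs = smlm.extract_clusters(pts, min_points=5, max_reach_nm=100)
        assert len(cs) == 2
        members = sorted(tuple(sorted(c.indices)) for c in cs.clusters)
        assert members == [tuple(range(10)), tuple(range(10, 20))]

    def test_sparse_csr_is_mostly_noise(self):
        spec = syn.PatternSpec(mode="csr", species_densities={"A": 0.4, "B": 0.4},
                               seed=19)
        table, _ = syn.gen_point_pattern(spec)
        pts = table[table.species == "A"][["x_nm", "y_nm"]]
        cs = smlm.extract_clusters(pts, min_points=10, max_reach_nm=60)
        assert len(cs.noise_indices) >= 0.9 * len(pts)

    def test_blob_diameter_near_construction(self):
        spec = syn.PatternSpec(mode="coclustered", n_clusters=1,
                               cluster_occupancy={"A": 40, "B": 40},
                               localization_precision_sd_nm=5, seed=23)
        table, _ = syn.gen_point_pattern(spec)
        pts = table[table.species == "A"][["x_nm", "y_nm"]]
        cs = smlm.extract_clusters(pts, min_points=5, max_reach_nm=100)
        assert len(cs) == 1
        assert abs(cs.clusters[0].diameter_nm - 120) <= 2 * 5 + 25

    def test_min_points_precondition(self):
        with pytest.raises(ValueError):
            smlm.extract_clusters(np.zeros((5, 2)), min_points=1)


class TestRelations:
    def test_identical_sets_are_fully_colocalized(self, rng):
        pts = rng.normal(0, 30, size=(15, 2))
        rel = smlm.classify_cluster_relations(cluster_set(pts), cluster_set(pts))
        assert rel.colocalized == 1.0
        assert rel.contacting == 0.0 and rel.neither == 0.0

    def test_distant_sets_are_unrelated(self, rng):
        a = rng.normal([0, 0], 30, size=(15, 2))
        b = rng.normal([5000, 5000], 30, size=(15, 2))
        rel = smlm.classify_cluster_relations(cluster_set(a), cluster_set(b),
                                              contact_dist_nm=20)
        assert rel.neither == 1.0

    def test_fractions_sum_to_one(self, rng):
        a1 = rng.normal([0, 0], 30, size=(12, 2))
        a2 = rng.normal([400, 0], 30, size=(12, 2))
        b = rng.normal([0, 10], 30, size=(12, 2))
        rel = smlm.classify_cluster_relations(cluster_set(a1, a2), cluster_set(b))
        assert rel.colocalized + rel.contacting + rel.neither == pytest.approx(1.0)

    def test_invariant_under_rigid_motion(self, rng):
        a1 = rng.normal([0, 0], 30, size=(12, 2))
        a2 = rng.normal([300, 0], 30, size=(12, 2))
        b = rng.normal([5, 0], 30, size=(12, 2))
        rel0 = smlm.classify_cluster_relations(cluster_set(a1, a2), cluster_set(b))
        th = 0.7
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        shift = np.array([1234.5, -987.0])
        rel1 = smlm.classify_cluster_relations(
            cluster_set(a1 @ rot.T + shift, a2 @ rot.T + shift),
            cluster_set(b @ rot.T + shift))
        assert rel0.colocalized == rel1.colocalized
        assert rel0.contacting == rel1.contacting

    def test_randomized_baseline_below_observed_for_coclustered(self):
        spec = syn.PatternSpec(mode="coclustered", n_clusters=25,
                               cluster_occupancy={"A": 15, "B": 15}, seed=29)
        table, _ = syn.gen_point_pattern(spec)
        roi = syn.field_roi(spec)
        rel = smlm.relation_analysis(
            table[table.species == "A"], table[table.species == "B"],
            roi, min_points=8, max_reach_nm=60, n_random=3, seed=1)
        observed = rel.colocalized + rel.contacting
        randomized = rel.randomized_colocalized + rel.randomized_contacting
        assert observed > randomized

    def test_empty_cluster_set_rejected(self, rng):
        a = cluster_set(rng.normal(0, 10, size=(5, 2)))
        empty = smlm.ClusterSet([], np.empty(0, int), {})
        with pytest.raises(ValueError):
            smlm.classify_cluster_relations(a, empty)
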