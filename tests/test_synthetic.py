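"""Generator correctness: ground truth must match what was simulated."""

import numpy as np
import pytest
from scipy.spatial import cKDTree

from efferoquant import synthetic as syn
from efferoquant.fret import FretCoefficients, compute_ea
from efferoquant.spt import msd


class TestPointPattern:
    def test_csr_counts_are_near_expected(self):
        spec = syn.PatternSpec(mode="csr", field_size_nm=10_000,
                               species_densities={"A": 0.4, "B": 0.4}, seed=7)
        table, _ = syn.gen_point_pattern(spec)
        counts = table.species.value_counts()
        # Poisson(40): both species within 4 sd of the mean
        for sp in ("A", "B"):
            assert abs(counts[sp] - 40) < 4 * np.sqrt(40)

    def test_fixed_seed_is_bit_identical(self):
        spec = syn.PatternSpec(mode="coclustered", seed=3)
        t1, _ = syn.gen_point_pattern(spec)
        t2, _ = syn.gen_point_pattern(spec)
        assert t1.equals(t2)

    def test_coclustered_points_near_truth_centres(self):
        spec = syn.PatternSpec(mode="coclustered", n_clusters=20,
                               cluster_diameter_nm=120,
                               cluster_occupancy={"A": 10, "B": 10},
                               localization_precision_sd_nm=10, seed=5)
        table, truth = syn.gen_point_pattern(spec)
        for sp in ("A", "B"):
            sub = table[table.species == sp]
            cid = truth["cluster_id"][table.species == sp]
            centres = truth["cluster_centers"][sp][cid]
            d = np.hypot(sub.x_nm.to_numpy() - centres[:, 0],
                         sub.y_nm.to_numpy() - centres[:, 1])
            assert np.all(d <= 60 + 3 * 10)

    def test_contacting_disks_touch_edge_to_edge(self):
        spec = syn.PatternSpec(mode="contacting", contact_gap_nm=0.0,
                               n_clusters=10, seed=2)
        _, truth = syn.gen_point_pattern(spec)
        ca, cb = truth["cluster_centers"].values()
        centre_dist = np.linalg.norm(ca - cb, axis=1)
        # gap 0 -> centre separation is exactly one cluster diameter
        np.testing.assert_allclose(centre_dist, spec.cluster_diameter_nm,
                                   rtol=1e-12)

    def test_csr_nearest_neighbour_matches_closed_form(self):
        # NN distance CDF for a Poisson process: F(r) = 1 - exp(-lambda pi r^2)
        spec = syn.PatternSpec(mode="csr", field_size_nm=10_000,
                               species_densities={"A": 15.0, "B": 15.0},
                               localization_precision_sd_nm=0.0, seed=11)
        table, _ = syn.gen_point_pattern(spec)
        pts = table[table.species == "A"][["x_nm", "y_nm"]].to_numpy()
        assert len(pts) >= 1000
        d, _ = cKDTree(pts).query(pts, k=2)
        nn = np.sort(d[:, 1])
        lam = len(pts) / spec.field_size_nm ** 2
        f_theory = 1.0 - np.exp(-lam * np.pi * nn ** 2)
        f_emp = np.arange(1, len(nn) + 1) / len(nn)
        assert np.max(np.abs(f_emp - f_theory)) < 0.05

    def test_invalid_density_rejected(self):
        with pytest.raises(ValueError):
            syn.gen_point_pattern(
                syn.PatternSpec(species_densities={"A": -1.0, "B": 1.0}))


class TestBleachTrace:
    def test_noiseless_trace_has_exact_unit_steps(self):
        spec = syn.TraceSpec(n_steps=3, unit_intensity=100, noise_sd=0, seed=1)
        trace, truth = syn.gen_bleach_trace(spec)
        drops = np.flatnonzero(np.diff(trace) < 0)
        total = trace[0] - trace[-1]
        assert total == pytest.approx(300)
        assert len(drops) <= 3  # coincident events can merge transitions
        assert np.all(np.diff(trace) <= 0)
        assert len(truth["bleach_frames"]) == 3

    def test_zero_steps_gives_flat_baseline(self):
        trace, truth = syn.gen_bleach_trace(
            syn.TraceSpec(n_steps=0, baseline=50.0, noise_sd=0))
        assert np.all(trace == 50.0)
        assert len(truth["bleach_frames"]) == 0

    def test_trace_is_reproducible(self):
        spec = syn.TraceSpec(n_steps=28, noise_sd=20.0, seed=9)
        t1, _ = syn.gen_bleach_trace(spec)
        t2, _ = syn.gen_bleach_trace(spec)
        np.testing.assert_array_equal(t1, t2)


class TestFretForward:
    def test_forward_model_inverts_exactly_at_zero_noise(self):
        coeffs = FretCoefficients(alpha=0.07, beta=0.11, gamma=0.21)
        for e in (0.0, 0.1, 0.25):
            stack = syn.gen_fret_stack(syn.FretForwardSpec(
                true_e_map=np.full((16, 16), e), coefficients=coeffs))
            ea = compute_ea(stack, coeffs)
            assert np.nanmax(np.abs(ea.E_A - e)) < 1e-10

    def test_acceptor_free_stack_is_donor_only_control(self):
        coeffs = FretCoefficients(alpha=0.05, beta=0.12, gamma=0.18)
        stack = syn.gen_fret_stack(syn.FretForwardSpec(
            true_e_map=np.zeros((8, 8)), acceptor_abundance=0.0,
            background=(5.0, 5.0, 5.0), coefficients=coeffs))
        np.testing.assert_allclose(stack.Iaa, 5.0)          # background only
        np.testing.assert_allclose(stack.Ida, 0.12 * (stack.Idd - 5.0) + 5.0)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            syn.FretForwardSpec(true_e_map=np.zeros((4, 4)),
                                donor_abundance=np.ones((8, 8))).validate()


class TestTrajectories:
    def test_brownian_msd_slope_matches_einstein_relation(self):
        spec = syn.MotionSpec(model="brownian", d_um2_s=0.1, n_tracks=300,
                              track_length=50, localization_error_sd_nm=0.0,
                              seed=4)
        table, _ = syn.gen_trajectories(spec)
        slopes = []
        for _, grp in table.groupby("id"):
            lags, curve = msd(grp, frame_interval_s=spec.frame_interval_s)
            slopes.append(np.polyfit(lags, curve, 1)[0])
        d_est = np.mean(slopes) / 4 * 1e-6
        assert d_est == pytest.approx(0.1, rel=0.05)

    def test_confined_positions_stay_inside_corral(self):
        spec = syn.MotionSpec(model="confined", corral_diameter_nm=200,
                              n_tracks=50, track_length=80,
                              localization_error_sd_nm=0.0, seed=6)
        _, truth = syn.gen_trajectories(spec)
        pos = truth["true_positions"]
        centres = pos.mean(axis=1, keepdims=True)
        r = np.linalg.norm(pos - centres, axis=-1)
        # all true positions inside the corral disk (small slack for the
        # centre being estimated from the track itself)
        assert np.all(r <= 100 * 1.35)

    def test_confined_msd_plateau_matches_disk_closed_form(self):
        # long-lag ensemble MSD for uniform points in a disk: diameter^2 / 4
        spec = syn.MotionSpec(model="confined", corral_diameter_nm=200,
                              d_um2_s=0.1, n_tracks=250, track_length=60,
                              localization_error_sd_nm=0.0, seed=8)
        table, _ = syn.gen_trajectories(spec)
        plateau = []
        for _, grp in table.groupby("id"):
            lags, curve = msd(grp, max_lag_fraction=0.5)
            plateau.append(curve[-5:].mean())
        assert np.mean(plateau) == pytest.approx(200 ** 2 / 4, rel=0.15)

    def test_zero_diffusion_track_is_static_plus_noise(self):
        spec = syn.MotionSpec(model="brownian", d_um2_s=0.0, n_tracks=5,
                              track_length=30, localization_error_sd_nm=15,
                              seed=2)
        _, truth = syn.gen_trajectories(spec)
        assert np.ptp(truth["true_positions"], axis=1).max() == 0.0

    def test_degenerate_corral_rejected(self):
        with pytest.raises(ValueError):
            syn.MotionSpec(model="confined", corral_diameter_nm=30,
                           localization_error_sd_nm=20).validate()


class TestUptakeScene:
    def test_ground_truth_counts(self):
        scene = syn.gen_uptake_scene(2, 3, 2, seed=0)
        assert scene.truth["index"] == 3.0
        assert scene.truth["bound"] == 2.0
        assert len(scene.cell_polygons) == 2

    def test_dye_integral_matches_mask_sum(self):
        scene = syn.gen_uptake_scene(2, 2, 1, seed=1, mode="apoptotic_cells",
                                     dye_intensity=50.0)
        for cell, integral in zip(scene.truth["per_cell"],
                                  scene.truth["internal_dye_integral_per_cell"]):
            assert integral == 50.0 * syn._disk_pixel_count(
                cell["internal_centers_px"], scene.truth["bead_radius_px"],
                *scene.target_channel.shape)

    def test_zero_internal_gives_zero_index(self):
        scene = syn.gen_uptake_scene(3, 0, 2, seed=2)
        assert scene.truth["index"] == 0.0
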