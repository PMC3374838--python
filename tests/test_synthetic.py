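"""Generator unit and property tests: speed process, trajectories,
dataset assembly, frame rendering."""

import math

import numpy as np
import pytest

from locotrack.synthetic import (
    PRESETS,
    GenotypeParams,
    SimConfig,
    generate_dataset,
    render_frame,
    sample_animal_params,
    simulate_speed_trace,
    simulate_track_population,
    simulate_trajectory,
    stationary_speed_sd,
)


class TestSpeedTrace:
    def test_zero_noise_fixed_point(self):
        p = GenotypeParams("g", mu_speed=0.1, theta=1.0, sigma=0.0)
        v = simulate_speed_trace(p, 50, dt=1.0, seed=0, v0=0.1)
        np.testing.assert_allclose(v, 0.1)

    def test_deterministic_relaxation_monotone(self):
        p = GenotypeParams("g", mu_speed=0.15, theta=0.8, sigma=0.0)
        v = simulate_speed_trace(p, 100, dt=0.5, seed=0, v0=0.01)
        assert np.all(np.diff(v) >= 0)  # monotone relaxation
        assert np.all(np.diff(v[:20]) > 0)  # strictly increasing far from mu
        assert v[-1] == pytest.approx(0.15, abs=1e-6)
        assert np.all(v <= 0.15 + 1e-12)

    def test_stationary_sd_closed_form(self):
        p = GenotypeParams("g", mu_speed=0.15, theta=1.0, sigma=0.05)
        v = simulate_speed_trace(p, 20000, dt=0.1, seed=11)
        target = stationary_speed_sd(p)
        assert target == pytest.approx(0.05 / math.sqrt(2.0), abs=1e-12)
        assert v.std(ddof=1) == pytest.approx(target, rel=0.05)
        assert v.mean() == pytest.approx(0.15, rel=0.05)

    def test_nonnegative_and_seed_reproducible(self):
        p = PRESETS["cat2_like"]
        a = simulate_speed_trace(p, 500, dt=1.0, seed=3)
        b = simulate_speed_trace(p, 500, dt=1.0, seed=3)
        assert np.all(a >= 0)
        np.testing.assert_array_equal(a, b)

    def test_parameter_errors(self):
        p = PRESETS["wild_type"]
        with pytest.raises(ValueError):
            simulate_speed_trace(p, 1, dt=1.0, seed=0)
        with pytest.raises(ValueError):
            simulate_speed_trace(p, 10, dt=0.0, seed=0)
        with pytest.raises(ValueError):
            GenotypeParams("g", mu_speed=0.1, theta=0.0, sigma=0.01)
        with pytest.raises(ValueError):
            GenotypeParams("g", mu_speed=-0.1, theta=1.0, sigma=0.01)


class TestTrajectory:
    def test_straight_line_at_constant_speed(self):
        speeds = np.full(10, 0.1)
        pos = simulate_trajectory(
            speeds, turn_sd=0.0, start=(1.0, 1.0), arena_size=(10, 10), seed=0, heading0=0.0
        )
        np.testing.assert_allclose(pos[:, 1], 1.0)
        np.testing.assert_allclose(np.diff(pos[:, 0]), 0.1)

    def test_zero_speed_stationary(self):
        pos = simulate_trajectory(
            np.zeros(20), turn_sd=0.3, start=(2.0, 3.0), arena_size=(10, 10), seed=1
        )
        np.testing.assert_allclose(pos, np.tile([2.0, 3.0], (21, 1)))

    def test_step_length_equals_speed_dt_in_interior(self, rng):
        speeds = rng.uniform(0, 0.2, 50)
        pos = simulate_trajectory(
            speeds, turn_sd=0.8, start=(5.0, 5.0), arena_size=(10, 10), seed=5
        )
        steps = np.hypot(*np.diff(pos, axis=0).T)
        np.testing.assert_allclose(steps, speeds, atol=1e-12)

    def test_reflective_boundary_keeps_path_inside(self):
        speeds = np.full(2000, 0.3)
        pos = simulate_trajectory(
            speeds, turn_sd=0.2, start=(0.5, 0.5), arena_size=(2.0, 2.0), seed=2
        )
        assert pos.min() >= 0.0 and pos.max() <= 2.0

    def test_same_seed_identical_paths(self):
        speeds = np.full(30, 0.1)
        kw = dict(turn_sd=0.5, start=(5, 5), arena_size=(10, 10))
        np.testing.assert_array_equal(
            simulate_trajectory(speeds, seed=9, **kw),
            simulate_trajectory(speeds, seed=9, **kw),
        )

    def test_start_outside_arena_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            simulate_trajectory(np.zeros(5), 0.1, (11, 5), (10, 10), seed=0)
        with pytest.raises(ValueError, match="nonnegative"):
            simulate_trajectory(np.array([-0.1]), 0.1, (5, 5), (10, 10), seed=0)


class TestGenerateDataset:
    def test_single_animal_count_conservation(self, wt_params):
        cfg = SimConfig(n_animals=1, duration_s=120.0, dropout_prob=0.0, seed=0)
        frames, gt = generate_dataset(cfg, [wt_params])
        assert len(frames) == 121
        assert all(len(f) == 1 for f in frames)

    def test_dropout_binomial_expectation(self, wt_params):
        cfg = SimConfig(
            n_animals=40, duration_s=120.0, dropout_prob=0.5, seed=3,
            arena_size=(30.0, 30.0),
        )
        frames, _ = generate_dataset(cfg, [wt_params])
        counts = np.array([len(f) for f in frames])
        # binomial(40, 0.5) mean 20, SE of the mean over 121 frames ~ 0.29
        assert abs(counts.mean() - 20) < 1.5

    def test_no_dropout_centroids_equal_truth(self, small_dataset):
        _, frames, gt = small_dataset
        for t, f in enumerate(frames):
            np.testing.assert_array_equal(f, gt.positions[:, t, :])

    def test_determinism(self, wt_params):
        cfg = SimConfig(n_animals=4, duration_s=30.0, seed=42)
        f1, g1 = generate_dataset(cfg, [wt_params])
        f2, g2 = generate_dataset(cfg, [wt_params])
        np.testing.assert_array_equal(g1.positions, g2.positions)
        for a, b in zip(f1, f2):
            np.testing.assert_array_equal(a, b)

    def test_genotype_round_robin(self, wt_params):
        other = PRESETS["cat2_like"]
        cfg = SimConfig(n_animals=5, duration_s=30.0, seed=0)
        _, gt = generate_dataset(cfg, [wt_params, other])
        assert gt.genotypes == ["wt", "cat2_like", "wt", "cat2_like", "wt"]

    def test_arena_too_small_rejected(self, wt_params):
        cfg = SimConfig(
            n_animals=100, duration_s=10.0, arena_size=(1.0, 1.0),
            min_separation=1.0, seed=0,
        )
        with pytest.raises(ValueError, match="too small"):
            generate_dataset(cfg, [wt_params])

    def test_min_separation_enforced_throughout(self, wt_params):
        cfg = SimConfig(
            n_animals=9, duration_s=60.0, min_separation=1.2, seed=5,
            arena_size=(9.0, 9.0), dropout_prob=0.0,
        )
        _, gt = generate_dataset(cfg, [wt_params])
        for t in range(gt.positions.shape[1]):
            pts = gt.positions[:, t, :]
            d = np.hypot(*(pts[:, None, :] - pts[None, :, :]).T)
            np.fill_diagonal(d, np.inf)
            assert d.min() > 1.2

    def test_ground_truth_table_schema(self, small_dataset):
        _, _, gt = small_dataset
        df = gt.to_dataframe()
        assert list(df.columns) == [
            "frame", "time_s", "animal_id", "genotype", "x_mm", "y_mm", "true_speed_mm_s",
        ]
        assert len(df) == 5 * 61


class TestPersonalParams:
    def test_mu_sd_zero_is_identity(self, rng):
        p = GenotypeParams("g", mu_speed=0.1, theta=1.0, sigma=0.02, mu_sd=0.0)
        assert sample_animal_params(p, rng) is p

    def test_population_mean_spread_matches_mu_sd(self):
        p = GenotypeParams("g", mu_speed=0.15, theta=0.5, sigma=0.037, mu_sd=0.031)
        rng = np.random.default_rng(0)
        mus = [sample_animal_params(p, rng).mu_speed for _ in range(4000)]
        assert np.std(mus) == pytest.approx(0.031, rel=0.1)
        assert np.mean(mus) == pytest.approx(0.15, abs=0.005)

    def test_track_population_reproducible(self, wt_params):
        a = simulate_track_population(wt_params, 5, 60, 1.0, 77)
        b = simulate_track_population(wt_params, 5, 60, 1.0, 77)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x, y)


class TestRenderFrame:
    def test_centroid_of_single_blob(self):
        img = render_frame(np.array([[0.8, 0.5]]), (100, 120), blob_sigma=3.0)
        yy, xx = np.mgrid[0:100, 0:120]
        cx = (img * xx).sum() / img.sum()
        cy = (img * yy).sum() / img.sum()
        assert cx == pytest.approx(80.0, abs=0.1)
        assert cy == pytest.approx(50.0, abs=0.1)

    def test_zero_animals_uniform_background(self):
        img = render_frame(np.empty((0, 2)), (32, 32), background=1.5)
        np.testing.assert_allclose(img, 1.5)

    def test_two_blobs_two_local_maxima(self):
        img = render_frame(np.array([[0.2, 0.2], [0.8, 0.7]]), (100, 100), blob_sigma=2.0)
        from scipy.ndimage import maximum_filter

        peaks = np.argwhere((img == maximum_filter(img, 5)) & (img > 10))
        assert len(peaks) == 2
        assert {tuple(p) for p in peaks} == {(20, 20), (70, 80)}

    def test_total_intensity_proportional_to_count(self):
        one = render_frame(np.array([[0.5, 0.5]]), (128, 128)).sum()
        three = render_frame(
            np.array([[0.3, 0.3], [0.5, 0.9], [0.9, 0.5]]), (128, 128)
        ).sum()
        assert three == pytest.approx(3 * one, rel=0.01)

    def test_position_outside_image_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            render_frame(np.array([[2.0, 0.5]]), (100, 100))
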