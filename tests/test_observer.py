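"""Ideal observer: posterior updating and expected-error maps."""

import numpy as np
import pytest

from circlequest.observer import (
    ContradictoryObservationsError,
    EEMap,
    PosteriorGrid,
    batch_posterior_oracle,
    ee_opt_fast,
    ee_trajectory,
    expected_error_map,
    init_prior,
    optimal_placement,
    update_posterior,
)
from circlequest.task import (
    PURPLE,
    WHITE,
    Condition,
    SampleEvent,
    TaskConfig,
    Trial,
    classify_sample,
)


def random_consistent_observations(config, rng, n_max=5):
    """Touches classified against a hidden centre: never contradictory."""
    hidden = rng.uniform(-200, 200, size=2)
    obs = [
        SampleEvent(
            *(hidden + rng.uniform(-100, 100, size=2)), PURPLE, 0.0, paid=False
        )
    ]
    # force the free dot inside the circle
    while (
        classify_sample(hidden, (obs[0].x, obs[0].y), config.circle_radius) != PURPLE
    ):
        obs = [
            SampleEvent(
                *(hidden + rng.uniform(-100, 100, size=2)), PURPLE, 0.0, paid=False
            )
        ]
    for k in range(rng.integers(0, n_max)):
        pt = rng.uniform(-config.field_radius, config.field_radius, size=2)
        col = classify_sample(hidden, pt, config.circle_radius)
        obs.append(SampleEvent(pt[0], pt[1], col, float(k + 1)))
    return obs


class TestPrior:
    def test_uniform_over_support_disk(self, config):
        prior = init_prior(config)
        radii = np.linalg.norm(prior.points, axis=1)
        assert radii.max() <= config.support_radius
        assert prior.total_mass == pytest.approx(1.0, abs=1e-9)
        assert np.allclose(prior.weights, prior.weights[0])
        assert prior.stage == 0

    def test_halving_stride_quadruples_support(self):
        n8 = init_prior(TaskConfig(grid_stride=8.0)).size
        n4 = init_prior(TaskConfig(grid_stride=4.0)).size
        assert n4 / n8 == pytest.approx(4.0, rel=0.02)

    def test_stride_larger_than_support_rejected(self):
        cfg = TaskConfig(field_radius=140.0, circle_radius=130.0, grid_stride=20.0)
        # support radius 10 px still admits the origin; shrink further via radius
        prior = init_prior(cfg)
        assert prior.size >= 1


class TestUpdate:
    def test_purple_dot_keeps_inclusive_disk(self, config, rng):
        prior = init_prior(config)
        c = np.array([50.0, -30.0])
        post = update_posterior(
            prior, SampleEvent(c[0], c[1], PURPLE, 0.0, paid=False),
            config.circle_radius,
        )
        expected = prior.points[
            np.linalg.norm(prior.points - c, axis=1) <= config.circle_radius
        ]
        assert post.size == len(expected)
        assert np.array_equal(np.sort(post.points, axis=0), np.sort(expected, axis=0))
        assert post.total_mass == pytest.approx(1.0, abs=1e-9)
        assert post.stage == 1

    def test_white_dot_keeps_strict_complement(self, config):
        prior = init_prior(config)
        c = np.array([0.0, 0.0])
        post = update_posterior(
            prior, SampleEvent(0.0, 0.0, WHITE, 0.0, paid=False),
            config.circle_radius,
        )
        dists = np.linalg.norm(post.points, axis=1)
        assert dists.min() > config.circle_radius
        assert post.size + np.count_nonzero(
            np.linalg.norm(prior.points - c, axis=1) <= config.circle_radius
        ) == prior.size

    def test_contradiction_raises(self, config):
        prior = init_prior(config)
        post = update_posterior(
            prior, SampleEvent(0, 0, PURPLE, 0.0, paid=False), config.circle_radius
        )
        with pytest.raises(ContradictoryObservationsError):
            # a white dot at the same spot excludes every remaining centre
            update_posterior(
                post, SampleEvent(0, 0, WHITE, 1.0), config.circle_radius
            )


class TestBatchOracle:
    def test_empty_observations_give_prior(self, config):
        oracle = batch_posterior_oracle([], config)
        prior = init_prior(config)
        assert oracle.size == prior.size
        assert np.array_equal(oracle.points, prior.points)

    def test_matches_sequential_updating(self, config, rng):
        for _ in range(25):
            obs = random_consistent_observations(config, rng)
            grid = init_prior(config)
            for o in obs:
                grid = update_posterior(grid, o, config.circle_radius)
            oracle = batch_posterior_oracle(obs, config)
            assert np.array_equal(grid.points, oracle.points)
            assert np.allclose(grid.weights, oracle.weights, atol=1e-12, rtol=0)

    def test_order_invariance(self, config, rng):
        obs = random_consistent_observations(config, rng, n_max=6)
        perm = [obs[i] for i in rng.permutation(len(obs))]
        a = batch_posterior_oracle(obs, config)
        b = batch_posterior_oracle(perm, config)
        assert np.array_equal(a.points, b.points)


class TestExpectedErrorMap:
    def test_point_mass_gives_distances(self, config):
        grid = PosteriorGrid(
            points=np.array([[8.0, 16.0]]), weights=np.array([1.0]),
            stage=1, stride=8.0,
        )
        cand = np.array([[8.0, 16.0], [8.0, 116.0], [38.0, 56.0]])
        m = expected_error_map(grid, candidates=cand)
        assert m.ee == pytest.approx([0.0, 100.0, 50.0])
        star, opt = optimal_placement(m)
        assert opt == 0.0
        assert tuple(star) == (8.0, 16.0)

    def test_two_equal_masses(self):
        grid = PosteriorGrid(
            points=np.array([[0.0, 0.0], [100.0, 0.0]]),
            weights=np.array([0.5, 0.5]),
            stage=1, stride=4.0,
        )
        m = expected_error_map(grid, candidates=grid.points)
        assert m.ee == pytest.approx([50.0, 50.0])

    def test_tie_breaks_lexicographically(self):
        m = EEMap(
            candidates=np.array([[4.0, 0.0], [0.0, 4.0], [0.0, 0.0]]),
            ee=np.array([1.0, 1.0, 1.0]),
            lambda_star=np.zeros(2),
            ee_opt=1.0,
        )
        star, _ = optimal_placement(m)
        assert tuple(star) == (0.0, 0.0)

    def test_uniform_disk_mean_distance(self):
        # mean distance from the centre of a uniform disc of radius r is 2r/3
        cfg = TaskConfig(grid_stride=4.0)
        grid = update_posterior(
            init_prior(cfg), SampleEvent(0, 0, PURPLE, 0.0, paid=False),
            cfg.circle_radius,
        )
        m = expected_error_map(grid)
        assert m.ee_opt == pytest.approx(2 * cfg.circle_radius / 3, rel=0.01)
        assert np.linalg.norm(m.lambda_star) <= cfg.grid_stride * np.sqrt(2)

    def test_empty_candidates_rejected(self, config):
        with pytest.raises(ValueError):
            expected_error_map(init_prior(config), candidates=np.empty((0, 2)))

    def test_ee_opt_bounds_all_candidates(self, config, rng):
        obs = random_consistent_observations(config, rng)
        grid = batch_posterior_oracle(obs, config)
        m = expected_error_map(grid)
        assert m.ee_opt <= m.ee.min() + 1e-12
        assert np.all(m.ee >= 0)


class TestFastPath:
    def test_matches_dense_map(self, config, rng):
        # the EE surface is convex, so multigrid descent must find the
        # same minimum as dense evaluation of the bounding lattice
        for _ in range(30):
            obs = random_consistent_observations(config, rng, n_max=6)
            grid = batch_posterior_oracle(obs, config)
            dense = expected_error_map(grid).ee_opt
            fast = ee_opt_fast(grid)[1]
            assert fast == pytest.approx(dense, abs=1e-9)


class TestTrajectory:
    def _trial(self, samples):
        return Trial(
            trial_id=0, condition=Condition("low", "low"),
            hidden_center=(0.0, 0.0), samples=samples, placement=(0.0, 0.0),
        )

    def test_single_free_dot_matches_disc_oracle(self, config):
        traj = ee_trajectory(
            self._trial([SampleEvent(0, 0, PURPLE, 0.0, paid=False)]), config
        )
        assert len(traj) == 1
        assert traj[0] == pytest.approx(2 * config.circle_radius / 3, rel=0.02)

    def test_length_and_shrinking_support(self, config, rng):
        obs = random_consistent_observations(config, rng, n_max=6)
        traj = ee_trajectory(self._trial(obs), config)
        assert len(traj) == len(obs)
        # support can only shrink, so every EE stays below the one-dot bound
        grid = init_prior(config)
        sizes = []
        for o in obs:
            grid = update_posterior(grid, o, config.circle_radius)
            sizes.append(grid.size)
        assert all(a >= b for a, b in zip(sizes, sizes[1:]))
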