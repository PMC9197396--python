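"""Synthetic cohort generator: agents, trials, questionnaires, offers."""

import numpy as np
import pytest

from circlequest.observer import init_prior, update_posterior
from circlequest.simulate import (
    PASSIVE_EE_BANDS,
    PASSIVE_REWARDS,
    AgentParams,
    CohortConfig,
    generate_passive_offer_set,
    next_sample_location,
    simulate_cohort,
    simulate_questionnaires,
    simulate_trial,
)
from circlequest.simulate import _expected_ee_after
from circlequest.task import PURPLE, Condition, SampleEvent, TaskConfig, score_trial

AGENT = AgentParams(
    isi_mu=float(np.log(1.7)), isi_sigma=0.35, q=0.7, stop_threshold=2.0, lapse=0.05
)
SMALL_COHORT = dict(n_control=2, n_sci=2, seed=11)


@pytest.fixture(scope="module")
def single_dot_grid(config):
    prior = init_prior(config)
    return update_posterior(
        prior, SampleEvent(0, 0, PURPLE, 0.0, paid=False), config.circle_radius
    )


class TestPolicy:
    def test_q0_is_uniform_and_reproducible(self, config, single_dot_grid):
        agent = AgentParams(
            isi_mu=0.5, isi_sigma=0.3, q=0.0, stop_threshold=2.0, lapse=0.0
        )
        a = next_sample_location(
            single_dot_grid, agent, config, np.random.default_rng(5)
        )
        b = next_sample_location(
            single_dot_grid, agent, config, np.random.default_rng(5)
        )
        assert np.array_equal(a, b)
        assert np.linalg.norm(a) <= config.field_radius

    def test_points_stay_inside_field(self, config, single_dot_grid, rng):
        for q in (0.0, 1.0):
            agent = AgentParams(
                isi_mu=0.5, isi_sigma=0.3, q=q, stop_threshold=2.0, lapse=0.0
            )
            for _ in range(20):
                pt = next_sample_location(single_dot_grid, agent, config, rng)
                assert np.linalg.norm(pt) <= config.field_radius + 1e-9

    def test_greedy_beats_random_touches(self, config, single_dot_grid, rng):
        # expected one-step EE reduction of the greedy choice vs uniform
        agent = AgentParams(
            isi_mu=0.5, isi_sigma=0.3, q=1.0, stop_threshold=2.0, lapse=0.0
        )
        greedy = np.mean(
            [
                _expected_ee_after(
                    single_dot_grid,
                    next_sample_location(single_dot_grid, agent, config, rng),
                    config.circle_radius,
                )
                for _ in range(15)
            ]
        )
        random_touch = np.mean(
            [
                _expected_ee_after(
                    single_dot_grid,
                    rng.uniform(-config.field_radius, config.field_radius, 2),
                    config.circle_radius,
                )
                for _ in range(60)
            ]
        )
        assert greedy < random_touch


class TestTrial:
    def test_respects_time_budget(self, config, rng):
        trial = simulate_trial(AGENT, Condition("high", "low"), config, rng)
        assert all(s.t <= config.sampling_duration for s in trial.samples)
        assert not trial.samples[0].paid
        assert trial.samples[0].colour == PURPLE

    def test_infinite_threshold_stops_immediately(self, config, rng):
        lazy = AgentParams(
            isi_mu=0.5, isi_sigma=0.3, q=1.0, stop_threshold=1e9, lapse=0.0
        )
        trial = simulate_trial(lazy, Condition("low", "high"), config, rng)
        assert trial.paid_count == 0
        assert len(trial.samples) == 1

    def test_score_conservation(self, config, rng):
        trial = simulate_trial(AGENT, Condition("low", "high"), config, rng)
        expected = score_trial(
            config.initial_credit("low"),
            config.sample_cost("high"),
            trial.paid_count,
            config.error_cost,
            trial.localisation_error,
        )
        assert trial.score(config) == pytest.approx(expected)

    def test_near_optimal_agent_samples_near_s_star(self, config, rng):
        # a greedy agent with a small stop margin should land close to the
        # rational optimum recovered from its own fitted efficiency
        from circlequest.efficiency import fit_extraction_rate
        from circlequest.observer import ee_trajectory
        from circlequest.optimality import expected_value_curve

        agent = AgentParams(
            isi_mu=float(np.log(1.2)), isi_sigma=0.2, q=1.0,
            stop_threshold=0.0, lapse=0.0,
        )
        prior = init_prior(config)
        cond = Condition("high", "high")
        trials = [
            simulate_trial(agent, cond, config, rng, trial_id=i, prior=prior)
            for i in range(25)
        ]
        fit = fit_extraction_rate([ee_trajectory(t, config) for t in trials])
        curve = expected_value_curve(
            fit, R0=config.initial_credit("high"),
            eta_s=config.sample_cost("high"), eta_e=config.error_cost,
        )
        mean_s = np.mean([t.paid_count for t in trials])
        assert abs(mean_s - curve.s_star) <= 2.5


class TestCohort:
    def test_default_block_structure(self, coarse_config):
        cfg = CohortConfig(n_control=1, n_sci=1, seed=2)
        data = simulate_cohort(cfg, coarse_config, include_passive=False)
        # 4 blocks x 15 trials for every participant
        per = data.trials.groupby("participant_id").size()
        assert (per == 60).all()
        combos = data.trials.groupby(["participant_id", "R0", "eta_s"]).size()
        assert (combos == 15).all()
        assert len(combos) == 2 * 4

    def test_same_seed_byte_identical(self, coarse_config):
        kw = dict(**SMALL_COHORT)
        a = simulate_cohort(
            CohortConfig(**kw),
            TaskConfig(grid_stride=16.0, trials_per_block=2),
            include_passive=False,
        )
        b = simulate_cohort(
            CohortConfig(**kw),
            TaskConfig(grid_stride=16.0, trials_per_block=2),
            include_passive=False,
        )
        assert a.trials.to_csv() == b.trials.to_csv()
        assert a.samples.to_csv() == b.samples.to_csv()
        assert a.questionnaires.to_csv() == b.questionnaires.to_csv()

    def test_group_shifts_have_expected_direction(self):
        # large cohort, agent parameters only (no trial simulation needed)
        cfg = CohortConfig(n_control=200, n_sci=200, seed=4)
        rng = np.random.default_rng(cfg.seed)
        from circlequest.simulate import _draw_agent

        ctl = [_draw_agent(cfg, "control", rng) for _ in range(cfg.n_control)]
        sci = [_draw_agent(cfg, "SCI", rng) for _ in range(cfg.n_sci)]
        assert np.mean([a.isi_mu for a in sci]) < np.mean([a.isi_mu for a in ctl])
        assert np.mean([a.stop_threshold for a in sci]) < np.mean(
            [a.stop_threshold for a in ctl]
        )
        assert np.mean([a.q for a in sci]) == pytest.approx(
            np.mean([a.q for a in ctl]), abs=0.05
        )


class TestPolicyEfficiencyLink:
    def test_alpha_ranks_agents_by_q(self, config):
        # agents differing only in policy quality q must be ranked by the
        # fitted information extraction rate
        from scipy import stats

        from circlequest.recovery import alpha_q_sweep

        sweep = alpha_q_sweep(n_agents=20, n_trials=60, seed=3, task=config)
        rho = stats.spearmanr(sweep["q"], sweep["alpha"]).statistic
        assert rho > 0.8


class TestQuestionnaires:
    def test_ranges_and_calibration(self):
        cfg = CohortConfig(n_control=300, n_sci=300, seed=8)
        q = simulate_questionnaires(cfg, np.random.default_rng(8))
        assert q["bdi"].between(0, 63).all()
        assert q["hads_anx"].between(0, 21).all()
        assert q["hads_dep"].between(0, 21).all()
        assert q["ace_iii"].between(88, 100).all()
        ctl = q[q["group"] == "control"]
        sci = q[q["group"] == "SCI"]
        assert ctl["bdi"].mean() == pytest.approx(4.59, abs=1.0)
        assert sci["bdi"].mean() == pytest.approx(15.44, abs=2.0)
        assert sci["bdi"].mean() > ctl["bdi"].mean()

    def test_depression_anxiety_correlate(self):
        cfg = CohortConfig(n_control=500, n_sci=1, seed=9)
        q = simulate_questionnaires(cfg, np.random.default_rng(9))
        ctl = q[q["group"] == "control"]
        r = np.corrcoef(ctl["bdi"], ctl["hads_anx"])[0, 1]
        assert r > 0.3


@pytest.fixture(scope="module")
def offers(config):
    return generate_passive_offer_set(config, np.random.default_rng(21))


class TestPassiveOffers:
    def test_offer_grid_structure(self, offers):
        assert len(offers) == 100
        types = {(o.ee_band, o.reward) for o in offers}
        assert len(types) == len(PASSIVE_EE_BANDS) * len(PASSIVE_REWARDS) == 20

    def test_four_purple_four_white(self, offers):
        for o in offers[::7]:
            colours = [d.colour for d in o.dots]
            assert colours.count("purple") == 4
            assert colours.count("white") == 4

    def test_ee_within_band(self, offers):
        for o in offers:
            lo, hi = PASSIVE_EE_BANDS[o.ee_band - 1]
            assert lo <= o.ee_opt <= hi
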