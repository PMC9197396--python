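"""Synthetic cohorts for the active and passive sampling tasks.

No participant data ships with this package; instead, an agent-based
generator produces datasets with the statistical structure the analysis
assumes: 27 + 27 participants (controls and a subjective-cognitive-
impairment group), four condition blocks of active trials, 100 passive
offers, and Table-1-calibrated questionnaires with correlated depression
and anxiety scores.

Each agent touches the screen at lognormally distributed inter-touch
intervals. With probability ``q`` a touch is *informative* — chosen from a
coarse proposal set to minimise the expected one-step-ahead posterior
uncertainty — and otherwise uniform over the field, so ``q`` maps onto the
fitted information extraction rate. Sampling stops when the 18 s budget
runs out or when the myopic expected-value gain of one more sample drops
below the agent's stopping threshold; the hidden-circle placement is the
ideal-observer optimum for the evidence gathered. The group structure
(faster sampling and a lower stopping threshold in the SCI group, equal
``q``) reproduces the faster-but-equally-efficient dissociation that the
analysis is designed to detect.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import _kernels
from .observer import (
    ContradictoryObservationsError,
    PosteriorGrid,
    batch_posterior_oracle,
    ee_opt_fast,
    expected_error_map,
    init_prior,
    update_posterior,
)
from .task import (
    PURPLE,
    WHITE,
    Condition,
    SampleEvent,
    TaskConfig,
    Trial,
    block_schedule,
    classify_sample,
    score_trial,
)

__all__ = [
    "AgentParams",
    "CohortConfig",
    "CohortData",
    "PassiveOffer",
    "PASSIVE_EE_BANDS",
    "PASSIVE_REWARDS",
    "next_sample_location",
    "simulate_trial",
    "simulate_cohort",
    "simulate_questionnaires",
    "generate_passive_offer_set",
    "simulate_passive_responses",
]

#: Experimentally defined uncertainty bands of the passive task (px).
PASSIVE_EE_BANDS = (
    (16.3, 24.4),
    (27.1, 38.9),
    (57.5, 58.9),
    (73.33, 74.18),
    (91.9, 93.3),
)
#: Reward levels on offer in the passive task (credits).
PASSIVE_REWARDS = (40, 65, 90, 115)


@dataclass(frozen=True)
class AgentParams:
    """Generative parameters of one simulated participant."""

    isi_mu: float  # lognormal location of inter-touch time (log s)
    isi_sigma: float  # lognormal scale (log units)
    q: float  # probability of an informative (greedy) touch
    stop_threshold: float  # credits; stop when myopic EV gain falls below
    lapse: float = 0.05  # probability of ignoring the stop rule

    def __post_init__(self) -> None:
        if not 0.0 <= self.q <= 1.0:
            raise ValueError("q must lie in [0, 1]")
        if self.isi_sigma <= 0:
            raise ValueError("isi_sigma must be positive")
        if not 0.0 <= self.lapse <= 1.0:
            raise ValueError("lapse must lie in [0, 1]")


@dataclass(frozen=True)
class CohortConfig:
    """Population structure of a simulated cohort.

    Group effects are expressed as shifts of the generative agent
    parameters: the SCI group has a shorter median inter-touch interval
    (``sci_log_isi_shift`` log-seconds) and a lower stopping threshold
    (``sci_stop_threshold_shift`` credits, yielding more samples), while
    ``q`` — hence sampling efficiency — is identical across groups. The
    default shifts equal twice the between-participant SD of the
    corresponding parameter. Questionnaire means and SDs follow the study
    cohort's demographics table.
    """

    n_control: int = 27
    n_sci: int = 27
    seed: int = 0
    # inter-touch interval population (log-seconds)
    log_isi_mean: float = math.log(1.7)
    log_isi_sd: float = 0.15  # between participants
    isi_sigma: float = 0.35  # within participant (lognormal scale)
    sci_log_isi_shift: float = -0.30  # 2 SD faster
    # stopping threshold population (credits)
    stop_threshold_mean: float = 2.0
    stop_threshold_sd: float = 0.5
    sci_stop_threshold_shift: float = -1.0  # 2 SD lower -> more samples
    # informative-touch probability (equal across groups)
    q_mean: float = 0.7
    q_sd: float = 0.1
    lapse: float = 0.05
    # questionnaires: (control mean, control SD, SCI mean, SCI SD)
    age: tuple = (62.04, 6.28, 59.81, 7.70)
    ace_iii: tuple = (97.89, 1.80, 95.41, 4.21)
    bdi: tuple = (4.59, 4.36, 15.44, 11.24)
    hads_dep: tuple = (1.48, 1.81, 5.26, 4.61)
    hads_anx: tuple = (4.30, 3.16, 7.04, 3.32)
    rho: float = 0.55  # within-group depression-anxiety correlation

    def __post_init__(self) -> None:
        if self.n_control < 1 or self.n_sci < 1:
            raise ValueError("group sizes must be at least 1")
        if not -1.0 < self.rho < 1.0:
            raise ValueError("|rho| must be below 1")


@dataclass
class CohortData:
    """A full simulated dataset: one row per trial, sample, participant."""

    trials: pd.DataFrame
    samples: pd.DataFrame
    questionnaires: pd.DataFrame
    passive: pd.DataFrame | None = None


@dataclass
class PassiveOffer:
    """One passive-task offer: a dot configuration with reward on top."""

    offer_id: int
    ee_band: int  # 1..5
    reward: float  # credits
    repetition: int  # 1..5
    ee_opt: float  # px, ideal-observer uncertainty of the configuration
    dots: list[SampleEvent] = field(default_factory=list)


# ---------------------------------------------------------------------------
# agent policy


def _uniform_in_disk(rng: np.random.Generator, radius: float) -> np.ndarray:
    rho = radius * math.sqrt(rng.random())
    theta = rng.random() * 2.0 * math.pi
    return np.array([rho * math.cos(theta), rho * math.sin(theta)])


def _expected_ee_after(
    grid: PosteriorGrid, touch: np.ndarray, r: float
) -> float:
    """Expected posterior uncertainty after touching ``touch``.

    Splits the posterior by the outcome disk and weighs the two branch
    uncertainties by their predictive probabilities. Each branch is scored
    by the EE at its centroid — an O(n) surrogate for the Weber-point
    optimum that is exact for symmetric supports and an upper bound in
    general (see the methods note).
    """
    px, py, w = grid.points[:, 0], grid.points[:, 1], grid.weights
    inside = _kernels.inside_disk(px, py, touch[0], touch[1], r)
    p_purple = float(w[inside].sum())
    total = float(w.sum())
    p_purple /= total
    ee = 0.0
    for mask, prob in ((inside, p_purple), (~inside, 1.0 - p_purple)):
        if prob <= 0.0 or not mask.any():
            continue
        wm = w[mask]
        wm = wm / wm.sum()
        ee += prob * _kernels.ee_at_centroid(px[mask], py[mask], wm)
    return ee


def _proposal_set(
    grid: PosteriorGrid, r: float, field_radius: float, rng: np.random.Generator
) -> np.ndarray:
    """Coarse candidate touches around the posterior bulk.

    Mixes points drawn near the support (offsets up to the support spread
    plus one circle radius, where the outcome disk can split the mass)
    with a few support points themselves.
    """
    centroid = grid.centroid()
    spread = float(
        np.sqrt(((grid.points - centroid) ** 2).sum(axis=1).max())
    )
    k_ring, k_support = 8, 4
    rho = (spread + r) * np.sqrt(rng.random(k_ring))
    theta = rng.random(k_ring) * 2.0 * math.pi
    ring = centroid + np.column_stack([rho * np.cos(theta), rho * np.sin(theta)])
    idx = rng.integers(0, grid.size, size=min(k_support, grid.size))
    props = np.vstack([ring, grid.points[idx]])
    norms = np.linalg.norm(props, axis=1)
    shrink = np.where(norms > field_radius, field_radius / np.maximum(norms, 1e-12), 1.0)
    return props * shrink[:, None]


def _best_greedy_touch(
    grid: PosteriorGrid, config: TaskConfig, rng: np.random.Generator
) -> tuple[np.ndarray, float]:
    """Greedy touch minimising expected one-step-ahead uncertainty."""
    props = _proposal_set(grid, config.circle_radius, config.field_radius, rng)
    j, best_ee = _kernels.best_expected_ee(
        grid.points[:, 0],
        grid.points[:, 1],
        grid.weights,
        np.ascontiguousarray(props[:, 0]),
        np.ascontiguousarray(props[:, 1]),
        config.circle_radius,
    )
    return props[j], float(best_ee)


def next_sample_location(
    grid: PosteriorGrid,
    agent: AgentParams,
    config: TaskConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Where the agent touches next.

    With probability ``q`` the greedy informative touch, otherwise a
    uniform draw over the search field. Always inside the field.
    """
    if rng.random() < agent.q:
        pt, _ = _best_greedy_touch(grid, config, rng)
        return pt
    return _uniform_in_disk(rng, config.field_radius)


# ---------------------------------------------------------------------------
# trial and cohort simulation


def simulate_trial(
    agent: AgentParams,
    condition: Condition,
    config: TaskConfig,
    rng: np.random.Generator,
    trial_id: int = 0,
    prior: PosteriorGrid | None = None,
) -> Trial:
    """One active trial of the agent under the given condition.

    The hidden centre is uniform over the prior support, the free initial
    purple dot is uniform inside the hidden circle, and sampling proceeds
    until the time budget or the myopic stop rule ends it. The placement
    is the exact ideal-observer optimum for the final posterior.
    """
    if prior is None:
        prior = init_prior(config)
    eta_s = config.sample_cost(condition.cost_level)
    # uniform over the prior support (a lattice point, so the observer's
    # feasible set always contains the truth and can never empty out)
    hidden = prior.points[rng.integers(0, prior.size)]
    free = hidden + _uniform_in_disk(rng, config.circle_radius)
    samples = [SampleEvent(free[0], free[1], PURPLE, 0.0, paid=False)]
    grid = update_posterior(prior, samples[0], config.circle_radius)

    t = 0.0
    while True:
        t += float(rng.lognormal(agent.isi_mu, agent.isi_sigma))
        if t > config.sampling_duration:
            break
        # myopic stop rule: expected EV gain of one more (greedy) sample
        ee_now = _kernels.ee_at_centroid(
            grid.points[:, 0], grid.points[:, 1], grid.weights
        )
        greedy_pt, greedy_ee = _best_greedy_touch(grid, config, rng)
        gain = config.error_cost * (ee_now - greedy_ee) - eta_s
        if gain < agent.stop_threshold and rng.random() >= agent.lapse:
            break
        if rng.random() < agent.q:
            touch = greedy_pt
        else:
            touch = _uniform_in_disk(rng, config.field_radius)
        colour = classify_sample(hidden, touch, config.circle_radius)
        obs = SampleEvent(touch[0], touch[1], colour, t, paid=True)
        grid = update_posterior(grid, obs, config.circle_radius)
        samples.append(obs)

    placement = ee_opt_fast(grid)[0]
    return Trial(
        trial_id=trial_id,
        condition=condition,
        hidden_center=(hidden[0], hidden[1]),
        samples=samples,
        placement=(float(placement[0]), float(placement[1])),
    )


def _draw_agent(
    cohort: CohortConfig, group: str, rng: np.random.Generator
) -> AgentParams:
    isi_shift = cohort.sci_log_isi_shift if group == "SCI" else 0.0
    stop_shift = cohort.sci_stop_threshold_shift if group == "SCI" else 0.0
    return AgentParams(
        isi_mu=float(rng.normal(cohort.log_isi_mean + isi_shift, cohort.log_isi_sd)),
        isi_sigma=cohort.isi_sigma,
        q=float(np.clip(rng.normal(cohort.q_mean, cohort.q_sd), 0.0, 1.0)),
        stop_threshold=float(
            rng.normal(cohort.stop_threshold_mean + stop_shift, cohort.stop_threshold_sd)
        ),
        lapse=cohort.lapse,
    )


def _trial_row(pid: str, trial: Trial, config: TaskConfig) -> dict:
    return {
        "participant_id": pid,
        "trial_id": trial.trial_id,
        "R0": config.initial_credit(trial.condition.R0_level),
        "eta_s": config.sample_cost(trial.condition.cost_level),
        "hidden_x": trial.hidden_center[0],
        "hidden_y": trial.hidden_center[1],
        "placement_x": trial.placement[0],
        "placement_y": trial.placement[1],
        "n_paid_samples": trial.paid_count,
        "error_px": trial.localisation_error,
        "score": trial.score(config),
    }


def simulate_cohort(
    cohort: CohortConfig,
    config: TaskConfig | None = None,
    include_passive: bool = True,
) -> CohortData:
    """Simulate the full study dataset for one cohort.

    Produces 4 condition blocks x ``trials_per_block`` active trials per
    participant (block order randomised per participant), Table-1-style
    questionnaires, and, optionally, the passive task (one shared offer
    set, individual responses). Fully determined by ``cohort.seed``.
    """
    if config is None:
        config = TaskConfig()
    rng = np.random.default_rng(cohort.seed)
    prior = init_prior(config)

    trial_rows: list[dict] = []
    sample_rows: list[dict] = []
    pids: list[str] = []
    groups: list[str] = []
    for group, n in (("control", cohort.n_control), ("SCI", cohort.n_sci)):
        tag = "C" if group == "control" else "S"
        for i in range(n):
            pid = f"{tag}{i + 1:02d}"
            pids.append(pid)
            groups.append(group)
            agent = _draw_agent(cohort, group, rng)
            trial_id = 0
            for cond in block_schedule(rng):
                for _ in range(config.trials_per_block):
                    trial = simulate_trial(
                        agent, cond, config, rng, trial_id=trial_id, prior=prior
                    )
                    trial_rows.append(_trial_row(pid, trial, config))
                    for j, s in enumerate(trial.samples):
                        sample_rows.append(
                            {
                                "participant_id": pid,
                                "trial_id": trial_id,
                                "sample_index": j,
                                "t_s": s.t,
                                "x": s.x,
                                "y": s.y,
                                "colour": s.colour,
                                "paid": int(s.paid),
                            }
                        )
                    trial_id += 1

    questionnaires = simulate_questionnaires(cohort, rng, pids=pids, groups=groups)
    passive = None
    if include_passive:
        offers = generate_passive_offer_set(config, rng)
        passive = simulate_passive_responses(offers, pids, groups, rng)
    return CohortData(
        trials=pd.DataFrame(trial_rows),
        samples=pd.DataFrame(sample_rows),
        questionnaires=questionnaires,
        passive=passive,
    )


def simulate_questionnaires(
    cohort: CohortConfig,
    rng: np.random.Generator,
    pids: list[str] | None = None,
    groups: list[str] | None = None,
) -> pd.DataFrame:
    """Questionnaire table with correlated depression and anxiety scores.

    BDI-II, HADS-depression and HADS-anxiety are drawn from a group-
    specific correlated Gaussian (correlation ``rho`` between each pair of
    affective scores), rounded and clipped to the instrument ranges; age
    and ACE-III are drawn independently from the group demographics.
    """
    if pids is None:
        pids = [f"C{i + 1:02d}" for i in range(cohort.n_control)] + [
            f"S{i + 1:02d}" for i in range(cohort.n_sci)
        ]
        groups = ["control"] * cohort.n_control + ["SCI"] * cohort.n_sci
    assert groups is not None and len(groups) == len(pids)

    rho = cohort.rho
    corr = np.array([[1.0, rho, rho], [rho, 1.0, rho], [rho, rho, 1.0]])
    chol = np.linalg.cholesky(corr)
    rows = []
    for pid, group in zip(pids, groups):
        col = 0 if group == "control" else 2
        z = chol @ rng.standard_normal(3)
        bdi = cohort.bdi[col] + cohort.bdi[col + 1] * z[0]
        dep = cohort.hads_dep[col] + cohort.hads_dep[col + 1] * z[1]
        anx = cohort.hads_anx[col] + cohort.hads_anx[col + 1] * z[2]
        rows.append(
            {
                "participant_id": pid,
                "group": group,
                "age": int(np.clip(round(rng.normal(*cohort.age[col : col + 2])), 40, 90)),
                "ace_iii": int(np.clip(round(rng.normal(*cohort.ace_iii[col : col + 2])), 88, 100)),
                "bdi": int(np.clip(round(bdi), 0, 63)),
                "hads_dep": int(np.clip(round(dep), 0, 21)),
                "hads_anx": int(np.clip(round(anx), 0, 21)),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# passive task


class BandUnreachableError(RuntimeError):
    """Rejection sampling failed to land in an uncertainty band."""


def _propose_configuration(
    config: TaskConfig, u: float, rng: np.random.Generator
) -> list[SampleEvent]:
    """Candidate 4-purple/4-white dot configuration.

    Purple dots are drawn inside a realised hidden circle within a
    fraction ``u`` of its radius; white dots sit just outside the circle,
    at gaps that widen as ``u`` grows. Small ``u`` (clumped purples,
    tightly carving whites) yields high uncertainty, large ``u`` low
    uncertainty, so sweeping ``u`` spans the experimental bands. The
    configuration is consistent with the realised circle by construction.
    """
    r = config.circle_radius
    # keep the circle comfortably inside the field so whites fit too
    c = _uniform_in_disk(rng, config.support_radius - 0.6 * r)
    dots = []
    for _ in range(4):
        p = c + _uniform_in_disk(rng, max(u, 0.02) * r)
        dots.append(SampleEvent(p[0], p[1], PURPLE, 0.0, paid=False))
    for _ in range(4):
        gap = 1.0 + 0.02 + u * float(rng.random())
        theta = rng.random() * 2.0 * math.pi
        w = c + r * gap * np.array([math.cos(theta), math.sin(theta)])
        dots.append(SampleEvent(w[0], w[1], WHITE, 0.0, paid=False))
    return dots


def generate_passive_offer_set(
    config: TaskConfig,
    rng: np.random.Generator,
    repetitions: int = 5,
    max_attempts: int = 50_000,
) -> list[PassiveOffer]:
    """The passive task's 100 offers: 5 EE bands x 4 rewards x 5 repeats.

    For each band and repetition, dot configurations are rejection-sampled
    until the ideal-observer uncertainty of the configuration falls inside
    the band; the accepted configuration is shown once at each of the four
    reward levels. Raises :class:`BandUnreachableError` if a band is not
    hit within ``max_attempts`` proposals.
    """
    # band-specific proposal spread, annealed from wide to narrow EE
    u_ranges = [(0.75, 1.0), (0.45, 0.85), (0.18, 0.5), (0.08, 0.3), (0.0, 0.12)]
    offers: list[PassiveOffer] = []
    offer_id = 0
    for band_idx, (lo, hi) in enumerate(PASSIVE_EE_BANDS, start=1):
        u_lo, u_hi = u_ranges[band_idx - 1]
        for rep in range(1, repetitions + 1):
            accepted = None
            for _ in range(max_attempts):
                u = u_lo + (u_hi - u_lo) * float(rng.random())
                dots = _propose_configuration(config, u, rng)
                try:
                    grid = batch_posterior_oracle(dots, config)
                except ContradictoryObservationsError:
                    continue
                ee = expected_error_map(grid).ee_opt
                if lo <= ee <= hi:
                    accepted = (dots, ee)
                    break
            if accepted is None:
                raise BandUnreachableError(
                    f"EE band {band_idx} ({lo}-{hi} px) not reached in "
                    f"{max_attempts} attempts; check geometry and stride"
                )
            dots, ee = accepted
            for reward in PASSIVE_REWARDS:
                offers.append(
                    PassiveOffer(
                        offer_id=offer_id,
                        ee_band=band_idx,
                        reward=float(reward),
                        repetition=rep,
                        ee_opt=ee,
                        dots=dots,
                    )
                )
                offer_id += 1
    return offers


def simulate_passive_responses(
    offers: list[PassiveOffer],
    pids: list[str],
    groups: list[str],
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Confidence ratings and accept/reject choices for each offer.

    Confidence falls with the offer's uncertainty band (9-point scale,
    Gaussian rating noise); acceptance is logistic in reward minus an
    uncertainty penalty. Both groups share the same response model —
    passive estimation and valuation of uncertainty are intact in the
    study population.
    """
    from .metrics import subjective_uncertainty

    rows = []
    for pid, group in zip(pids, groups):
        conf = np.clip(
            np.round(
                9.5
                - 1.6 * np.array([o.ee_band for o in offers])
                + rng.normal(0.0, 1.0, size=len(offers))
            ),
            1,
            9,
        )
        subj = subjective_uncertainty(conf)
        logits = (
            0.3
            + 1.2 * (np.array([o.reward for o in offers]) - 77.5) / 25.0
            - 1.0 * (np.array([o.ee_band for o in offers]) - 3.0)
        )
        accept = rng.random(len(offers)) < 1.0 / (1.0 + np.exp(-logits))
        for o, c, su, a in zip(offers, conf, subj, accept):
            rows.append(
                {
                    "participant_id": pid,
                    "group": group,
                    "offer_id": o.offer_id,
                    "ee_band": o.ee_band,
                    "reward": o.reward,
                    "ee_opt": o.ee_opt,
                    "confidence": int(c),
                    "subjective_uncertainty": float(su),
                    "accept": int(a),
                }
            )
    return pd.DataFrame(rows)
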