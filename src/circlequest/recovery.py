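"""End-to-end recovery studies on simulated cohorts.

These studies close the loop over the whole pipeline: simulate a cohort
with known group structure, re-analyse it blind (observer -> efficiency
fit -> behavioural markers -> permutation contrasts), and ask whether the
configured effects are recovered. The headline design mirrors the study
population: the SCI group samples faster (shorter inter-touch intervals)
and more extensively (lower stopping threshold), while the informative-
touch probability q — and therefore sampling efficiency — is identical
across groups, so a sound pipeline must flag the speed and extent
contrasts and must *not* flag an efficiency difference.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .metrics import permutation_group_contrast
from .pipeline import _isi_per_participant, compute_trajectories, fit_efficiency_all
from .simulate import CohortConfig, simulate_cohort
from .task import TaskConfig

__all__ = ["replicate_contrasts", "run_recovery_study", "alpha_q_sweep"]

#: Desk-scale study conditions: analysis stride 8 px, one 5-trial run of
#: each of the four condition blocks per participant.
RECOVERY_TASK = TaskConfig(grid_stride=8.0, trials_per_block=5)


def replicate_contrasts(
    cohort: CohortConfig, task: TaskConfig, stat_seed: int
) -> dict:
    """Simulate one cohort and test the three group contrasts.

    Returns the SCI-minus-control difference and permutation p-value for
    mean paid samples, mean inter-touch interval, and fitted alpha.
    """
    data = simulate_cohort(cohort, task, include_passive=False)
    groups = data.questionnaires.set_index("participant_id")["group"]

    mean_samples = data.trials.groupby("participant_id")["n_paid_samples"].mean()
    mean_isi = _isi_per_participant(data.samples)
    trajectories = compute_trajectories(data, task)
    efficiency, _ = fit_efficiency_all(trajectories)
    alpha = efficiency.set_index("participant_id")["alpha"]

    rng = np.random.default_rng(stat_seed)
    out = {}
    for name, series in (
        ("samples", mean_samples),
        ("isi", mean_isi),
        ("alpha", alpha),
    ):
        df = pd.DataFrame({"v": series, "g": groups}).dropna()
        diff, p = permutation_group_contrast(
            df["v"].to_numpy(), df["g"].to_numpy(), rng=rng, reference="control"
        )
        out[f"{name}_diff"] = diff
        out[f"{name}_p"] = p
    return out


def run_recovery_study(
    n_replicates: int = 100,
    seed: int = 0,
    cohort: CohortConfig | None = None,
    task: TaskConfig | None = None,
) -> pd.DataFrame:
    """Replicate cohorts and collect contrast outcomes, one row each.

    The default cohort is the study structure: 27 controls + 27 SCI,
    2-SD group shifts on the inter-touch interval and stopping threshold,
    identical q.
    """
    if cohort is None:
        cohort = CohortConfig()
    if task is None:
        task = RECOVERY_TASK
    rows = []
    for i in range(n_replicates):
        rep_cohort = replace(cohort, seed=seed + 1000 * i)
        rows.append(
            replicate_contrasts(rep_cohort, task, stat_seed=seed + 1000 * i + 1)
        )
    return pd.DataFrame(rows)


def alpha_q_sweep(
    n_agents: int = 20,
    n_trials: int = 60,
    seed: int = 0,
    task: TaskConfig | None = None,
) -> pd.DataFrame:
    """Fitted extraction rate as a function of the agent's policy quality.

    Simulates agents whose informative-touch probability q sweeps 0..1
    (all else equal) and refits alpha from their trials; a sound
    efficiency measure must rank agents by q.
    """
    from .efficiency import fit_extraction_rate
    from .observer import ee_trajectory, init_prior
    from .simulate import AgentParams, simulate_trial
    from .task import Condition

    if task is None:
        task = RECOVERY_TASK
    rng = np.random.default_rng(seed)
    prior = init_prior(task)
    cond = Condition("high", "low")
    rows = []
    for q in np.linspace(0.0, 1.0, n_agents):
        agent = AgentParams(
            isi_mu=float(np.log(1.7)), isi_sigma=0.35, q=float(q),
            stop_threshold=2.0, lapse=0.05,
        )
        trajs = []
        for t in range(n_trials):
            trial = simulate_trial(agent, cond, task, rng, trial_id=t, prior=prior)
            trajs.append(ee_trajectory(trial, task))
        fit = fit_extraction_rate(trajs)
        rows.append({"q": float(q), "alpha": fit.alpha})
    return pd.DataFrame(rows)
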