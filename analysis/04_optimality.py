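#!/usr/bin/env python
"""Optimal stopping analysis: how far does sampling deviate from s*?

For every participant and condition, the expected-value curve implied by
their fitted efficiency gives the optimal paid-sample count s*; deviation
is the mean acquired samples minus s* (positive = over-sampling). Writes
results/cohort/optimality.csv and prints the condition breakdown.
"""

import pandas as pd

from circlequest.optimality import deviation_from_optimal
from circlequest.pipeline import (
    attach_condition_levels,
    fit_efficiency_all,
    load_dataset,
)
from circlequest.task import TaskConfig

DATADIR = "results/cohort"


def main() -> None:
    task = TaskConfig(grid_stride=8.0)
    data = load_dataset(DATADIR)
    traj = pd.read_csv(f"{DATADIR}/ee_trajectories.csv")
    _, fits = fit_efficiency_all(traj)
    trials = attach_condition_levels(data.trials, task)
    table = deviation_from_optimal(trials, fits, task)
    table.to_csv(f"{DATADIR}/optimality.csv", index=False, float_format="%.6g")
    merged = table.merge(
        data.questionnaires[["participant_id", "group"]], on="participant_id"
    )
    print("mean deviation from optimal sampling (s - s*):")
    pivot = merged.pivot_table(
        index=["R0_level", "cost_level"], columns="group", values="deviation"
    )
    print(pivot.round(2).to_string())


if __name__ == "__main__":
    main()
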