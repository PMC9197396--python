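"""Optimal stopping: expected-value curves and deviation from optimality.

Given a participant's fitted efficiency, the expected value of stopping
after ``s`` *paid* samples replaces the realised error in the scoring rule
with the model-predicted expected error:

    EV(s) = R0 - s * eta_s - eta_e * EE_hat(s + 1)

``s`` counts paid touches, so ``s + 1`` dots are on screen (the initial
dot is free). A softmax over the EV values — in raw credit units, unit
temperature — gives the stopping distribution of a rational agent, and the
optimal sample count ``s_star`` is the (smallest) argmax of EV, which is
also the mode of that distribution. Deviation from optimality is the
participant's mean paid sample count minus ``s_star`` for that condition:
positive values are over-sampling, negative under-sampling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .efficiency import EfficiencyFit, predict_ee
from .task import Condition, TaskConfig

__all__ = [
    "EVCurve",
    "expected_value_curve",
    "stopping_distribution",
    "optimal_sample_count",
    "deviation_from_optimal",
]

logger = logging.getLogger(__name__)

_S_MAX_CAP = 60
_EE_TAIL_RTOL = 1e-3  # s_max: EE within 0.1% of the asymptote


@dataclass
class EVCurve:
    """Expected value and stopping probability per paid-sample count."""

    ev: np.ndarray  # credits, index = paid samples 0..s_max
    stop_prob: np.ndarray  # softmax of ev
    s_star: int  # smallest argmax of ev
    condition: Condition | None = None


def _default_s_max(fit: EfficiencyFit) -> int:
    """Smallest s where the predicted EE is within 0.1% of EE_inf (cap 60)."""
    for s in range(1, _S_MAX_CAP + 1):
        excess = predict_ee(fit, s + 1) - fit.ee_inf
        if abs(excess) <= _EE_TAIL_RTOL * fit.ee_inf:
            return s
    return _S_MAX_CAP


def expected_value_curve(
    fit: EfficiencyFit,
    R0: float,
    eta_s: float,
    eta_e: float,
    s_max: int | None = None,
    condition: Condition | None = None,
) -> EVCurve:
    """EV(s) for s = 0..s_max paid samples, with stopping distribution."""
    if s_max is None:
        s_max = _default_s_max(fit)
    if s_max < 1:
        raise ValueError("s_max must be at least 1")
    s = np.arange(0, s_max + 1)
    ev = R0 - s * eta_s - eta_e * predict_ee(fit, s + 1)
    p = stopping_distribution(ev)
    return EVCurve(ev=ev, stop_prob=p, s_star=optimal_argmax(ev), condition=condition)


def stopping_distribution(ev: np.ndarray) -> np.ndarray:
    """Softmax of the EV values (unit temperature), overflow-safe."""
    ev = np.asarray(ev, dtype=float)
    if ev.size == 0:
        raise ValueError("empty EV vector")
    if not np.all(np.isfinite(ev)):
        raise ValueError("EV values must be finite")
    z = np.exp(ev - ev.max())
    return z / z.sum()


def optimal_argmax(ev: np.ndarray) -> int:
    """Smallest index maximising EV (np.argmax returns the first maximum)."""
    return int(np.argmax(ev))


def optimal_sample_count(curve: EVCurve) -> int:
    """The optimal number of paid samples: the smallest argmax of EV."""
    return optimal_argmax(curve.ev)


def deviation_from_optimal(
    trials: pd.DataFrame,
    fits: dict[str, EfficiencyFit],
    config: TaskConfig,
) -> pd.DataFrame:
    """Per participant and condition: mean paid samples minus s_star.

    ``trials`` needs columns participant_id, R0_level, cost_level,
    n_paid_samples. Participants missing from ``fits`` or conditions with
    no trials are skipped with a warning.
    """
    rows = []
    for (pid, r0_level, cost_level), sub in trials.groupby(
        ["participant_id", "R0_level", "cost_level"], sort=True
    ):
        fit = fits.get(pid)
        if fit is None:
            logger.warning("participant %s has no efficiency fit; skipped", pid)
            continue
        if sub.empty:  # pragma: no cover - groupby yields non-empty groups
            continue
        curve = expected_value_curve(
            fit,
            R0=config.initial_credit(r0_level),
            eta_s=config.sample_cost(cost_level),
            eta_e=config.error_cost,
        )
        mean_s = float(sub["n_paid_samples"].mean())
        rows.append(
            {
                "participant_id": pid,
                "R0_level": r0_level,
                "cost_level": cost_level,
                "mean_samples": mean_s,
                "s_star": curve.s_star,
                "deviation": mean_s - curve.s_star,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "participant_id",
            "R0_level",
            "cost_level",
            "mean_samples",
            "s_star",
            "deviation",
        ],
    )
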