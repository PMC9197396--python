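"""Sampling-efficiency model: exponential decay of expected error.

Across a participant's trials, uncertainty (EE at the ideal placement)
falls roughly exponentially with each successive dot. The model

    EE_hat(s) = (EE_1 - EE_inf) * (1 - alpha)**(s - 1) + EE_inf

has two free parameters: the information extraction rate ``alpha`` in
(0, 1) — the per-sample proportional reduction of excess uncertainty, the
participant's efficiency index — and the asymptote ``EE_inf`` > 0, the
floor imposed by task geometry. The baseline ``EE_1`` is not fitted: it is
the participant's mean first-dot EE across trials. ``s`` counts dots on
the screen, with the free initial dot as s = 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = ["EfficiencyFit", "fit_extraction_rate", "predict_ee"]

_ALPHA_LO = 1e-6
_ALPHA_HI = 1.0 - 1e-6
_EEINF_LO = 1e-6


@dataclass(frozen=True)
class EfficiencyFit:
    """Per-participant parameters of the EE decay model."""

    alpha: float  # extraction rate, in (0, 1)
    ee_inf: float  # asymptotic EE, px
    baseline: float  # mean first-dot EE across trials, px
    sse: float  # summed squared residual of the fit, px^2


def predict_ee(fit: EfficiencyFit, s: int | np.ndarray) -> float | np.ndarray:
    """Model EE at dot count ``s`` (s = 1 is the free initial dot)."""
    s = np.asarray(s)
    if np.any(s < 1):
        raise ValueError("dot count must be at least 1")
    out = (fit.baseline - fit.ee_inf) * (1.0 - fit.alpha) ** (s - 1) + fit.ee_inf
    return float(out) if out.ndim == 0 else out


def _flatten(trajectories: Sequence[Sequence[float]]) -> tuple[np.ndarray, np.ndarray]:
    s_idx, ee = [], []
    for traj in trajectories:
        for k, v in enumerate(traj, start=1):
            s_idx.append(k)
            ee.append(v)
    return np.asarray(s_idx, dtype=float), np.asarray(ee, dtype=float)


def fit_extraction_rate(
    trajectories: Sequence[Sequence[float]],
) -> EfficiencyFit:
    """Least-squares fit of (alpha, EE_inf) to one participant's EE data.

    ``trajectories`` holds one EE-per-dot list per trial. The baseline is
    the mean first-dot EE over all trials; (alpha, EE_inf) minimise the
    summed squared error between the observed EE values and the decay
    curve, pooling every trial and dot index. A coarse grid multistart
    followed by bounded local refinement guards against local minima in
    the 2-parameter landscape.
    """
    trajectories = [list(t) for t in trajectories if len(t) > 0]
    if not trajectories:
        raise ValueError("no trajectories to fit")
    if all(len(t) < 2 for t in trajectories):
        raise ValueError("all trajectories have a single point; nothing to fit")

    baseline = float(np.mean([t[0] for t in trajectories]))
    s_idx, ee = _flatten(trajectories)
    ee_inf_hi = max(baseline, _EEINF_LO * 2)

    def residuals(theta: np.ndarray) -> np.ndarray:
        a, e_inf = theta
        return (baseline - e_inf) * (1.0 - a) ** (s_idx - 1) + e_inf - ee

    # coarse multistart grid; the lower alpha bound is included first so that
    # decay-free (flat) data resolves to the smallest-alpha solution
    alphas = np.concatenate([[_ALPHA_LO], np.linspace(0.02, 0.95, 12)])
    einfs = np.linspace(_EEINF_LO, ee_inf_hi * 0.95, 10)
    best, best_sse = None, np.inf
    for a in alphas:
        for e in einfs:
            sse = float(np.sum(residuals(np.array([a, e])) ** 2))
            if sse < best_sse:
                best, best_sse = (a, e), sse

    sol = least_squares(
        residuals,
        x0=np.array(best),
        bounds=([_ALPHA_LO, _EEINF_LO], [_ALPHA_HI, ee_inf_hi]),
        xtol=1e-12,
        ftol=1e-12,
        gtol=1e-12,
    )
    alpha, ee_inf = (float(v) for v in sol.x)
    sse = float(np.sum(sol.fun**2))
    return EfficiencyFit(alpha=alpha, ee_inf=ee_inf, baseline=baseline, sse=sse)
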