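"""Behavioural markers and cohort statistics.

Covers the inter-sampling interval (sampling-speed index), the passive
task's subjective-uncertainty score, the affective-burden composite
(first principal component of standardised depression and anxiety
scores), partial Spearman correlations with permutation p-values, a
permutation contrast for two-group comparisons, and Bonferroni
correction for families of tests.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from .task import Trial

__all__ = [
    "inter_sampling_interval",
    "subjective_uncertainty",
    "affective_burden",
    "AffectiveBurdenResult",
    "partial_spearman",
    "permutation_group_contrast",
    "bonferroni_threshold",
]

logger = logging.getLogger(__name__)

DEFAULT_PERMUTATIONS = 10_000


def inter_sampling_interval(trial: Trial) -> float:
    """Mean time between consecutive paid touches, in seconds.

    Shorter ISI means faster sampling. Undefined (NaN) for trials with
    fewer than two paid touches; such trials are excluded from
    aggregation.
    """
    ts = np.array([s.t for s in trial.samples if s.paid])
    if ts.size < 2:
        logger.debug(
            "trial %s has %d paid touches; ISI undefined", trial.trial_id, ts.size
        )
        return float("nan")
    return float(np.mean(np.diff(ts)))


def subjective_uncertainty(confidence_ratings: np.ndarray) -> np.ndarray:
    """Z-scored, sign-flipped confidence ratings (per participant).

    Higher confidence maps to lower subjective uncertainty; the output has
    mean 0 and sample SD 1 within the participant. Constant ratings yield
    all zeros with a warning.
    """
    x = np.asarray(confidence_ratings, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two ratings")
    sd = x.std(ddof=1)
    if sd == 0:
        warnings.warn(
            "constant confidence ratings; subjective uncertainty set to 0",
            stacklevel=2,
        )
        return np.zeros_like(x)
    return -(x - x.mean()) / sd


@dataclass
class AffectiveBurdenResult:
    """PC1 composite of standardised depression and anxiety scores."""

    scores: np.ndarray  # PC1 score per participant, higher = more burdened
    variance_explained: float  # % of total variance on PC1
    loadings: np.ndarray  # (2,) PC1 loadings on (depression, anxiety)


def affective_burden(bdi: np.ndarray, hads_anx: np.ndarray) -> AffectiveBurdenResult:
    """First principal component of standardised (BDI-II, HADS-anxiety).

    Both scores are z-standardised, so the PCA acts on their correlation
    structure; for two standardised variables PC1 explains
    100 * (1 + |r|) / 2 percent of the total variance. The component is
    oriented so that higher scores mean greater affective burden (positive
    loading on depression; on both scores when they correlate positively).
    """
    bdi = np.asarray(bdi, dtype=float)
    hads_anx = np.asarray(hads_anx, dtype=float)
    if bdi.shape != hads_anx.shape or bdi.ndim != 1:
        raise ValueError("bdi and hads_anx must be 1-D vectors of equal length")
    if bdi.size < 3:
        raise ValueError("need at least 3 paired observations")
    X = np.column_stack([bdi, hads_anx])
    X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    pca = PCA(n_components=2)
    scores = pca.fit_transform(X)
    load = pca.components_[0]
    # orient: positive on depression (and on both when positively correlated)
    if load[0] < 0:
        load = -load
        scores[:, 0] = -scores[:, 0]
    var = 100.0 * pca.explained_variance_ratio_[0]
    return AffectiveBurdenResult(
        scores=scores[:, 0], variance_explained=float(var), loadings=load
    )


def _rank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, axis=0)


def _residualise(y: np.ndarray, Z: np.ndarray) -> np.ndarray:
    """Least-squares residual of y on [1, Z]."""
    design = np.column_stack([np.ones(len(y)), Z])
    beta, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < design.shape[1]:
        raise ValueError("rank-deficient covariate matrix")
    return y - design @ beta


def partial_spearman(
    x: np.ndarray,
    y: np.ndarray,
    covariates: np.ndarray | None = None,
    n_permutations: int = DEFAULT_PERMUTATIONS,
    rng: np.random.Generator | int | None = 0,
) -> tuple[float, float]:
    """Spearman correlation of x and y controlling for covariates.

    All variables are rank-transformed, x and y are residualised on the
    covariates by least squares, and the statistic is the Pearson
    correlation of the residuals. The two-sided p-value comes from
    permuting the pairing of the residuals (``n_permutations`` draws,
    add-one correction), so it is exact under exchangeability and makes no
    normality assumption.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if y.size != n:
        raise ValueError("x and y must have equal length")
    if covariates is None:
        Z = np.empty((n, 0))
    else:
        Z = np.asarray(covariates, dtype=float)
        if Z.ndim == 1:
            Z = Z[:, None]
    if n < Z.shape[1] + 3:
        raise ValueError("too few observations for the number of covariates")
    rx = _residualise(_rank(x), _rank(Z) if Z.size else Z)
    ry = _residualise(_rank(y), _rank(Z) if Z.size else Z)
    sx = np.linalg.norm(rx)
    sy = np.linalg.norm(ry)
    if sx == 0 or sy == 0:
        raise ValueError("degenerate (constant) ranks after residualisation")
    rho = float(rx @ ry / (sx * sy))

    rng = np.random.default_rng(rng)
    perm = np.empty(n_permutations)
    ry_unit = ry / sy
    rx_unit = rx / sx
    shuffled = np.tile(ry_unit, (n_permutations, 1))
    shuffled = rng.permuted(shuffled, axis=1)
    perm = shuffled @ rx_unit
    p = (np.count_nonzero(np.abs(perm) >= abs(rho) - 1e-12) + 1) / (
        n_permutations + 1
    )
    return rho, float(p)


def permutation_group_contrast(
    values: np.ndarray,
    group_labels: np.ndarray,
    n_permutations: int = DEFAULT_PERMUTATIONS,
    rng: np.random.Generator | int | None = 0,
    reference: str | None = None,
) -> tuple[float, float]:
    """Difference of group means with a two-sided permutation p-value.

    The observed statistic is mean(other group) - mean(reference group);
    ``reference`` defaults to the first label in sorted order.
    Significance comes from shuffling the group labels
    (``n_permutations`` draws, add-one correction).
    """
    values = np.asarray(values, dtype=float)
    group_labels = np.asarray(group_labels)
    labels = np.unique(group_labels)
    if labels.size != 2:
        raise ValueError("exactly two groups are required")
    if reference is None:
        reference = labels[0]
    elif reference not in labels:
        raise ValueError(f"reference {reference!r} is not a group label")
    other = labels[labels != reference][0]
    mask_b = group_labels == other
    n_b = int(mask_b.sum())
    n_a = values.size - n_b
    if n_a < 2 or n_b < 2:
        raise ValueError("each group needs at least 2 observations")
    observed = values[mask_b].mean() - values[~mask_b].mean()

    rng = np.random.default_rng(rng)
    # mean_b - mean_a is affine in the permuted group-B sum
    total = values.sum()
    shuffled = np.tile(values, (n_permutations, 1))
    shuffled = rng.permuted(shuffled, axis=1)
    sum_b = shuffled[:, :n_b].sum(axis=1)
    diff = sum_b / n_b - (total - sum_b) / n_a
    p = (np.count_nonzero(np.abs(diff) >= abs(observed) - 1e-12) + 1) / (
        n_permutations + 1
    )
    return float(observed), float(p)


def bonferroni_threshold(
    p_values: np.ndarray, alpha: float = 0.05
) -> tuple[float, np.ndarray]:
    """Family-wise threshold alpha/k and the rejection flags at it."""
    p_values = np.asarray(p_values, dtype=float)
    if p_values.size == 0:
        raise ValueError("empty p-value family")
    reject, _, _, _ = multipletests(p_values, alpha=alpha, method="bonferroni")
    return alpha / p_values.size, reject
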