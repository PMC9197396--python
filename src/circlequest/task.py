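"""Task geometry, condition scheduling, and the trial scoring rule.

The task: a circle of fixed radius ``r`` is hidden inside a circular search
field. Touching the screen yields a purple dot if the touch lies inside the
hidden circle and a white dot otherwise. Each paid touch costs ``eta_s``
credits from an initial reserve ``R0``; at the end of the trial the distance
``e`` between the chosen placement and the true centre is charged at
``eta_e`` credits per pixel:

    score = R0 - s * eta_s - e * eta_e

Two levels each of ``R0`` and ``eta_s`` give four conditions, presented as
four blocks of 15 trials.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "TaskConfig",
    "Condition",
    "SampleEvent",
    "Trial",
    "PURPLE",
    "WHITE",
    "classify_sample",
    "score_trial",
    "block_schedule",
]

#: Colour labels for sample dots. Purple marks a touch inside the hidden
#: circle, white a touch outside it.
PURPLE = "purple"
WHITE = "white"


@dataclass(frozen=True)
class TaskConfig:
    """Geometry, costs, and timing of the active sampling task.

    The default field radius of 540 px is chosen so the hidden circle covers
    about 5.80 % of the search field (130 / sqrt(0.058) = 539.8 px).
    """

    field_radius: float = 540.0  # px
    circle_radius: float = 130.0  # px, hidden circle and placement disc
    dot_radius: float = 4.0  # px, cosmetic only
    error_cost: float = 1.2  # credits per px of localisation error
    sample_cost_levels: dict = field(
        default_factory=lambda: {"low": 1.0, "high": 5.0}
    )  # credits per paid sample
    initial_credit_levels: dict = field(
        default_factory=lambda: {"low": 95.0, "high": 130.0}
    )  # credits
    sampling_duration: float = 18.0  # s
    placement_duration: float = 6.0  # s
    trials_per_block: int = 15
    grid_stride: float = 4.0  # px, lattice spacing of the observer grid

    def __post_init__(self) -> None:
        if self.field_radius <= 0 or self.circle_radius <= 0 or self.dot_radius <= 0:
            raise ValueError("all lengths must be positive")
        if self.circle_radius >= self.field_radius:
            raise ValueError("circle_radius must be smaller than field_radius")
        if self.error_cost <= 0:
            raise ValueError("error_cost must be positive")
        if self.grid_stride < 1.0:
            raise ValueError("grid_stride must be at least 1 px")
        if self.trials_per_block < 1:
            raise ValueError("trials_per_block must be at least 1")

    @property
    def support_radius(self) -> float:
        """Radius within which the hidden-circle centre may lie.

        The hidden circle is always fully contained in the search field, so
        its centre is at most ``field_radius - circle_radius`` from the
        field centre.
        """
        return self.field_radius - self.circle_radius

    @property
    def circle_area_fraction(self) -> float:
        """Hidden-circle area as a fraction of the search-field area."""
        return (self.circle_radius / self.field_radius) ** 2

    def sample_cost(self, level: str) -> float:
        return self.sample_cost_levels[level]

    def initial_credit(self, level: str) -> float:
        return self.initial_credit_levels[level]


@dataclass(frozen=True)
class Condition:
    """One of the four (initial credit, sampling cost) blocks."""

    R0_level: str  # "low" | "high"
    cost_level: str  # "low" | "high"
    block_index: int = 0

    def __post_init__(self) -> None:
        if self.R0_level not in ("low", "high"):
            raise ValueError(f"invalid R0_level: {self.R0_level!r}")
        if self.cost_level not in ("low", "high"):
            raise ValueError(f"invalid cost_level: {self.cost_level!r}")


@dataclass(frozen=True)
class SampleEvent:
    """A single dot on the screen: location, colour, time, and whether paid.

    The initial purple dot shown at trial onset is stored with
    ``paid=False`` at ``t=0`` and is never charged the sampling cost.
    """

    x: float
    y: float
    colour: str  # PURPLE | WHITE
    t: float  # s from trial onset
    paid: bool = True

    @property
    def location(self) -> np.ndarray:
        return np.array([self.x, self.y], dtype=float)


@dataclass
class Trial:
    """One active-sampling trial: samples in time order plus the outcome."""

    trial_id: int
    condition: Condition
    hidden_center: tuple[float, float]
    samples: list[SampleEvent]
    placement: tuple[float, float]

    def __post_init__(self) -> None:
        ts = [s.t for s in self.samples]
        if ts != sorted(ts):
            raise ValueError("samples must be ordered by timestamp")
        if self.samples and self.samples[0].paid:
            raise ValueError("first sample must be the free initial dot")

    @property
    def paid_count(self) -> int:
        return sum(1 for s in self.samples if s.paid)

    @property
    def localisation_error(self) -> float:
        return math.dist(self.placement, self.hidden_center)

    def score(self, config: TaskConfig) -> float:
        return score_trial(
            config.initial_credit(self.condition.R0_level),
            config.sample_cost(self.condition.cost_level),
            self.paid_count,
            config.error_cost,
            self.localisation_error,
        )


def classify_sample(
    hidden_center: Sequence[float], touch: Sequence[float], r: float
) -> str:
    """Colour of the dot produced by touching ``touch``.

    Purple iff the touch is within ``r`` of the hidden centre (boundary
    inclusive), white otherwise.
    """
    if r <= 0:
        raise ValueError("circle radius must be positive")
    return PURPLE if math.dist(hidden_center, touch) <= r else WHITE


def score_trial(R0: float, eta_s: float, s: int, eta_e: float, e: float) -> float:
    """Trial score: initial reserve minus sampling and error costs.

    May be negative when costs exceed the reserve.
    """
    if s < 0:
        raise ValueError("paid sample count must be non-negative")
    if e < 0:
        raise ValueError("localisation error must be non-negative")
    return R0 - s * eta_s - e * eta_e


def block_schedule(rng: np.random.Generator | None = None) -> list[Condition]:
    """The four condition blocks, optionally in a randomised order.

    Every (R0, cost) pair appears in exactly one block, as in the
    counterbalanced design.
    """
    pairs = [(r0, c) for r0 in ("low", "high") for c in ("low", "high")]
    if rng is not None:
        order = rng.permutation(len(pairs))
        pairs = [pairs[i] for i in order]
    return [
        Condition(R0_level=r0, cost_level=c, block_index=i)
        for i, (r0, c) in enumerate(pairs)
    ]
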