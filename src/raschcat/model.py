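"""Rasch rating-scale model (RSM) core.

The RSM is a polytomous item-response model in which every item shares a
single set of category step calibrations (thresholds).  A person with
measure ``theta`` responding to an item of difficulty ``delta`` in
categories ``0..M`` has

    P(X = k)  proportional to  exp( sum_{j<=k} (theta - delta - tau_j) )

with the empty sum for ``k = 0`` equal to zero.  ``tau_j`` is the logit
point at which categories ``j-1`` and ``j`` are equally probable.  All
quantities live on one common logit (log-odds) scale.

This module provides the closed-form category probabilities, expected
scores, item information (the category-score variance), the response
log-likelihood, and Newton-Raphson maximum-likelihood estimation of the
person measure with its standard error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "RatingScale",
    "Item",
    "ItemBank",
    "AbilityEstimate",
    "category_probabilities",
    "adjacent_logit_probability",
    "expected_score",
    "item_information",
    "log_likelihood",
    "estimate_theta",
]

#: Hard bounds on person measures during estimation (logits).
THETA_BOUNDS = (-10.0, 10.0)
#: Largest Newton-Raphson step accepted per iteration (logits).
MAX_NR_STEP = 1.0
#: Score-unit adjustment applied to extreme (all-minimum / all-maximum)
#: raw scores before estimation, a standard Rasch convention.
EXTREME_ADJUSTMENT = 0.25


@dataclass(frozen=True)
class RatingScale:
    """Shared category structure: M step calibrations for M+1 categories.

    ``thresholds[j-1]`` is tau_j, the logit at which categories j-1 and j
    are equally probable.  Categories are coded 0..M internally.
    """

    thresholds: tuple[float, ...]

    def __post_init__(self) -> None:
        t = tuple(float(x) for x in self.thresholds)
        if len(t) < 1:
            raise ValueError("a rating scale needs at least one threshold (M >= 1)")
        if not all(math.isfinite(x) for x in t):
            raise ValueError("thresholds must be finite")
        object.__setattr__(self, "thresholds", t)

    @property
    def n_steps(self) -> int:
        return len(self.thresholds)

    @property
    def n_categories(self) -> int:
        return len(self.thresholds) + 1

    @property
    def cumulative(self) -> np.ndarray:
        """Partial sums (0, tau_1, tau_1+tau_2, ...), length M+1."""
        return np.concatenate(([0.0], np.cumsum(self.thresholds)))


@dataclass
class Item:
    """One questionnaire item located on the latent logit scale."""

    item_id: int
    label: str = ""
    difficulty: Optional[float] = None
    se: Optional[float] = None
    infit: Optional[float] = None
    outfit: Optional[float] = None
    status: str = "calibrated"

    def __post_init__(self) -> None:
        if self.item_id <= 0:
            raise ValueError("item_id must be a positive integer")
        if self.status not in ("calibrated", "misfit"):
            raise ValueError(f"unknown item status {self.status!r}")
        if self.status == "calibrated":
            if self.difficulty is None or not math.isfinite(self.difficulty):
                raise ValueError(
                    f"item {self.item_id}: calibrated items need a finite difficulty"
                )


@dataclass
class ItemBank:
    """A set of items sharing one rating scale (RSM parameterization)."""

    items: list[Item]
    scale: RatingScale

    def __post_init__(self) -> None:
        ids = [it.item_id for it in self.items]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate item_id in bank")
        if not any(it.status == "calibrated" for it in self.items):
            raise ValueError("bank needs at least one calibrated item")

    @property
    def calibrated(self) -> list[Item]:
        return [it for it in self.items if it.status == "calibrated"]

    def __len__(self) -> int:
        return len(self.items)

    def get(self, item_id: int) -> Item:
        for it in self.items:
            if it.item_id == item_id:
                return it
        raise KeyError(f"item {item_id} not in bank")


@dataclass
class AbilityEstimate:
    """Person measure theta (logits) with its standard error.

    ``se`` equals the reciprocal square root of the total test
    information at ``theta``.  ``extreme`` marks all-minimum or
    all-maximum raw-score patterns, whose finite estimate rests on the
    conventional 0.25 score-unit adjustment.
    """

    theta: float
    se: float
    n_items: int
    converged: bool = True
    extreme: bool = False


def _check_finite(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not math.isfinite(value):
            raise ValueError(f"{name} must be finite, got {value!r}")


def category_probabilities(
    theta: float, difficulty: float, scale: RatingScale
) -> np.ndarray:
    """Category probability vector over 0..M under the rating-scale model.

    Computed in closed form from the partial sums of theta - delta - tau_j,
    with exponents shifted by their maximum for numerical stability.
    """
    _check_finite(theta=theta, difficulty=difficulty)
    k = np.arange(scale.n_categories)
    logits = k * (theta - difficulty) - scale.cumulative
    logits -= logits.max()
    p = np.exp(logits)
    return p / p.sum()


def adjacent_logit_probability(theta: float, difficulty: float, tau_j: float) -> float:
    """P(X=j | X in {j-1, j}): the logistic of theta - delta - tau_j."""
    _check_finite(theta=theta, difficulty=difficulty, tau_j=tau_j)
    x = theta - difficulty - tau_j
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    e = math.exp(x)
    return e / (1.0 + e)


def expected_score(theta: float, difficulty: float, scale: RatingScale) -> float:
    """Model-expected category score, sum_k k * P_k, in (0, M)."""
    p = category_probabilities(theta, difficulty, scale)
    return float(np.arange(scale.n_categories) @ p)


def item_information(theta: float, difficulty: float, scale: RatingScale) -> float:
    """Fisher information of one item at theta (logit^-2).

    For the RSM this equals the variance of the category-score
    distribution, sum_k k^2 P_k - (sum_k k P_k)^2.
    """
    p = category_probabilities(theta, difficulty, scale)
    k = np.arange(scale.n_categories)
    mean = k @ p
    return float((k * k) @ p - mean * mean)


def _validate_responses(
    responses: Sequence[tuple[Item, int]], scale: RatingScale
) -> None:
    if not responses:
        raise ValueError("responses must be non-empty")
    m = scale.n_steps
    for item, x in responses:
        if item.status != "calibrated" or item.difficulty is None:
            raise ValueError(f"item {item.item_id} is not calibrated")
        if not (isinstance(x, (int, np.integer)) and 0 <= x <= m):
            raise ValueError(
                f"item {item.item_id}: category {x!r} outside 0..{m}"
            )


def log_likelihood(
    responses: Sequence[tuple[Item, int]], theta: float, scale: RatingScale
) -> float:
    """Log-probability of the observed categories at a fixed theta."""
    _validate_responses(responses, scale)
    _check_finite(theta=theta)
    total = 0.0
    for item, x in responses:
        p = category_probabilities(theta, item.difficulty, scale)
        total += math.log(p[x])
    return total


def estimate_theta(
    responses: Sequence[tuple[Item, int]],
    scale: RatingScale,
    init: float = 0.0,
    tol: float = 1e-3,
    max_iter: int = 50,
) -> AbilityEstimate:
    """Maximum-likelihood person measure by Newton-Raphson iteration.

    Iterates ``theta <- theta + (raw - sum E_i(theta)) / sum W_i(theta)``
    where ``E_i`` is the expected score and ``W_i`` the item information,
    until the update is below ``tol`` or ``max_iter`` is reached.  Steps
    are capped at 1 logit and theta is clamped to [-10, 10].  Extreme raw
    scores (all 0 or all M) are pulled 0.25 score units toward the
    interior before estimation and flagged ``extreme``.
    """
    _validate_responses(responses, scale)
    _check_finite(init=init)
    m = scale.n_steps
    raw = float(sum(x for _, x in responses))
    extreme = False
    if raw == 0.0:
        raw += EXTREME_ADJUSTMENT
        extreme = True
    elif raw == m * len(responses):
        raw -= EXTREME_ADJUSTMENT
        extreme = True

    lo, hi = THETA_BOUNDS
    theta = min(max(init, lo), hi)
    converged = False
    info = 0.0
    for _ in range(max_iter):
        expected = 0.0
        info = 0.0
        for item, _ in responses:
            expected += expected_score(theta, item.difficulty, scale)
            info += item_information(theta, item.difficulty, scale)
        step = (raw - expected) / info
        step = min(max(step, -MAX_NR_STEP), MAX_NR_STEP)
        theta = min(max(theta + step, lo), hi)
        if abs(step) < tol:
            converged = True
            break
    info = sum(item_information(theta, it.difficulty, scale) for it, _ in responses)
    return AbilityEstimate(
        theta=theta,
        se=1.0 / math.sqrt(info),
        n_items=len(responses),
        converged=converged,
        extreme=extreme,
    )
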