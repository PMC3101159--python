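"""Model-based response generation.

Person measures are drawn from a cohort law (normal by default, with the
option of an arbitrary quantile function) and item responses are drawn by
inverse-CDF sampling from the rating-scale-model category probabilities.
Everything flows through one seedable generator, so a run is fully
reproducible from (spec, bank, seed).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np

from .calibration import ResponseMatrix
from .model import Item, ItemBank, RatingScale, category_probabilities

__all__ = ["CohortSpec", "simulate_response", "simulate_cohort"]


@dataclass
class CohortSpec:
    """A simulated survey cohort on the latent logit scale.

    Defaults describe the reference hospital-employee calibration
    cohort: 300 respondents with person measures of mean 2.30 and
    standard deviation 1.99 logits.
    """

    n_persons: int = 300
    mean: float = 2.30
    sd: float = 1.99
    seed: Optional[int] = None
    quantile_fn: Optional[Callable[[np.ndarray], np.ndarray]] = None

    def __post_init__(self) -> None:
        if self.n_persons < 1:
            raise ValueError("n_persons must be >= 1")
        if not (self.sd >= 0):
            raise ValueError("sd must be non-negative")

    def draw_thetas(self, rng: np.random.Generator) -> np.ndarray:
        if self.quantile_fn is not None:
            return np.asarray(self.quantile_fn(rng.random(self.n_persons)), dtype=float)
        return rng.normal(self.mean, self.sd, self.n_persons)


def simulate_response(
    theta: float, item: Item, scale: RatingScale, rng: np.random.Generator
) -> int:
    """One category draw by inverse CDF over the model probabilities."""
    p = category_probabilities(theta, item.difficulty, scale)
    return int(np.searchsorted(np.cumsum(p), rng.random(), side="right"))


def simulate_cohort(
    spec: CohortSpec,
    bank: ItemBank,
    item_shift: Optional[dict[int, float]] = None,
) -> tuple[np.ndarray, ResponseMatrix]:
    """Draw true measures and a full person x item response matrix.

    ``item_shift`` adds per-item logit shifts to the generating
    difficulties (positive shift = harder to endorse), which emulates a
    localized year-on-year deterioration for group-comparison studies.
    """
    rng = np.random.default_rng(spec.seed)
    thetas = spec.draw_thetas(rng)
    items = bank.calibrated
    shift = item_shift or {}
    m1 = bank.scale.n_categories
    cum_tau = bank.scale.cumulative
    k = np.arange(m1)
    delta = np.array([it.difficulty + shift.get(it.item_id, 0.0) for it in items])

    logits = k[None, None, :] * (thetas[:, None, None] - delta[None, :, None]) - cum_tau
    logits -= logits.max(axis=2, keepdims=True)
    p = np.exp(logits)
    p /= p.sum(axis=2, keepdims=True)
    u = rng.random((spec.n_persons, len(items)))
    data = (p.cumsum(axis=2) < u[..., None]).sum(axis=2).astype(float)

    matrix = ResponseMatrix(
        person_ids=[f"P{i + 1:04d}" for i in range(spec.n_persons)],
        item_ids=[it.item_id for it in items],
        data=data,
        n_categories=m1,
    )
    return thetas, matrix
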