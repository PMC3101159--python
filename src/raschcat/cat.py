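"""Adaptive-test driver: item selection, stop rules, session log, person fit.

The session starts from a coarse measure mapped from the examinee's global
self-rating, administers a short burn-in at that measure, then re-estimates
the person measure after every response and always presents the
unadministered item with the most Fisher information at the provisional
measure.  The test stops when the standard error reaches the SEM target
(never before the minimum length), when the bank is exhausted or the
maximum length is reached, or — if enabled — when the running outfit
mean-square signals an aberrant respondent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .model import (
    AbilityEstimate,
    Item,
    ItemBank,
    estimate_theta,
    expected_score,
    item_information,
    category_probabilities,
)

__all__ = [
    "CatConfig",
    "CatStep",
    "CatSession",
    "BankExhaustedError",
    "initial_theta",
    "select_next_item",
    "should_stop",
    "run_cat",
    "person_fit",
]

DEFAULT_RATING_MAP = {1: -2.0, 2: -0.5, 3: 0.5, 4: 2.0}


class BankExhaustedError(RuntimeError):
    """No unadministered calibrated item remains."""


@dataclass
class CatConfig:
    """Adaptive-session policy.

    ``se_target`` is the SEM stop value in logits; the session never
    stops for precision before ``min_items``.  ``burn_in`` responses are
    collected at the initial mapped measure before estimation starts.
    ``abort_mnsq`` (off by default) aborts the session early when the
    running outfit exceeds it; ``aberrance_mnsq`` only flags the final
    record as aberrant.
    """

    se_target: float = 0.68
    min_items: int = 10
    max_items: Optional[int] = None  # None = bank size
    burn_in: int = 3
    initial_rating_map: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_RATING_MAP)
    )
    aberrance_mnsq: float = 2.0
    z_flag: float = 1.96
    abort_mnsq: Optional[float] = None

    def validate(self, bank_size: int) -> None:
        max_items = self.max_items if self.max_items is not None else bank_size
        if not (1 <= self.burn_in < self.min_items <= max_items <= bank_size):
            raise ValueError(
                "need 1 <= burn_in < min_items <= max_items <= bank size "
                f"(got burn_in={self.burn_in}, min={self.min_items}, "
                f"max={max_items}, bank={bank_size})"
            )
        if not (self.se_target >= 0):
            raise ValueError("se_target must be non-negative")


@dataclass
class CatStep:
    """One administered item, mirroring the seven report columns."""

    step: int
    item_id: int
    difficulty: float
    prob_observed: float     # model probability of the response, pre-response measure
    observed: int
    expected: float          # expected score at the pre-response measure
    theta: float             # post-response measure (initial value during burn-in)
    se: Optional[float]      # None until estimation begins
    outfit: Optional[float]  # running outfit MNSQ, None during burn-in
    unexpected: bool = False  # |z| > z_flag at the final measure


@dataclass
class CatSession:
    steps: list[CatStep]
    final: AbilityEstimate
    stop_reason: str  # se_met | max_items | aberrant
    aberrant: bool
    global_rating: int
    config: CatConfig
    outfit: float = math.nan

    @property
    def administered(self) -> list[int]:
        return [s.item_id for s in self.steps]

    @property
    def responses(self) -> list[tuple[int, int]]:
        return [(s.item_id, s.observed) for s in self.steps]


def initial_theta(global_rating: int, config: CatConfig) -> float:
    """Starting measure mapped from the 1-4 global self-rating."""
    try:
        return float(config.initial_rating_map[int(global_rating)])
    except (KeyError, ValueError, TypeError):
        raise ValueError(
            f"global rating {global_rating!r} not in map "
            f"{sorted(config.initial_rating_map)}"
        ) from None


def select_next_item(
    theta: float, bank: ItemBank, administered: set[int] | Sequence[int]
) -> Item:
    """The unadministered calibrated item with the most information at theta.

    Ties break toward the lowest item id.
    """
    seen = set(administered)
    best: Optional[Item] = None
    best_info = -1.0
    for item in sorted(bank.calibrated, key=lambda it: it.item_id):
        if item.item_id in seen:
            continue
        info = item_information(theta, item.difficulty, bank.scale)
        if info > best_info + 1e-15:
            best, best_info = item, info
    if best is None:
        raise BankExhaustedError("all calibrated items administered")
    return best


def should_stop(
    n_items: int,
    se: Optional[float],
    running_outfit: Optional[float],
    config: CatConfig,
    bank_size: int,
) -> tuple[bool, Optional[str]]:
    """Termination decision after a response has been scored."""
    max_items = config.max_items if config.max_items is not None else bank_size
    if (
        config.abort_mnsq is not None
        and running_outfit is not None
        and running_outfit > config.abort_mnsq
    ):
        return True, "aberrant"
    if n_items >= config.min_items and se is not None and se <= config.se_target:
        return True, "se_met"
    if n_items >= max_items:
        return True, "max_items"
    return False, None


def run_cat(
    responder: Callable[[Item], int],
    bank: ItemBank,
    config: Optional[CatConfig] = None,
    global_rating: int = 3,
) -> CatSession:
    """Administer a full adaptive session and return its log.

    ``responder`` is called once per administered item and must return a
    category in 0..M.  During the burn-in the provisional measure stays
    at the initial mapped value but items are still chosen by maximum
    information there.
    """
    cfg = config or CatConfig()
    bank_size = len(bank.calibrated)
    cfg.validate(bank_size)
    scale = bank.scale
    m = scale.n_steps

    theta = initial_theta(global_rating, cfg)
    steps: list[CatStep] = []
    responses: list[tuple[Item, int]] = []
    administered: set[int] = set()
    est: Optional[AbilityEstimate] = None
    stop_reason: Optional[str] = None

    while True:
        item = select_next_item(theta, bank, administered)
        x = responder(item)
        if not (isinstance(x, (int, np.integer)) and 0 <= x <= m):
            raise ValueError(
                f"session aborted: responder returned {x!r} for item "
                f"{item.item_id}; expected a category in 0..{m}"
            )
        prob = float(category_probabilities(theta, item.difficulty, scale)[x])
        exp = expected_score(theta, item.difficulty, scale)
        administered.add(item.item_id)
        responses.append((item, int(x)))

        se: Optional[float] = None
        outfit: Optional[float] = None
        if len(responses) > cfg.burn_in:
            est = estimate_theta(responses, scale, init=theta)
            theta = est.theta
            se = est.se
            outfit = _outfit_at(responses, theta, scale)
        steps.append(
            CatStep(
                step=len(responses),
                item_id=item.item_id,
                difficulty=item.difficulty,
                prob_observed=prob,
                observed=int(x),
                expected=exp,
                theta=theta,
                se=se,
                outfit=outfit,
            )
        )
        stop, stop_reason = should_stop(len(responses), se, outfit, cfg, bank_size)
        if stop:
            break

    final = estimate_theta(responses, scale, init=theta)
    session = CatSession(
        steps=steps,
        final=final,
        stop_reason=stop_reason or "max_items",
        aberrant=False,
        global_rating=global_rating,
        config=cfg,
    )
    outfit, flags, aberrant = person_fit(session, bank)
    session.outfit = outfit
    session.aberrant = aberrant or session.stop_reason == "aberrant"
    for step, flagged in zip(session.steps, flags):
        step.unexpected = flagged
    return session


def _outfit_at(responses, theta: float, scale) -> float:
    z2 = []
    for item, x in responses:
        e = expected_score(theta, item.difficulty, scale)
        w = item_information(theta, item.difficulty, scale)
        z2.append((x - e) ** 2 / max(w, 1e-12))
    return float(np.mean(z2))


def person_fit(
    session: CatSession, bank: ItemBank
) -> tuple[float, list[bool], bool]:
    """Outfit MNSQ at the final measure, per-step flags, aberrance flag.

    The outfit is the mean squared standardized residual across all
    administered items, evaluated at the final person measure.  A step
    is flagged unexpected when |z| exceeds the configured cutoff
    (two-sided 5% under the model); the session is aberrant when the
    outfit exceeds the configured mean-square threshold.
    """
    if not session.steps:
        raise ValueError("session has no steps")
    theta = session.final.theta
    scale = bank.scale
    z2, flags = [], []
    for step in session.steps:
        item = bank.get(step.item_id)
        e = expected_score(theta, item.difficulty, scale)
        w = item_information(theta, item.difficulty, scale)
        z = (step.observed - e) / math.sqrt(max(w, 1e-12))
        z2.append(z * z)
        flags.append(abs(z) > session.config.z_flag)
    outfit = float(np.mean(z2))
    return outfit, flags, outfit > session.config.aberrance_mnsq
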