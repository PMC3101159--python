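"""Joint calibration of items, thresholds and persons, with diagnostics.

Estimation is joint maximum likelihood (JMLE): alternating Newton-Raphson
updates of person measures, item difficulties and the shared step
calibrations until the largest parameter change falls below a tolerance.
Missing cells are simply omitted from every sum.

Diagnostics cover the quantities a Rasch analyst inspects before trusting
a scale: infit/outfit mean-squares with Wilson-Hilferty standardized Z,
person-separation reliability, the SEM-based CAT stop value, principal
component analysis of standardized residuals (unidimensionality), and the
Linacre category-functioning guidelines.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .model import (
    AbilityEstimate,
    Item,
    ItemBank,
    RatingScale,
    estimate_theta,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ResponseMatrix",
    "CalibrationConfig",
    "CalibrationResult",
    "DimensionalitySummary",
    "CategoryDiagnostics",
    "FitTable",
    "jmle_calibrate",
    "fit_statistics",
    "misfit_filter",
    "separation_reliability",
    "sem_stop_value",
    "residual_pca",
    "category_diagnostics",
]


@dataclass
class ResponseMatrix:
    """Persons x items integer categories with missing support.

    ``data`` is a float array (NaN = missing) of shape
    ``(len(person_ids), len(item_ids))`` holding categories 0..M.
    """

    person_ids: list[str]
    item_ids: list[int]
    data: np.ndarray
    n_categories: Optional[int] = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.shape != (len(self.person_ids), len(self.item_ids)):
            raise ValueError("data shape does not match id lists")
        obs = self.data[~np.isnan(self.data)]
        if obs.size:
            if np.any(obs < 0) or np.any(obs != np.round(obs)):
                raise ValueError("categories must be non-negative integers")
            if self.n_categories is None:
                self.n_categories = int(obs.max()) + 1
            elif obs.max() > self.n_categories - 1:
                raise ValueError(
                    f"category {int(obs.max())} outside 0..{self.n_categories - 1}"
                )
        rows_ok = (~np.isnan(self.data)).sum(axis=1) > 0
        cols_ok = (~np.isnan(self.data)).sum(axis=0) > 0
        if rows_ok.sum() < 2 or cols_ok.sum() < 2:
            raise ValueError("need at least 2 persons and 2 items with data")

    @property
    def n_persons(self) -> int:
        return len(self.person_ids)

    @property
    def n_items(self) -> int:
        return len(self.item_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.data, index=self.person_ids, columns=self.item_ids)


@dataclass
class CalibrationConfig:
    """Convergence control for :func:`jmle_calibrate`."""

    tol: float = 1e-4          # largest parameter change, logits
    max_iter: int = 500
    person_tol: float = 1e-3   # final person-measure NR tolerance
    person_max_iter: int = 50
    # Wright's first-order JMLE bias correction: shrink the centered
    # item/threshold structure by (L-1)/L for test length L.  JMLE
    # overdisperses structural estimates because person measures are
    # estimated jointly from finitely many responses.
    bias_correction: bool = True


@dataclass
class DimensionalitySummary:
    """Residual-PCA unidimensionality evidence.

    Common criteria: variance explained by the measures >= 60%, first
    residual contrast eigenvalue < 3, and first-contrast variance < 5%.
    All three are reported; policy is left to the caller.
    """

    variance_explained_by_measures: float  # percent
    first_contrast_eigenvalue: float
    first_contrast_variance: float  # percent


@dataclass
class CategoryDiagnostics:
    """Category-functioning evidence against the Linacre guidelines.

    Flags (True = pass, None = undetermined for lack of observations):
      1. average person measures advance monotonically with category;
      2. step calibrations advance;
      3. adjacent steps advance by at least 1.4 logits;
      4. adjacent steps advance by less than 5.0 logits.
    """

    average_measures_per_category: list[Optional[float]]
    threshold_advances: list[float]
    guideline_flags: dict[str, Optional[bool]]


@dataclass
class FitTable:
    """Per-item and per-person fit statistics (MNSQ and standardized Z)."""

    items: pd.DataFrame    # index item_id: infit, outfit, infit_z, outfit_z
    persons: pd.DataFrame  # index person_id: same columns


@dataclass
class CalibrationResult:
    bank: ItemBank
    person_measures: list[AbilityEstimate]
    person_ids: list[str]
    reliability: float
    misfit_item_ids: list[int]
    fit: FitTable
    dimensionality: DimensionalitySummary
    category_report: CategoryDiagnostics
    converged: bool = True
    n_iter: int = 0
    dropped_items: list[int] = field(default_factory=list)
    dropped_persons: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# vectorized RSM kernels (persons x items x categories)
# ---------------------------------------------------------------------------

def _probs(theta: np.ndarray, delta: np.ndarray, tau: np.ndarray) -> np.ndarray:
    """P[n, i, k] for all persons, items and categories, stably."""
    k = np.arange(tau.size + 1)
    cum = np.concatenate(([0.0], np.cumsum(tau)))
    logits = k[None, None, :] * (theta[:, None, None] - delta[None, :, None]) - cum
    logits -= logits.max(axis=2, keepdims=True)
    p = np.exp(logits)
    return p / p.sum(axis=2, keepdims=True)


def _moments(p: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Expected score E, variance W and fourth central moment C per cell."""
    k = np.arange(p.shape[2])
    e = p @ k
    w = p @ (k * k) - e * e
    c = np.einsum("nik,nik->ni", p, (k[None, None, :] - e[..., None]) ** 4)
    return e, w, c


# ---------------------------------------------------------------------------
# JMLE
# ---------------------------------------------------------------------------

def jmle_calibrate(
    matrix: ResponseMatrix,
    anchors: Optional[ItemBank] = None,
    config: Optional[CalibrationConfig] = None,
) -> CalibrationResult:
    """Estimate item difficulties, shared thresholds and person measures.

    Unanchored runs are identified by centering: mean item difficulty = 0
    and thresholds summing to 0 (the RSM is invariant to a joint location
    shift between difficulties and thresholds, and between persons and
    items).  When ``anchors`` is given, its item difficulties are held
    fixed and no centering is applied, so the threshold location is
    identified by the anchors.

    Items or persons whose observed responses show no variance (all in
    one category) are dropped from parameter estimation with a logged
    warning; dropped persons still receive a final measure, flagged
    extreme where applicable.  Deterministic given inputs.
    """
    cfg = config or CalibrationConfig()
    frame = matrix.to_frame()
    m_cat = matrix.n_categories
    if anchors is not None:
        m_cat = anchors.scale.n_categories
    if m_cat is None or m_cat < 2:
        raise ValueError("need at least 2 observed categories to calibrate")
    m = m_cat - 1

    data = frame.to_numpy(dtype=float)
    obs = ~np.isnan(data)

    # drop no-variance items, then persons (extreme or constant patterns)
    item_var = np.array(
        [np.nanvar(data[:, j]) if obs[:, j].any() else 0.0 for j in range(data.shape[1])]
    )
    keep_items = item_var > 0
    dropped_items = [matrix.item_ids[j] for j in np.where(~keep_items)[0]]
    if dropped_items:
        logger.warning("dropping no-variance items from calibration: %s", dropped_items)
        warnings.warn(f"dropping no-variance items: {dropped_items}", stacklevel=2)
    sub = data[:, keep_items]
    sub_obs = ~np.isnan(sub)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        person_var = np.nanvar(sub, axis=1)
    person_var = np.where(np.isnan(person_var), 0.0, person_var)
    keep_persons = (person_var > 0) & (sub_obs.sum(axis=1) > 0)
    dropped_persons = [matrix.person_ids[n] for n in np.where(~keep_persons)[0]]
    if dropped_persons:
        logger.warning(
            "dropping %d no-variance persons from calibration", len(dropped_persons)
        )
    est = sub[keep_persons]
    est_obs = ~np.isnan(est)
    if est.shape[0] < 2 or est.shape[1] < 2:
        raise ValueError("fewer than 2 persons or items with variance; cannot calibrate")
    x = np.where(est_obs, est, 0.0)

    kept_item_ids = [matrix.item_ids[j] for j in np.where(keep_items)[0]]
    anchored = anchors is not None
    if anchored:
        delta = np.array([anchors.get(i).difficulty for i in kept_item_ids])
        tau = np.array(anchors.scale.thresholds, dtype=float)
        anchor_tau_mean = tau.mean()
    else:
        delta = np.zeros(len(kept_item_ids))
        tau = np.zeros(m)
    theta = np.zeros(est.shape[0])

    converged = False
    it = 0
    raw = (x * est_obs).sum(axis=1)
    for it in range(1, cfg.max_iter + 1):
        p = _probs(theta, delta, tau)
        k = np.arange(m_cat)
        e = p @ k
        w = p @ (k * k) - e * e
        e = np.where(est_obs, e, 0.0)
        w_obs = np.where(est_obs, w, 0.0)

        # persons
        step_t = (raw - e.sum(axis=1)) / np.maximum(w_obs.sum(axis=1), 1e-10)
        step_t = np.clip(step_t, -1.0, 1.0)
        theta = np.clip(theta + step_t, -10.0, 10.0)

        # items
        if not anchored:
            p = _probs(theta, delta, tau)
            e = np.where(est_obs, p @ k, 0.0)
            w_obs = np.where(est_obs, p @ (k * k) - (p @ k) ** 2, 0.0)
            step_d = (e.sum(axis=0) - x.sum(axis=0)) / np.maximum(
                w_obs.sum(axis=0), 1e-10
            )
            step_d = np.clip(step_d, -1.0, 1.0)
            delta = np.clip(delta + step_d, -10.0, 10.0)
        else:
            step_d = np.zeros_like(delta)

        # shared thresholds: diagonal Newton on P(X >= j)
        p = _probs(theta, delta, tau)
        step_tau = np.zeros(m)
        for j in range(1, m + 1):
            pj = p[:, :, j:].sum(axis=2)
            sj = (est >= j) & est_obs
            num = (pj[est_obs] - sj[est_obs]).sum()
            den = (pj * (1.0 - pj))[est_obs].sum()
            step_tau[j - 1] = np.clip(num / max(den, 1e-10), -1.0, 1.0)
        tau = tau + step_tau

        if not anchored:
            # identification: sum(tau) = 0, mean(delta) = 0
            tshift = tau.mean()
            tau -= tshift
            delta = delta + tshift
            dshift = delta.mean()
            delta -= dshift
            theta -= dshift
        else:
            # with difficulties fixed, a joint shift of persons and
            # thresholds is still unidentified; keep the threshold sum at
            # the anchor scale's value so estimates live in its frame
            tshift = tau.mean() - anchor_tau_mean
            tau -= tshift
            theta -= tshift

        biggest = max(
            np.abs(step_t).max(),
            np.abs(step_d).max() if step_d.size else 0.0,
            np.abs(step_tau).max(),
        )
        if biggest < cfg.tol:
            converged = True
            break
    if not converged:
        logger.warning("JMLE did not converge in %d iterations", cfg.max_iter)

    if cfg.bias_correction:
        length = float(est_obs.sum(axis=1).mean())
        if length > 1:
            shrink = (length - 1.0) / length
            tmean = tau.mean()
            tau = tmean + (tau - tmean) * shrink
            if not anchored:
                delta = delta * shrink  # mean is 0 by identification

    scale = RatingScale(tuple(tau))
    items = []
    for j, iid in enumerate(kept_item_ids):
        label = anchors.get(iid).label if anchored else ""
        items.append(Item(item_id=iid, label=label, difficulty=float(delta[j]),
                          status="calibrated"))
    bank = ItemBank(items=items, scale=scale)

    # final person measures for every person with data, via the scalar NR
    person_measures: list[AbilityEstimate] = []
    person_ids: list[str] = []
    id_to_item = {it_.item_id: it_ for it_ in items}
    for n, pid in enumerate(matrix.person_ids):
        resp = [
            (id_to_item[matrix.item_ids[j]], int(data[n, j]))
            for j in range(data.shape[1])
            if not np.isnan(data[n, j]) and matrix.item_ids[j] in id_to_item
        ]
        if not resp:
            continue
        person_ids.append(pid)
        person_measures.append(
            estimate_theta(resp, scale, init=0.0,
                           tol=cfg.person_tol, max_iter=cfg.person_max_iter)
        )

    sub_matrix = ResponseMatrix(
        person_ids=person_ids,
        item_ids=kept_item_ids,
        data=frame.loc[person_ids, kept_item_ids].to_numpy(dtype=float),
        n_categories=m_cat,
    )
    fit = fit_statistics(sub_matrix, bank, person_measures)
    for item in bank.items:
        item.infit = float(fit.items.loc[item.item_id, "infit"])
        item.outfit = float(fit.items.loc[item.item_id, "outfit"])
    # item SEs from the information accumulated over persons
    pfin = _probs(np.array([a.theta for a in person_measures]),
                  np.array([id_to_item[i].difficulty for i in kept_item_ids]), tau)
    kk = np.arange(m_cat)
    wfin = pfin @ (kk * kk) - (pfin @ kk) ** 2
    wfin = np.where(~np.isnan(sub_matrix.data), wfin, 0.0)
    for j, item in enumerate(bank.items):
        total = wfin[:, j].sum()
        item.se = float(1.0 / math.sqrt(total)) if total > 0 else None

    misfit_ids = [
        it_.item_id
        for it_ in bank.items
        if not (0.5 <= fit.items.loc[it_.item_id, "infit"] <= 1.5)
    ]
    reliability = separation_reliability(person_measures)
    dimensionality = residual_pca(sub_matrix, bank, person_measures)
    category_report = category_diagnostics(sub_matrix, bank, person_measures)

    return CalibrationResult(
        bank=bank,
        person_measures=person_measures,
        person_ids=person_ids,
        reliability=reliability,
        misfit_item_ids=misfit_ids,
        fit=fit,
        dimensionality=dimensionality,
        category_report=category_report,
        converged=converged,
        n_iter=it,
        dropped_items=dropped_items,
        dropped_persons=dropped_persons,
    )


# ---------------------------------------------------------------------------
# fit statistics
# ---------------------------------------------------------------------------

def _wilson_hilferty_z(mnsq: np.ndarray, q2: np.ndarray) -> np.ndarray:
    """Cube-root (Wilson-Hilferty) standardization of a mean-square."""
    q = np.sqrt(np.maximum(q2, 1e-12))
    return (np.cbrt(mnsq) - 1.0) * (3.0 / q) + q / 3.0


def fit_statistics(
    matrix: ResponseMatrix,
    bank: ItemBank,
    person_measures: Sequence[AbilityEstimate],
) -> FitTable:
    """Infit/outfit mean-squares and standardized Z per item and person.

    The standardized residual is z_ni = (x_ni - E_ni) / sqrt(W_ni).
    Outfit is the plain mean of z^2 over the margin; infit is the
    information-weighted version sum (x-E)^2 / sum W.  Z uses the
    Wilson-Hilferty cube-root transform with the Wright-Masters moment
    variances.  Both MNSQ have expectation 1 under the model.
    """
    theta = np.array([a.theta for a in person_measures])
    if theta.size != matrix.n_persons:
        raise ValueError("one measure required per person in the matrix")
    delta = np.array([bank.get(i).difficulty for i in matrix.item_ids])
    tau = np.asarray(bank.scale.thresholds)
    data = matrix.data
    obs = ~np.isnan(data)

    p = _probs(theta, delta, tau)
    e, w, c = _moments(p)
    tiny = w <= 1e-12
    if np.any(tiny & obs):
        warnings.warn("zero-variance cells excluded from fit statistics", stacklevel=2)
        obs = obs & ~tiny
    r2 = np.where(obs, (np.where(obs, data, 0.0) - e) ** 2, 0.0)
    z2 = np.where(obs, r2 / np.where(obs, np.maximum(w, 1e-12), 1.0), 0.0)

    def margin(axis: int, ids: list) -> pd.DataFrame:
        n = obs.sum(axis=axis).astype(float)
        n = np.maximum(n, 1.0)
        outfit = z2.sum(axis=axis) / n
        sw = np.where(obs, w, 0.0).sum(axis=axis)
        infit = r2.sum(axis=axis) / np.maximum(sw, 1e-12)
        q2_out = np.where(obs, c / np.maximum(w, 1e-12) ** 2, 0.0).sum(axis=axis) / n**2 - 1.0 / n
        q2_in = np.where(obs, c - w**2, 0.0).sum(axis=axis) / np.maximum(sw, 1e-12) ** 2
        return pd.DataFrame(
            {
                "infit": infit,
                "outfit": outfit,
                "infit_z": _wilson_hilferty_z(infit, q2_in),
                "outfit_z": _wilson_hilferty_z(outfit, q2_out),
                "n_obs": obs.sum(axis=axis),
            },
            index=ids,
        )

    return FitTable(
        items=margin(0, list(matrix.item_ids)),
        persons=margin(1, list(matrix.person_ids)),
    )


def misfit_filter(
    source: CalibrationResult | ItemBank,
    lower: float = 0.5,
    upper: float = 1.5,
) -> tuple[ItemBank, list[int]]:
    """Split a bank into retained items and misfits by infit MNSQ.

    Items whose infit lies in the closed interval [lower, upper] are
    retained; items already marked misfit, or outside the band, are
    listed.  Single pass: no refit after removal.
    """
    bank = source.bank if isinstance(source, CalibrationResult) else source
    retained, misfit = [], []
    for item in bank.items:
        if item.status != "calibrated":
            misfit.append(item.item_id)
        elif item.infit is not None and not (lower <= item.infit <= upper):
            misfit.append(item.item_id)
        else:
            retained.append(item)
    if not retained:
        raise ValueError("all items misfit; nothing retained")
    return ItemBank(items=retained, scale=bank.scale), misfit


# ---------------------------------------------------------------------------
# reliability and the SEM stop value
# ---------------------------------------------------------------------------

def separation_reliability(person_measures: Sequence[AbilityEstimate]) -> float:
    """Person-separation reliability (analogue of Cronbach's alpha).

    (observed variance of non-extreme measures - mean squared SE) /
    observed variance, floored at 0.
    """
    interior = [a for a in person_measures if not a.extreme]
    if len(interior) < 2:
        raise ValueError("need at least 2 non-extreme person measures")
    t = np.array([a.theta for a in interior])
    var = float(np.var(t, ddof=1))
    if var <= 0:
        warnings.warn("zero variance of person measures; reliability 0", stacklevel=2)
        return 0.0
    mse = float(np.mean([a.se**2 for a in interior]))
    return max(0.0, (var - mse) / var)


def sem_stop_value(sd_person: float, reliability: float) -> float:
    """CAT stopping SEM: sd_person * sqrt(1 - reliability)."""
    if not (sd_person > 0):
        raise ValueError("sd_person must be positive")
    if not (0.0 <= reliability <= 1.0):
        raise ValueError("reliability must lie in [0, 1]")
    return sd_person * math.sqrt(1.0 - reliability)


# ---------------------------------------------------------------------------
# dimensionality and category diagnostics
# ---------------------------------------------------------------------------

def residual_pca(
    matrix: ResponseMatrix,
    bank: ItemBank,
    person_measures: Sequence[AbilityEstimate],
) -> DimensionalitySummary:
    """PCA of standardized residuals as a unidimensionality check.

    Standardized residuals z_ni = (x - E) / sqrt(W) are formed at the
    estimated parameters; their item-by-item correlation matrix is
    eigen-decomposed.  The first contrast eigenvalue is the largest
    eigenvalue.  Variance explained by the measures is the
    model-variance share 100 x var(E) / (var(E) + mean W) over observed
    cells.  The first-contrast variance share is expressed against the
    TOTAL variance (measures + residual): the residual eigenvalues sum
    to n_items units, so the total is n_items / (1 - explained) units
    and the share is eigenvalue / total x 100 — the convention under
    which an eigenvalue of ~1.8 on a 24-item scale is ~4% of variance.
    """
    theta = np.array([a.theta for a in person_measures])
    delta = np.array([bank.get(i).difficulty for i in matrix.item_ids])
    tau = np.asarray(bank.scale.thresholds)
    data = matrix.data
    obs = ~np.isnan(data)
    if matrix.n_items > matrix.n_persons:
        warnings.warn(
            "more items than persons: residual eigenstructure is unstable",
            stacklevel=2,
        )

    p = _probs(theta, delta, tau)
    e, w, _ = _moments(p)
    var_e = float(np.var(e[obs]))
    mean_w = float(np.mean(w[obs]))
    explained = 100.0 * var_e / (var_e + mean_w)

    z = np.where(obs, (np.where(obs, data, 0.0) - e) / np.sqrt(np.maximum(w, 1e-12)),
                 np.nan)
    corr = pd.DataFrame(z, columns=matrix.item_ids).corr().to_numpy()
    corr = np.where(np.isnan(corr), 0.0, corr)
    np.fill_diagonal(corr, 1.0)
    eigvals = np.linalg.eigvalsh(corr)
    first = float(eigvals[-1])
    total_units = matrix.n_items / max(1.0 - explained / 100.0, 1e-12)
    return DimensionalitySummary(
        variance_explained_by_measures=explained,
        first_contrast_eigenvalue=first,
        first_contrast_variance=100.0 * first / total_units,
    )


def category_diagnostics(
    matrix: ResponseMatrix,
    bank: ItemBank,
    person_measures: Sequence[AbilityEstimate],
) -> CategoryDiagnostics:
    """Evidence for the four Linacre category-functioning guidelines."""
    theta = np.array([a.theta for a in person_measures])
    data = matrix.data
    m = bank.scale.n_steps
    avg: list[Optional[float]] = []
    theta_grid = np.broadcast_to(theta[:, None], data.shape)
    for k in range(m + 1):
        mask = data == k
        if mask.any():
            avg.append(float(theta_grid[mask].mean()))
        else:
            warnings.warn(f"category {k} unobserved; guideline 1 undetermined",
                          stacklevel=2)
            avg.append(None)
    tau = np.asarray(bank.scale.thresholds)
    advances = list(np.diff(tau).astype(float))

    if any(a is None for a in avg):
        g1: Optional[bool] = None
    else:
        g1 = all(avg[k] < avg[k + 1] for k in range(m))
    g2 = bool(np.all(np.diff(tau) > 0)) if m > 1 else True
    g3 = bool(all(a >= 1.4 for a in advances)) if advances else True
    g4 = bool(all(a < 5.0 for a in advances)) if advances else True
    return CategoryDiagnostics(
        average_measures_per_category=avg,
        threshold_advances=advances,
        guideline_flags={
            "average_measures_advance": g1,
            "steps_advance": g2,
            "advance_at_least_1.4": g3,
            "advance_less_than_5.0": g4,
        },
    )
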