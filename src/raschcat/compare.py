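"""Item-by-item and demographic group comparisons.

Item scores (raw 1-4 Likert categories by default) are compared between
two survey waves with Welch's unequal-variance t-test, overall and within
demographic strata; demographic composition is compared with Pearson's
chi-square, Yates-corrected for 2x2 tables.  No multiple-testing
correction is applied; reports state the number of tests performed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .calibration import ResponseMatrix

__all__ = ["ComparisonRow", "item_t_test", "demographic_chi_square", "itemwise_report"]


@dataclass
class ComparisonRow:
    """One group contrast: mean difference in score units with Welch CI."""

    stratum: str
    mean_difference: float
    se: float
    ci_lower: float
    ci_upper: float
    t: float
    df: float
    p: float
    n_a: int
    n_b: int


def item_t_test(
    responses_a: Sequence[float],
    responses_b: Sequence[float],
    stratum: str = "all",
    alpha: float = 0.05,
) -> ComparisonRow:
    """Welch unequal-variance t-test of mean item scores, A minus B.

    Degrees of freedom are Satterthwaite-approximated; the confidence
    interval is difference +/- t_crit(df) * se.  Identical constant
    groups return t = 0, p = 1.
    """
    a = np.asarray(responses_a, dtype=float)
    b = np.asarray(responses_b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = a.size, b.size
    diff = float(a.mean() - b.mean())
    se2 = va / na + vb / nb
    se = float(np.sqrt(se2))
    if se == 0.0:
        if diff == 0.0:
            return ComparisonRow(stratum, 0.0, 0.0, 0.0, 0.0, 0.0, float(na + nb - 2),
                                 1.0, na, nb)
        raise ValueError("zero variance in both groups with unequal means")
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    t = diff / se
    p = float(2.0 * stats.t.sf(abs(t), df))
    crit = float(stats.t.ppf(1.0 - alpha / 2.0, df))
    return ComparisonRow(
        stratum=stratum,
        mean_difference=diff,
        se=se,
        ci_lower=diff - crit * se,
        ci_upper=diff + crit * se,
        t=float(t),
        df=float(df),
        p=p,
        n_a=na,
        n_b=nb,
    )


def demographic_chi_square(
    contingency: Sequence[Sequence[int]] | np.ndarray,
) -> tuple[float, int, float]:
    """Pearson chi-square on a counts table; Yates correction iff 2x2."""
    table = np.asarray(contingency)
    if table.ndim != 2 or table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("contingency table must be at least 2x2")
    if np.any(table < 0) or np.any(table != np.round(table)):
        raise ValueError("counts must be non-negative integers")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("zero marginal in contingency table")
    correction = table.shape == (2, 2)
    res = stats.chi2_contingency(table, correction=correction)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def itemwise_report(
    matrix_a: ResponseMatrix,
    matrix_b: ResponseMatrix,
    strata: Optional[tuple[Mapping[str, str], Mapping[str, str]]] = None,
    score_offset: float = 0.0,
) -> pd.DataFrame:
    """One Welch contrast per (item, stratum): wave A minus wave B.

    ``strata`` is a pair of person_id -> stratum-label mappings, one per
    matrix; omitted persons fall in no stratum, ``None`` compares whole
    cohorts under the label ``all``.  ``score_offset`` is added to raw
    categories for display (e.g. 1.0 to report on the 1-4 Likert scale);
    it cancels in the differences.  Empty strata are omitted with a
    warning.  Rows are ordered by item then stratum.
    """
    common = [i for i in matrix_a.item_ids if i in set(matrix_b.item_ids)]
    if not common:
        raise ValueError("matrices share no item ids")
    fa = matrix_a.to_frame() + score_offset
    fb = matrix_b.to_frame() + score_offset
    if strata is None:
        groups = {"all": (list(fa.index), list(fb.index))}
    else:
        map_a, map_b = strata
        labels = sorted(set(map_a.values()) | set(map_b.values()))
        groups = {
            lab: (
                [p for p in fa.index if map_a.get(p) == lab],
                [p for p in fb.index if map_b.get(p) == lab],
            )
            for lab in labels
        }

    rows = []
    for item_id in common:
        for lab, (pa, pb) in groups.items():
            a = fa.loc[pa, item_id].dropna() if pa else pd.Series(dtype=float)
            b = fb.loc[pb, item_id].dropna() if pb else pd.Series(dtype=float)
            if len(a) < 2 or len(b) < 2:
                warnings.warn(
                    f"stratum {lab!r} too small for item {item_id}; row omitted",
                    stacklevel=2,
                )
                continue
            r = item_t_test(a.to_numpy(), b.to_numpy(), stratum=lab)
            rows.append(
                {
                    "item_id": item_id,
                    "stratum": lab,
                    "mean_difference": r.mean_difference,
                    "se": r.se,
                    "ci_lower": r.ci_lower,
                    "ci_upper": r.ci_upper,
                    "t": r.t,
                    "df": r.df,
                    "p": r.p,
                    "n_a": r.n_a,
                    "n_b": r.n_b,
                }
            )
    report = pd.DataFrame(rows)
    report.attrs["n_tests"] = len(rows)
    return report
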