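"""Discrimination and association summaries.

The c-statistic is the concordance probability: the chance that a
randomly chosen non-adherent patient receives a higher predicted risk
than a randomly chosen adherent one, with ties counting one half. It
equals the area under the ROC curve and the normalised Mann-Whitney
statistic, and maps to Somers' rank correlation as Dxy = 2c - 1.
Nagelkerke's R^2 is the normalised likelihood-ratio pseudo-R^2.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from statsmodels.stats.proportion import proportion_confint

from .errors import UndefinedOutcomeError

__all__ = [
    "c_statistic",
    "somers_dxy",
    "nagelkerke_r2",
    "roc_points",
    "trapezoid_auc",
    "relative_risk_ci",
    "mpr_bin_curve",
    "discrimination_report",
]


def c_statistic(scores, labels) -> float:
    """Concordance probability by midrank (Mann-Whitney) counting."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n1 = int(labels.sum())
    n0 = int((~labels).sum())
    if n1 == 0 or n0 == 0:
        raise UndefinedOutcomeError("both classes are needed for the c-statistic")
    ranks = rankdata(scores)
    return float((ranks[labels].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def somers_dxy(c: float) -> float:
    """Somers' rank correlation from the c-statistic: 2c - 1."""
    if not (0.0 <= c <= 1.0):
        raise UndefinedOutcomeError(f"c-statistic must lie in [0, 1], got {c!r}")
    return 2.0 * c - 1.0


def nagelkerke_r2(ll0: float, ll1: float, n: int) -> float:
    """Normalised Cox-Snell pseudo-R^2 for a binary model."""
    if n <= 0:
        raise UndefinedOutcomeError("n must be positive")
    if ll0 == 0.0:
        raise UndefinedOutcomeError("degenerate outcome: null log-likelihood is zero")
    cox_snell = 1.0 - np.exp((2.0 / n) * (ll0 - ll1))
    return float(cox_snell / (1.0 - np.exp((2.0 / n) * ll0)))


def roc_points(scores, labels) -> np.ndarray:
    """Empirical ROC curve as (fpr, tpr) pairs, from (0,0) to (1,1).

    Thresholds sweep the distinct score values from high to low; tied
    scores move the curve diagonally, so the trapezoid area equals the
    midrank c-statistic.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    order = np.argsort(-scores, kind="mergesort")
    s, y = scores[order], labels[order]
    distinct = np.r_[np.flatnonzero(np.diff(s)), len(s) - 1]
    tp = np.cumsum(y)[distinct]
    fp = np.cumsum(~y)[distinct]
    n1, n0 = labels.sum(), (~labels).sum()
    fpr = np.concatenate([[0.0], fp / n0])
    tpr = np.concatenate([[0.0], tp / n1])
    return np.column_stack([fpr, tpr])


def trapezoid_auc(points: np.ndarray) -> float:
    """Area under an ROC point set by the trapezoid rule."""
    fpr, tpr = points[:, 0], points[:, 1]
    return float(np.trapezoid(tpr, fpr))


def relative_risk_ci(
    p1: float | None = None,
    p2: float | None = None,
    counts: tuple[int, int, int, int] | None = None,
) -> tuple[float, float, float]:
    """Relative risk with a 95% log-normal CI.

    Either supply proportions ``(p1, p2)`` (CI returned as NaN) or
    ``counts=(a, n1, b, n2)`` with a/n1 and b/n2 the two risks.
    """
    if counts is not None:
        a, n1, b, n2 = counts
        if min(a, n1, b, n2) <= 0:
            raise UndefinedOutcomeError("counts must be positive for a CI")
        rr = (a / n1) / (b / n2)
        se = np.sqrt(1.0 / a - 1.0 / n1 + 1.0 / b - 1.0 / n2)
        lo, hi = np.exp(np.log(rr) - 1.96 * se), np.exp(np.log(rr) + 1.96 * se)
        return float(rr), float(lo), float(hi)
    if p2 is None or p2 == 0:
        raise UndefinedOutcomeError("reference proportion must be positive")
    return float(p1 / p2), float("nan"), float("nan")


def mpr_bin_curve(
    mpr_line1, nonadh_line2, bin_edges=None
) -> pd.DataFrame:
    """Second-line non-adherence proportion by first-line MPR bin.

    Bins are left-closed, the last bin closed on both sides; intervals
    carry Wilson 95% limits. Empty bins report NaN proportions.
    """
    if bin_edges is None:
        bin_edges = [20, 50, 60, 70, 80, 85, 90, 95, 100, 105, 110, 120]
    edges = np.asarray(bin_edges, dtype=float)
    mpr = np.asarray(mpr_line1, dtype=float)
    y = np.asarray(nonadh_line2, dtype=float)
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        last = hi == edges[-1]
        m = (mpr >= lo) & ((mpr <= hi) if last else (mpr < hi))
        n = int(m.sum())
        if n == 0:
            rows.append((lo, hi, 0, np.nan, np.nan, np.nan))
            continue
        k = int(y[m].sum())
        p = k / n
        ci_lo, ci_hi = proportion_confint(k, n, alpha=0.05, method="wilson")
        rows.append((lo, hi, n, p, float(ci_lo), float(ci_hi)))
    return pd.DataFrame(
        rows, columns=["mpr_lo", "mpr_hi", "n", "proportion", "ci_lo", "ci_hi"]
    )


def discrimination_report(scores, labels, ll0=None, ll1=None, n=None) -> dict:
    """c-statistic, Dxy, optional Nagelkerke R^2 and the ROC point set."""
    c = c_statistic(scores, labels)
    out = {
        "c_statistic": c,
        "dxy": somers_dxy(c),
        "roc_points": roc_points(scores, labels).tolist(),
    }
    if ll0 is not None and ll1 is not None and n is not None:
        out["nagelkerke_r2"] = nagelkerke_r2(ll0, ll1, n)
    return out
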