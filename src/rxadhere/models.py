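"""Logistic modelling machinery: spline bases, ML fits, nested tests.

Non-adherence (MPR <= 80%) is modelled by maximum-likelihood logistic
regression. Non-linear continuous predictors enter either as simple
linear splines (two slopes around a knot, e.g. age with a knot at 70)
or, for sensitivity analysis, as restricted cubic splines (natural
cubic, linear beyond the boundary knots, Harrell's truncated-power
construction). A binned empirical-logit smoother stands in for the
usual GAM shape plot when choosing knots; it is advisory only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .errors import IncomparableModelsError, RxAdhereError

__all__ = [
    "ModelSpec",
    "FitResult",
    "linear_spline_basis",
    "rcs_basis",
    "rcs_default_knots",
    "build_design",
    "fit_logistic",
    "shape_diagnostic",
    "lr_test",
    "loglik_share",
    "simulate_logistic",
]

IRLS_TOL = 1e-8
IRLS_MAXITER = 100


# ---------------------------------------------------------------------------
# bases


def linear_spline_basis(x, knot: float) -> tuple[np.ndarray, np.ndarray]:
    """Two-piece linear basis: ``(min(x, knot), max(x - knot, 0))``.

    The fitted coefficients are the slopes before and after the knot;
    the fitted function is continuous at the knot.
    """
    x = np.asarray(x, dtype=float)
    if not np.isfinite(knot):
        raise ValueError("knot must be finite")
    return np.minimum(x, knot), np.maximum(x - knot, 0.0)


def rcs_default_knots(x, n_knots: int = 4) -> np.ndarray:
    """Default knot placement at the 5th/35th/65th/95th percentiles
    (equally spaced quantiles between 5 and 95 for other counts)."""
    x = np.asarray(x, dtype=float)
    qs = np.linspace(5, 95, n_knots)
    return np.unique(np.percentile(x[np.isfinite(x)], qs))


def rcs_basis(x, knots) -> np.ndarray:
    """Restricted cubic spline basis with k knots -> k-1 columns.

    Column 0 is x itself; the remaining columns are the truncated-power
    natural-spline terms, constrained to be linear beyond the boundary
    knots and scaled by the squared knot range for conditioning. A
    linear function is reproduced exactly by the first column alone.
    """
    x = np.asarray(x, dtype=float)
    knots = np.asarray(knots, dtype=float)
    if len(knots) < 3:
        raise ValueError("restricted cubic splines need at least 3 knots")
    if np.any(np.diff(knots) <= 0):
        raise ValueError("knots must be strictly increasing")
    k = len(knots)
    t1, tk, tk1 = knots[0], knots[-1], knots[-2]
    scale = (tk - t1) ** 2

    def ppart(v):
        return np.maximum(v, 0.0) ** 3

    cols = [x]
    for j in range(k - 2):
        tj = knots[j]
        term = (
            ppart(x - tj)
            - ppart(x - tk1) * (tk - tj) / (tk - tk1)
            + ppart(x - tk) * (tk1 - tj) / (tk - tk1)
        ) / scale
        cols.append(term)
    return np.column_stack(cols)


# ---------------------------------------------------------------------------
# model specification


@dataclass
class ModelSpec:
    """Outcome, terms and complete-case policy for one logistic model.

    ``terms`` is a list of ``(column, transform)`` pairs with transform
    one of ``"linear"``, ``"binary"``, ``("linear_spline", knot)``,
    ``("rcs", knots-or-None)`` or ``"categorical"``.
    """

    name: str
    outcome: str
    terms: list = field(default_factory=list)
    complete_case_fields: list[str] | None = None

    def fields_used(self) -> list[str]:
        return [t[0] for t in self.terms]


def build_design(
    features: pd.DataFrame, spec: ModelSpec
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Design matrix (with intercept), outcome vector and row index.

    Rows are restricted to complete cases on ``complete_case_fields``
    (default: every numeric field the model uses; the ethnicity
    ``missing`` level only drops rows when ethnicity is itself a term
    listed in the complete-case fields).
    """
    cc = spec.complete_case_fields
    if cc is None:
        cc = [c for c in spec.fields_used() if c != "ethnicity"]
    mask = np.ones(len(features), dtype=bool)
    for col in cc:
        if col == "ethnicity":
            mask &= (features[col] != "missing").to_numpy()
        else:
            mask &= features[col].notna().to_numpy()
    mask &= features[spec.outcome].notna().to_numpy()
    sub = features.loc[mask]

    cols: dict[str, np.ndarray] = {"const": np.ones(len(sub))}
    for col, transform in spec.terms:
        x = sub[col]
        if transform == "linear":
            cols[col] = x.to_numpy(float)
        elif transform == "binary":
            cols[col] = x.astype(float).to_numpy()
        elif transform == "categorical":
            dummies = pd.get_dummies(x, prefix=col, drop_first=True, dtype=float)
            for c in dummies.columns:
                cols[c] = dummies[c].to_numpy()
        elif isinstance(transform, tuple) and transform[0] == "linear_spline":
            b1, b2 = linear_spline_basis(x.to_numpy(float), transform[1])
            cols[f"{col}_lt{transform[1]:g}"] = b1
            cols[f"{col}_gt{transform[1]:g}"] = b2
        elif isinstance(transform, tuple) and transform[0] == "rcs":
            knots = transform[1]
            if knots is None:
                knots = rcs_default_knots(x.to_numpy(float))
            basis = rcs_basis(x.to_numpy(float), knots)
            cols[col] = basis[:, 0]
            for j in range(1, basis.shape[1]):
                cols[f"{col}_rcs{j}"] = basis[:, j]
        else:
            raise RxAdhereError(f"unknown transform {transform!r} for {col!r}")
    X = pd.DataFrame(cols, index=sub.index)
    y = sub[spec.outcome].astype(float).to_numpy()
    return X, y, sub.index.to_numpy()


# ---------------------------------------------------------------------------
# fitting


@dataclass
class FitResult:
    name: str
    params: pd.Series
    bse: pd.Series
    log_likelihood: float
    null_log_likelihood: float
    n_used: int
    converged: bool
    predicted: np.ndarray
    row_index: np.ndarray

    @property
    def n_params(self) -> int:
        return len(self.params)


def _check_rank(X: pd.DataFrame) -> None:
    arr = X.to_numpy(float)
    r = np.linalg.matrix_rank(arr)
    if r < arr.shape[1]:
        _, R = np.linalg.qr(arr, mode="reduced")
        rdiag = np.abs(np.diag(R))
        tol = rdiag.max() * max(arr.shape) * np.finfo(float).eps
        aliased = [c for c, d in zip(X.columns, rdiag) if d <= tol]
        raise RxAdhereError(f"design matrix is rank deficient; aliased columns: {aliased}")


def fit_logistic(
    X: pd.DataFrame, y: np.ndarray, name: str = "model", row_index=None
) -> FitResult:
    """Maximum-likelihood logistic fit by IRLS.

    Convergence at relative log-likelihood change below 1e-8 within 100
    iterations; complete separation is reported through
    ``converged=False`` rather than raised.
    """
    y = np.asarray(y, dtype=float)
    if X.shape[0] <= X.shape[1]:
        raise RxAdhereError("need more observations than parameters")
    _check_rank(X)
    sep_flag = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            model = sm.GLM(y, X, family=sm.families.Binomial())
            res = model.fit(maxiter=IRLS_MAXITER, tol=IRLS_TOL, scale=1.0)
        except Exception:  # statsmodels raises on hopeless separation
            sep_flag = True
            res = None
        for w in caught:
            if "separat" in str(w.message).lower():
                sep_flag = True

    if res is None:
        nan = pd.Series(np.nan, index=X.columns)
        p_null = y.mean()
        lln = float(
            (y * np.log(p_null) + (1 - y) * np.log1p(-p_null)).sum()
        ) if 0 < p_null < 1 else 0.0
        return FitResult(name, nan, nan, np.nan, lln, len(y), False,
                         np.full(len(y), np.nan), np.asarray(row_index) if row_index is not None else np.arange(len(y)))

    fitted = np.asarray(res.fittedvalues, dtype=float)
    if np.any(fitted <= 1e-10) or np.any(fitted >= 1 - 1e-10):
        sep_flag = True
    p_null = y.mean()
    if 0 < p_null < 1:
        llnull = float((y * np.log(p_null) + (1 - y) * np.log1p(-p_null)).sum())
    else:
        raise RxAdhereError("outcome is single-class; logistic fit undefined")
    ll = float(res.llf)
    converged = bool(getattr(res, "converged", True)) and not sep_flag
    return FitResult(
        name=name,
        params=pd.Series(res.params, index=X.columns),
        bse=pd.Series(res.bse, index=X.columns),
        log_likelihood=ll,
        null_log_likelihood=llnull,
        n_used=len(y),
        converged=converged,
        predicted=np.clip(fitted, 1e-12, 1 - 1e-12),
        row_index=np.asarray(row_index) if row_index is not None else np.arange(len(y)),
    )


def fit_spec(features: pd.DataFrame, spec: ModelSpec) -> FitResult:
    """Build the design for a ModelSpec and fit it."""
    X, y, idx = build_design(features, spec)
    return fit_logistic(X, y, name=spec.name, row_index=idx)


# ---------------------------------------------------------------------------
# diagnostics and tests


def shape_diagnostic(
    x, y_binary, n_bins: int = 20
) -> dict[str, np.ndarray]:
    """Binned empirical-logit curve with a moving-average smoother.

    Returns bin centres, raw and smoothed logits, and the x-locations of
    turning points (sign changes of the smoothed first differences).
    Advisory only — knots remain user configuration.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y_binary, dtype=float)
    if len(x) < 5 * n_bins:
        raise RxAdhereError(f"need at least {5 * n_bins} observations for {n_bins} bins")
    order = np.argsort(x, kind="stable")
    x_parts = np.array_split(x[order], n_bins)
    y_parts = np.array_split(y[order], n_bins)
    centres = np.array([np.mean(p) for p in x_parts])
    # +0.5 continuity correction handles all-0/all-1 bins
    logits = np.array(
        [np.log((p.sum() + 0.5) / (len(p) - p.sum() + 0.5)) for p in y_parts]
    )
    kernel = np.ones(3) / 3.0
    padded = np.concatenate([logits[:1], logits, logits[-1:]])
    smooth = np.convolve(padded, kernel, mode="valid")
    d = np.diff(smooth)
    sign = np.sign(d)
    turns = [
        float(centres[i + 1])
        for i in range(len(d) - 1)
        if sign[i] != 0 and sign[i + 1] != 0 and sign[i] != sign[i + 1]
    ]
    return {
        "bin_x": centres,
        "logit": logits,
        "smoothed": smooth,
        "turning_points": np.array(turns),
    }


def lr_test(nested: FitResult, full: FitResult) -> tuple[float, int, float]:
    """Likelihood-ratio test of a nested against a full fit on the same rows."""
    if nested.n_used != full.n_used:
        raise IncomparableModelsError(
            f"fits use different rows ({nested.n_used} vs {full.n_used})"
        )
    chi2 = max(0.0, 2.0 * (full.log_likelihood - nested.log_likelihood))
    df = full.n_params - nested.n_params
    p = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0
    return chi2, df, p


def loglik_share(ll_null: float, ll_partial: float, ll_full: float) -> float:
    """Fraction of the full model's log-likelihood gain captured by a
    partial model: (LL_partial - LL0) / (LL_full - LL0)."""
    if ll_full == ll_null:
        raise RxAdhereError("full model does not improve on the null; share undefined")
    return (ll_partial - ll_null) / (ll_full - ll_null)


def simulate_logistic(
    beta: np.ndarray, n: int, rng: np.random.Generator
) -> tuple[pd.DataFrame, np.ndarray]:
    """Draw (X, y) from a logistic model with standard-normal covariates;
    beta[0] is the intercept."""
    beta = np.asarray(beta, dtype=float)
    p = len(beta) - 1
    X = np.column_stack([np.ones(n), rng.standard_normal((n, p))])
    eta = X @ beta
    y = (rng.random(n) < 1.0 / (1.0 + np.exp(-eta))).astype(float)
    names = ["const"] + [f"x{j}" for j in range(1, p + 1)]
    return pd.DataFrame(X, columns=names), y
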