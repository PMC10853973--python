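"""Statistical modeling of optimal-CE dependence on structure.

Per-channel linear trendlines against m/z, ANCOVA-style general linear models
with homogeneity-of-slopes testing, an L1-regularized regression path with
empirical minimal-feature selection, and correlation diagnostics.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import lasso_path as _sklearn_lasso_path

__all__ = [
    "TrendlineFit",
    "GLMResult",
    "LassoPathResult",
    "fit_trendline",
    "test_slope_homogeneity",
    "ancova",
    "lasso_path",
    "select_features",
    "pearson",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrendlineFit:
    channel: str
    slope: float
    intercept: float
    r_squared: float
    n: int


@dataclass(frozen=True)
class GLMResult:
    formula: str
    interaction_F: float
    interaction_p: float
    covariate_p: float | None          # continuous-variable case
    contrasts: Mapping[str, tuple[float, float]] | None  # level -> (estimate, p)
    coefficients: Mapping[str, float]
    reference_level: str | None = None
    used_interaction: bool = False


@dataclass
class LassoPathResult:
    penalties: np.ndarray
    coefficients: pd.DataFrame   # features x penalties, original scale
    r_squared: np.ndarray
    feature_names: tuple[str, ...]
    dropped_constant: tuple[str, ...] = ()
    selected_features: tuple[str, ...] | None = None
    delta_r2: float | None = None
    X: pd.DataFrame | None = None
    y: np.ndarray | None = None


# ---------------------------------------------------------------------------
# OLS helpers (plain linear algebra; fast enough for simulation loops)

def _ols(X: np.ndarray, y: np.ndarray):
    """Least-squares fit; returns (beta, rss, df_resid, XtX_inv)."""
    n, p = X.shape
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    df = n - rank
    return beta, rss, df, rank


def _r_squared(X: np.ndarray, y: np.ndarray) -> float:
    _, rss, _, _ = _ols(X, y)
    tss = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - rss / tss if tss > 0 else 0.0


def _partial_f_test(X_full, X_reduced, y):
    """F-test of the full model against a nested reduced model."""
    _, rss_full, df_full, rank_full = _ols(X_full, y)
    _, rss_red, _, rank_red = _ols(X_reduced, y)
    df_num = rank_full - rank_red
    if df_num <= 0 or df_full <= 0:
        return np.nan, np.nan
    if rss_full <= 0:  # exact fit: no evidence against the reduced model
        # unless it also fits exactly, in which case F is undefined -> 0
        return 0.0, 1.0
    f_stat = ((rss_red - rss_full) / df_num) / (rss_full / df_full)
    p = float(stats.f.sf(f_stat, df_num, df_full))
    return float(f_stat), p


def fit_trendline(mz: Sequence[float], ce: Sequence[float], channel: str = "") -> TrendlineFit:
    """Ordinary least squares line of optimal CE against m/z."""
    mz = np.asarray(mz, dtype=float)
    ce = np.asarray(ce, dtype=float)
    if len(mz) < 3:
        raise ValueError(f"need >= 3 points, got {len(mz)}")
    if np.ptp(mz) == 0 or np.var(mz) < 1e-24:
        raise ValueError("degenerate m/z variance")
    X = np.column_stack([np.ones_like(mz), mz])
    beta, rss, _, _ = _ols(X, ce)
    tss = float(np.sum((ce - ce.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else 1.0
    return TrendlineFit(channel=channel, slope=float(beta[1]),
                        intercept=float(beta[0]), r_squared=r2, n=len(mz))


# ---------------------------------------------------------------------------
# ANCOVA / homogeneity of slopes

def _merge_sparse_levels(factor: np.ndarray, min_count: int = 2) -> np.ndarray:
    values, counts = np.unique(factor, return_counts=True)
    sparse = {v for v, c in zip(values, counts) if c < min_count}
    if sparse:
        warnings.warn(f"merging sparse factor level(s) {sorted(map(str, sparse))} into 'other'")
        factor = np.array(["other" if v in sparse else str(v) for v in factor])
    return factor


def _dummy_matrix(factor: np.ndarray, reference: str):
    levels = [lv for lv in sorted(np.unique(factor).tolist()) if lv != reference]
    dummies = np.column_stack([(factor == lv).astype(float) for lv in levels]) \
        if levels else np.empty((len(factor), 0))
    return dummies, levels


def test_slope_homogeneity(ce, variable, mz, is_factor: bool | None = None):
    """F-test of the mz-by-variable interaction against the additive model.

    ``variable`` may be categorical (factor) or continuous; factor levels with
    fewer than 2 observations are merged into an ``"other"`` level with a
    warning.  Returns ``(F, p)``.
    """
    ce = np.asarray(ce, dtype=float)
    mz = np.asarray(mz, dtype=float)
    variable = np.asarray(variable)
    if is_factor is None:
        is_factor = not np.issubdtype(variable.dtype, np.floating)
    ones = np.ones_like(ce)
    mz_c = mz - mz.mean()  # centered products keep main effects interpretable
    if is_factor:
        factor = _merge_sparse_levels(variable.astype(str))
        levels = np.unique(factor)
        if len(levels) < 2:
            raise ValueError("factor must have >= 2 populated levels")
        dummies, _ = _dummy_matrix(factor, reference=str(sorted(levels.tolist())[0]))
        X_add = np.column_stack([ones, mz, dummies])
        X_int = np.column_stack([X_add, dummies * mz_c[:, None]])
    else:
        v = variable.astype(float)
        if np.var(v) < 1e-24:
            raise ValueError("degenerate covariate")
        X_add = np.column_stack([ones, mz, v])
        X_int = np.column_stack([X_add, mz_c * (v - v.mean())])
    return _partial_f_test(X_int, X_add, ce)


# keep pytest from collecting the operation by its name
test_slope_homogeneity.__test__ = False  # type: ignore[attr-defined]


def _t_pvalues(X: np.ndarray, y: np.ndarray):
    """Coefficient estimates and two-sided t-test p-values for full-rank X."""
    n, p = X.shape
    beta, rss, df, rank = _ols(X, y)
    if rank < p:
        raise ValueError("collinear design")
    tss = float(np.sum((y - y.mean()) ** 2))
    if df <= 0:
        return beta, np.full(p, np.nan)
    if rss <= max(1e-12 * tss, 1e-20):
        # numerically exact fit: zero coefficients are exactly null
        pvals = np.where(np.abs(beta) < 1e-9 * max(1.0, np.abs(beta).max()), 1.0, 0.0)
        return beta, pvals
    sigma2 = rss / df
    cov = sigma2 * np.linalg.inv(X.T @ X)
    se = np.sqrt(np.diag(cov))
    tvals = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df)
    return beta, pvals


def ancova(ce, variable, mz, reference_level=None, is_factor: bool | None = None,
           alpha_interaction: float = 0.05) -> GLMResult:
    """General linear model of optimal CE on m/z plus one extra variable.

    A homogeneity-of-slopes test decides whether the mz-by-variable
    interaction is retained (interaction p < ``alpha_interaction``).  For
    categorical variables, per-level contrasts against ``reference_level`` are
    reported with two-sided p-values; for continuous variables a single
    covariate p-value is reported.
    """
    ce = np.asarray(ce, dtype=float)
    mz = np.asarray(mz, dtype=float)
    variable = np.asarray(variable)
    if is_factor is None:
        is_factor = not np.issubdtype(variable.dtype, np.floating)
    f_stat, f_p = test_slope_homogeneity(ce, variable, mz, is_factor=is_factor)
    use_interaction = bool(np.isfinite(f_p) and f_p < alpha_interaction)
    ones = np.ones_like(ce)
    mz_c = mz - mz.mean()

    if is_factor:
        factor = _merge_sparse_levels(variable.astype(str))
        levels = sorted(np.unique(factor).tolist())
        reference = str(reference_level) if reference_level is not None else levels[0]
        if reference not in levels:
            raise ValueError(f"reference level {reference!r} not present")
        dummies, contrast_levels = _dummy_matrix(factor, reference)
        names = ["intercept", "mz"] + [f"level[{lv}]" for lv in contrast_levels]
        X = np.column_stack([ones, mz, dummies])
        if use_interaction:
            X = np.column_stack([X, dummies * mz_c[:, None]])
            names += [f"mz:level[{lv}]" for lv in contrast_levels]
        beta, pvals = _t_pvalues(X, ce)
        contrasts = {lv: (float(beta[2 + i]), float(pvals[2 + i]))
                     for i, lv in enumerate(contrast_levels)}
        formula = "ce ~ mz + level" + (" + mz:level" if use_interaction else "")
        return GLMResult(formula=formula, interaction_F=f_stat, interaction_p=f_p,
                         covariate_p=None, contrasts=contrasts,
                         coefficients=dict(zip(names, map(float, beta))),
                         reference_level=reference, used_interaction=use_interaction)

    v = variable.astype(float)
    X = np.column_stack([ones, mz, v])
    names = ["intercept", "mz", "covariate"]
    if use_interaction:
        X = np.column_stack([X, mz_c * (v - v.mean())])
        names.append("mz:covariate")
    beta, pvals = _t_pvalues(X, ce)
    formula = "ce ~ mz + covariate" + (" + mz:covariate" if use_interaction else "")
    return GLMResult(formula=formula, interaction_F=f_stat, interaction_p=f_p,
                     covariate_p=float(pvals[2]), contrasts=None,
                     coefficients=dict(zip(names, map(float, beta))),
                     used_interaction=use_interaction)


# ---------------------------------------------------------------------------
# lasso path + empirical minimal-feature selection

def lasso_path(X: pd.DataFrame, y, penalties=None, n_penalties: int = 100,
               decades: float = 4.0, tol: float = 1e-7) -> LassoPathResult:
    """L1-penalized least-squares path over a logarithmic penalty grid.

    Features are standardized to zero mean / unit variance before
    penalization; coefficients are reported on the original scale.  Constant
    features are dropped with a warning.  The default grid spans 4 decades
    down from the smallest penalty that zeroes every slope.
    """
    X = pd.DataFrame(X)
    y = np.asarray(y, dtype=float)
    n = len(y)
    stds = X.std(axis=0, ddof=0)
    constant = tuple(X.columns[stds < 1e-12])
    if constant:
        warnings.warn(f"dropping constant feature(s) {list(constant)}")
        X = X.drop(columns=list(constant))
        stds = stds.drop(labels=list(constant))
    if X.shape[1] == 0:
        raise ValueError("no non-constant features")
    if n <= X.shape[1]:
        warnings.warn(f"n={n} <= {X.shape[1]} candidate features; path may be unstable")
    means = X.mean(axis=0)
    Xs = (X - means) / stds
    yc = y - y.mean()
    lam_max = float(np.max(np.abs(Xs.T @ yc)) / n)
    if penalties is None:
        penalties = np.logspace(np.log10(lam_max), np.log10(lam_max) - decades, n_penalties)
    penalties = np.asarray(penalties, dtype=float)

    coefs_std = np.empty((Xs.shape[1], len(penalties)))
    positive_mask = penalties > 1e-12
    if positive_mask.any():
        alphas = penalties[positive_mask]
        order = np.argsort(alphas)[::-1]  # sklearn wants decreasing alphas
        _, path_coefs, _ = _sklearn_lasso_path(
            Xs.to_numpy(), yc, alphas=alphas[order], tol=tol, max_iter=100_000)
        inverse = np.empty_like(order)
        inverse[order] = np.arange(len(order))
        coefs_std[:, positive_mask] = path_coefs[:, inverse]
    if (~positive_mask).any():
        # exact zero penalty: ordinary least squares limit
        beta0, _, _, _ = _ols(np.column_stack([np.ones(n), Xs.to_numpy()]), y)
        for j in np.where(~positive_mask)[0]:
            coefs_std[:, j] = beta0[1:]

    coefs_orig = coefs_std / stds.to_numpy()[:, None]
    r2 = np.empty(len(penalties))
    var_y = float(np.sum(yc ** 2))
    for j in range(len(penalties)):
        pred = Xs.to_numpy() @ coefs_std[:, j]
        r2[j] = 1.0 - float(np.sum((yc - pred) ** 2)) / var_y if var_y > 0 else 0.0

    coef_frame = pd.DataFrame(coefs_orig, index=X.columns, columns=penalties)
    return LassoPathResult(penalties=penalties, coefficients=coef_frame, r_squared=r2,
                           feature_names=tuple(X.columns), dropped_constant=constant,
                           X=X, y=y)


def select_features(path: LassoPathResult, delta_r2: float = 0.01) -> tuple[str, ...]:
    """Smallest active set along the path whose refitted (unpenalized) R² is
    within ``delta_r2`` of the full-model R²."""
    if path.X is None or path.y is None or len(path.penalties) == 0:
        raise ValueError("empty path")
    X, y = path.X, path.y
    n = len(y)
    Xfull = np.column_stack([np.ones(n), X.to_numpy()])
    full_r2 = _r_squared(Xfull, y)

    seen: list[tuple[str, ...]] = []
    # penalties ordered large -> small gives active sets small -> large
    for j in np.argsort(path.penalties)[::-1]:
        active = tuple(f for f in path.feature_names
                       if abs(path.coefficients.loc[f, path.penalties[j]]) > 1e-12)
        if active not in seen:
            seen.append(active)
    # order candidate sets by size, then by first appearance on the path
    seen.sort(key=len)
    best: tuple[str, ...] | None = None
    for active in seen:
        cols = [list(path.feature_names).index(f) for f in active]
        Xa = np.column_stack([np.ones(n)] + [X.to_numpy()[:, c] for c in cols])
        if _r_squared(Xa, y) >= full_r2 - delta_r2:
            best = active
            break
    if best is None:  # fall back to the largest set on the path
        best = seen[-1]
    path.selected_features = best
    path.delta_r2 = delta_r2
    return best


def pearson(x, y) -> float:
    """Sample Pearson correlation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(x) != len(y):
        raise ValueError("need >= 3 paired observations")
    if np.var(x) < 1e-24 or np.var(y) < 1e-24:
        raise ValueError("zero variance")
    r, _ = stats.pearsonr(x, y)
    return float(r)
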