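"""Feature selection: cross-validated Lasso and GLM risk-factor ranking.

The biomarker screen is a squared-loss Lasso on the binary outcome,

    beta_hat = argmin_beta  sum_i (y_i - b - sum_j beta_j x_ij)^2
               + lambda * sum_j |beta_j|,

with lambda chosen by ten-fold cross-validation over a log-spaced grid; the
nonzero-coefficient columns form the selected set.  A logistic-loss variant is
available via ``loss="logistic"``.  From the selected set, per-feature
univariate binomial GLMs (logit link) rank candidate risk factors by the
absolute Wald statistic |z| = |beta_hat / SE(beta_hat)|; the top k (default 3)
become the risk factors that constrain the graph predictor's adjacency.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np
import statsmodels.api as sm
from sklearn.linear_model import Lasso, LassoCV, LogisticRegressionCV
from sklearn.model_selection import KFold, StratifiedKFold

__all__ = [
    "SelectionResult",
    "RiskFactorSet",
    "lasso_select",
    "glm_rank_risk_factors",
    "univariate_logit",
    "make_lasso_selector",
]


class SelectionError(ValueError):
    pass


@dataclass
class SelectionResult:
    """Lasso-selected columns with their fitted coefficients.

    ``coefficients`` are on the internally standardized scale and are nonzero
    exactly on ``selected_indices`` (original column indices of the input X).
    ``lambda_`` is on the sum-of-squares objective scale.
    """

    selected_indices: np.ndarray
    coefficients: np.ndarray
    intercept: float
    lambda_: float
    cv_folds: int
    seed: int
    loss: str = "squared"
    n_input_features: int = 0


@dataclass
class RiskFactorSet:
    """Top-k risk factors ranked by absolute Wald z of a univariate GLM."""

    factor_indices: np.ndarray          # indices into the selected-feature matrix
    glm_coefficients: List[tuple]       # per factor: (slope, intercept)
    rank_statistic: np.ndarray          # |z|, non-increasing
    k: int
    separated: np.ndarray = field(default=None)  # per-factor separation flag


def _standardize(X: np.ndarray):
    """Column-standardize; returns (Xs, keep_mask) after dropping constants."""
    X = np.asarray(X, dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    keep = sd > 0
    if not keep.all():
        warnings.warn(
            f"dropping {np.count_nonzero(~keep)} constant column(s) before selection",
            stacklevel=3,
        )
    if not keep.any():
        raise SelectionError("all input columns are constant")
    Xs = (X[:, keep] - mu[keep]) / sd[keep]
    return Xs, np.flatnonzero(keep)


def _validate_labels(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y, dtype=int)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise SelectionError("labels contain a single class")
    if counts.min() < 2:
        raise SelectionError("need at least 2 rows per class")
    return y


def lasso_select(
    X: np.ndarray,
    y: np.ndarray,
    cv_folds: int = 10,
    seed: int = 0,
    loss: str = "squared",
    n_lambda: int = 100,
    lambda_min_ratio: float = 1e-4,
    min_features: int = 1,
) -> SelectionResult:
    """Cross-validated L1 feature selection.

    The grid spans 100 log-spaced penalties from ``lambda_max`` (the smallest
    penalty with an empty model) down to ``1e-4 * lambda_max``; CV picks the
    minimizer of the mean held-out error (no 1-SE rule).  If the CV choice
    yields fewer than ``min_features`` nonzero coefficients (possible on
    signal-free data), the largest penalty on the grid attaining
    ``min_features`` is used instead, keeping downstream stages well defined.
    """
    y = _validate_labels(y)
    Xs, keep = _standardize(X)
    n = Xs.shape[0]

    if loss == "squared":
        yc = y - y.mean()
        alpha_max = np.max(np.abs(Xs.T @ yc)) / n
        if alpha_max <= 0:
            raise SelectionError("labels are orthogonal to every column")
        alphas = np.geomspace(alpha_max, alpha_max * lambda_min_ratio, n_lambda)
        cv = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
        model = LassoCV(alphas=alphas, cv=cv, max_iter=5000).fit(Xs, y.astype(float))
        coef, intercept, alpha = model.coef_, float(model.intercept_), float(model.alpha_)
        nz = np.flatnonzero(coef)
        if nz.size < min_features:
            # walk down the path from the penalized end
            for a in alphas:
                m = Lasso(alpha=a, max_iter=5000).fit(Xs, y.astype(float))
                if np.count_nonzero(m.coef_) >= min_features:
                    coef, intercept, alpha = m.coef_, float(m.intercept_), float(a)
                    nz = np.flatnonzero(coef)
                    break
        lam = 2.0 * n * alpha  # sum-of-squares objective scale
    elif loss == "logistic":
        Cs = np.geomspace(1e-2, 1e3, n_lambda)
        cv = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
        model = LogisticRegressionCV(
            Cs=Cs,
            cv=cv,
            penalty="l1",
            solver="liblinear",
            scoring="neg_log_loss",
            random_state=seed,
            max_iter=2000,
        ).fit(Xs, y)
        coef = model.coef_.ravel()
        intercept = float(model.intercept_[0])
        lam = 1.0 / float(model.C_[0])
        nz = np.flatnonzero(coef)
        if nz.size < min_features:
            scores = np.abs(Xs.T @ (y - y.mean())) / n
            nz = np.argsort(-scores)[:min_features]
            coef = np.zeros_like(coef)
            coef[nz] = scores[nz]
    else:
        raise SelectionError(f"unknown loss {loss!r} (use 'squared' or 'logistic')")

    order = np.argsort(nz)
    nz = nz[order]
    return SelectionResult(
        selected_indices=keep[nz],
        coefficients=coef[nz],
        intercept=intercept,
        lambda_=lam,
        cv_folds=cv_folds,
        seed=seed,
        loss=loss,
        n_input_features=X.shape[1],
    )


def make_lasso_selector(cv_folds: int = 10, seed: int = 0, **kwargs):
    """Selector handle ``(X_train, y_train) -> SelectionResult`` for variant assembly."""

    def selector(X, y):
        return lasso_select(X, y, cv_folds=cv_folds, seed=seed, **kwargs)

    return selector


def _ridge_logit_z(x: np.ndarray, y: np.ndarray, penalty: float = 1.0):
    """Newton fit of a 2-parameter logistic model with an L2 penalty on the
    slope; z from the penalized Fisher information.  Used as the fallback when
    the unpenalized fit separates."""
    X = np.column_stack([np.ones_like(x), x])
    beta = np.zeros(2)
    R = np.diag([0.0, penalty])
    for _ in range(100):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        W = p * (1 - p)
        grad = X.T @ (y - p) - R @ beta
        info = (X.T * W) @ X + R
        step = np.linalg.solve(info, grad)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-10:
            break
    se = np.sqrt(np.diag(np.linalg.inv(info)))
    z = beta[1] / se[1]
    return float(beta[1]), float(beta[0]), float(z)


def univariate_logit(x: np.ndarray, y: np.ndarray, standardize: bool = False):
    """Univariate binomial GLM (logit link) of y on a single column.

    Returns ``(slope, intercept, z, separated)``.  On (quasi-)separation the
    maximum-likelihood fit diverges; the column is flagged and refit with a
    ridge-penalized logistic model so a finite rank statistic is available.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.std() == 0:
        return 0.0, float(np.log(y.mean() / (1 - y.mean() + 1e-300))), 0.0, False
    if standardize:
        x = (x - x.mean()) / x.std()
    exog = sm.add_constant(x)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.GLM(y, exog, family=sm.families.Binomial()).fit(maxiter=100)
        slope, intercept = float(fit.params[1]), float(fit.params[0])
        se = float(fit.bse[1])
        z = slope / se if se > 0 else np.inf
        ok = np.isfinite(z) and se < 1e3 and abs(slope) < 1e3
    except Exception:
        ok = False
    if ok:
        return slope, intercept, float(z), False
    slope, intercept, z = _ridge_logit_z(x, y)
    return slope, intercept, z, True


def glm_rank_risk_factors(
    X_sel: np.ndarray, y: np.ndarray, k: int = 3, standardize: bool = True
) -> RiskFactorSet:
    """Rank selected features as risk factors by univariate GLM Wald |z|.

    Columns are standardized before fitting (|z| itself is scale-invariant;
    standardization keeps the reported slopes comparable).  Separated columns
    get a penalized-fit z and a flag.  Ties in |z| break toward the lower
    column index.
    """
    X_sel = np.atleast_2d(np.asarray(X_sel, dtype=float))
    y = _validate_labels(y)
    p = X_sel.shape[1]
    if not 1 <= k <= p:
        raise SelectionError(f"k={k} must be in [1, {p}]")
    stats = []
    for j in range(p):
        slope, intercept, z, sep = univariate_logit(
            X_sel[:, j], y, standardize=standardize
        )
        stats.append((abs(z), slope, intercept, sep))
    absz = np.array([s[0] for s in stats])
    order = np.lexsort((np.arange(p), -absz))[:k]
    return RiskFactorSet(
        factor_indices=order,
        glm_coefficients=[(stats[j][1], stats[j][2]) for j in order],
        rank_statistic=absz[order],
        k=k,
        separated=np.array([stats[j][3] for j in order]),
    )
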