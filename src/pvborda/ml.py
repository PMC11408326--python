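"""Machine-learning detectors: L1-penalized logistic screening and
random-forest importance with pseudo-variable (shadow) correction.

Both detectors regress the exposure indicator on all retained event codes at
once, plus covariates, so each code's score is adjusted for the others — the
property that sets them apart from the pairwise disproportionality methods.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from .cohort import AnalysisMatrix

logger = logging.getLogger(__name__)


@dataclass
class LassoFit:
    """Per-code |beta| scores with the cross-validated penalty."""

    scores: pd.DataFrame  # index icd; columns beta, score
    lambda_selected: float
    lambda_grid: np.ndarray
    cv_deviance: np.ndarray


def _standardize(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    return (X - mu) / sd


def _l1_logit(y, X, alpha):
    model = sm.Logit(y, X)
    return model.fit_regularized(
        method="l1", alpha=alpha, disp=0, acc=1e-10, maxiter=2000, trim_mode="size",
        size_trim_tol=1e-6,
    )


def lasso_scores(
    matrix: AnalysisMatrix,
    cv_folds: int = 5,
    seed: int = 0,
    n_lambda: int = 12,
    lambda_min_ratio: float = 1e-3,
    penalize_covariates: bool = False,
    lambda_fixed: float | None = None,
) -> LassoFit:
    """L1-penalized logistic regression of exposure on all event codes.

    Predictors are standardized internally; covariates (and the intercept)
    are unpenalized by default. The penalty is chosen on a log-spaced grid by
    ``cv_folds``-fold cross-validated deviance at its minimum — not the 1-SE
    rule, which would collapse more scores into the tie at zero and blunt the
    ranking. The per-code score is |beta| at the selected penalty, on the
    standardized scale.

    ``lambda_fixed`` bypasses cross-validation (``np.inf`` forces every
    penalized coefficient to zero). The penalty here multiplies the summed
    absolute coefficients against the *total* (not average) log-likelihood.
    """
    y = matrix.y.to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("exposure indicator must take both values")
    cols = matrix.adr_codes + matrix.covariates
    X = _standardize(matrix.data[cols].to_numpy(dtype=float))
    X = sm.add_constant(X)
    n, p = X.shape
    n_adr = len(matrix.adr_codes)
    penalized = np.zeros(p, dtype=bool)
    penalized[1 : 1 + n_adr] = True
    if penalize_covariates:
        penalized[1 + n_adr :] = True

    def alpha_vec(lam):
        a = np.zeros(p)
        a[penalized] = lam
        return a

    # lambda_max: smallest penalty with all penalized coefficients at zero
    # (KKT bound from the gradient of the unpenalized-null fit)
    resid = y - y.mean()
    lam_max = np.abs(X[:, penalized].T @ resid).max()
    grid = np.geomspace(lam_max * 1.05, lam_max * lambda_min_ratio, n_lambda)

    if lambda_fixed is not None:
        lam_sel = lambda_fixed
        grid = np.array([lam_sel])
        dev = np.array([np.nan])
    else:
        counts = np.bincount(y.astype(int))
        if counts.min() < cv_folds:
            raise ValueError(
                f"cannot build {cv_folds} stratified folds with class counts {counts}"
            )
        skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
        dev = np.zeros(len(grid))
        for train, test in skf.split(X, y):
            for k, lam in enumerate(grid):
                fit = _l1_logit(y[train], X[train], alpha_vec(lam))
                eta = X[test] @ fit.params
                # held-out deviance
                dev[k] += -2.0 * np.sum(
                    y[test] * eta - np.log1p(np.exp(np.clip(eta, -500, 500)))
                )
        lam_sel = float(grid[int(np.argmin(dev))])

    if np.isinf(lam_sel):
        beta = np.zeros(p)
    else:
        final = _l1_logit(y, X, alpha_vec(lam_sel))
        beta = np.asarray(final.params, dtype=float)
    adr_beta = beta[1 : 1 + n_adr]
    scores = pd.DataFrame(
        {"beta": adr_beta, "score": np.abs(adr_beta)},
        index=pd.Index(matrix.adr_codes, name="icd"),
    )
    logger.info("lasso: lambda=%.4g, %d nonzero of %d codes", lam_sel,
                int((scores["score"] > 1e-10).sum()), n_adr)
    return LassoFit(scores=scores, lambda_selected=lam_sel, lambda_grid=grid, cv_deviance=dev)


@dataclass
class RfFit:
    """Shadow-corrected impurity importances."""

    scores: pd.DataFrame  # index icd; columns importance, score
    n_trees: int
    mtry: int
    repeats: int


def rf_scores(
    matrix: AnalysisMatrix,
    n_trees: int = 500,
    seed: int = 0,
    repeats: int = 3,
    mtry: int | None = None,
) -> RfFit:
    """Random-forest screening with pseudo-variable-corrected impurity.

    Plain impurity importance is biased toward high-cardinality and
    high-frequency predictors; the correction augments the design with an
    independently permuted copy (shadow) of every event column, fits the
    forest on the augmented design, and reports

        importance_j = impurity(x_j) - impurity(shadow_j),

    averaged over ``repeats`` seeded repetitions. Shadow importances estimate
    the bias a null feature with x_j's marginal distribution would receive,
    so corrected importances of null features center at zero (and may go
    negative). Covariates are included in the forest but not scored.
    """
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    codes = matrix.adr_codes
    if not codes:
        raise ValueError("no event columns to score")
    y = matrix.y.to_numpy()
    X_adr = matrix.data[codes].to_numpy()
    X_cov = matrix.data[matrix.covariates].to_numpy() if matrix.covariates else None
    p = X_adr.shape[1]
    mtry = mtry or max(1, int(np.sqrt(2 * p + (0 if X_cov is None else X_cov.shape[1]))))

    total = np.zeros(p)
    for r in range(repeats):
        rng = np.random.default_rng([seed, r])
        shadows = rng.permuted(X_adr, axis=0)
        parts = [X_adr, shadows] + ([X_cov] if X_cov is not None else [])
        X_aug = np.hstack(parts)
        forest = RandomForestClassifier(
            n_estimators=n_trees,
            max_features=mtry,
            random_state=int(rng.integers(0, 2**31 - 1)),
            n_jobs=1,
        )
        forest.fit(X_aug, y)
        imp = forest.feature_importances_
        total += imp[:p] - imp[p : 2 * p]
    importance = total / repeats
    scores = pd.DataFrame(
        {"importance": importance, "score": importance},
        index=pd.Index(codes, name="icd"),
    )
    return RfFit(scores=scores, n_trees=n_trees, mtry=mtry, repeats=repeats)
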