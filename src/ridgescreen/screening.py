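"""Stage-1 marginal screening: univariate t-tests and multivariate ridge.

Two screening statistics are provided:

* ``univariate_screen`` regresses the outcome on each biomarker alone and
  ranks biomarkers by the two-sided p-value for the slope.
* ``ridge_screen`` fits a single multivariate ridge regression of the
  outcome on the (centered) treatment indicator and all (standardized)
  biomarkers, with one shared L2 penalty on the treatment and biomarker
  coefficients, and ranks biomarkers by absolute coefficient size.

Ridge convention: we minimize ``||y - D d||^2 + lambda * ||d||^2`` (sum of
squared errors, penalty ``lambda``), so for an orthonormalized design with
D'D = n*I each coefficient is the OLS value shrunk by n/(n+lambda).  The
intercept is absorbed by centering and never penalized.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError
from .trial import TrialDataset

__all__ = ["ScreeningResult", "univariate_screen", "ridge_screen", "default_lambda_grid"]


@dataclass
class ScreeningResult:
    """Per-biomarker stage-1 score plus a complete best-first ranking.

    ``scores`` holds p-values for the univariate method (smaller = better)
    and standardized ridge coefficients for the ridge method (larger
    absolute value = better).  ``ranking`` is a permutation of 1..m with the
    most promising biomarker first.
    """

    method: str
    scores: np.ndarray
    ranking: np.ndarray
    names: list[str] = field(default_factory=list)
    lambda_: float | None = None
    cv_seed: int | None = None
    cv_errors: pd.DataFrame | None = None

    @property
    def m(self) -> int:
        return self.scores.shape[0]

    def rank_of(self) -> np.ndarray:
        """Length-m vector: rank (1 = best) of each biomarker."""
        out = np.empty(self.m, dtype=int)
        out[self.ranking - 1] = np.arange(1, self.m + 1)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "biomarker": self.names or [f"X{j}" for j in range(1, self.m + 1)],
                "score": self.scores,
                "rank": self.rank_of(),
                "method": self.method,
                "lambda": self.lambda_ if self.lambda_ is not None else np.nan,
            }
        )


def univariate_screen(data: TrialDataset) -> ScreeningResult:
    """Marginal association screen: simple linear regression of Y on each Xj.

    Returns the two-sided t-test p-value for each slope (n-2 df,
    homoscedastic).  Constant biomarker columns are assigned p = 1 with a
    warning and rank last.  Ranking is by ascending p-value, ties broken by
    column index.
    """
    n = data.n
    if n < 3:
        raise ConfigurationError("univariate screening needs n >= 3")
    y = data.outcome
    x = data.biomarkers
    xc = x - x.mean(axis=0)
    yc = y - y.mean()
    sxx = np.einsum("ij,ij->j", xc, xc)
    constant = sxx <= 0.0
    if constant.any():
        bad = [data.names[j] for j in np.flatnonzero(constant)]
        warnings.warn(f"constant biomarker column(s) assigned p=1: {bad}", stacklevel=2)
    sxx_safe = np.where(constant, 1.0, sxx)
    slope = (xc.T @ yc) / sxx_safe
    rss = yc @ yc - slope**2 * sxx_safe
    sigma2 = np.maximum(rss, 0.0) / (n - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(sigma2 / sxx_safe)
        tstat = np.where(se > 0.0, slope / np.where(se > 0.0, se, 1.0), np.inf)
    pvals = 2.0 * stats.t.sf(np.abs(tstat), df=n - 2)
    pvals = np.where(constant, 1.0, pvals)
    # ascending p, constant columns last, ties by column index (stable sort)
    order = np.lexsort((np.arange(data.m), constant, pvals))
    return ScreeningResult(
        method="univariate",
        scores=pvals,
        ranking=order + 1,
        names=list(data.names),
    )


def default_lambda_grid(d: np.ndarray, y: np.ndarray, n_lambda: int = 100, eps: float = 1e-4) -> np.ndarray:
    """glmnet-style grid: n_lambda log-spaced values from a data-driven
    lambda_max = ||D'y||_inf down to lambda_max * eps, descending."""
    lam_max = float(np.abs(d.T @ y).max())
    if lam_max <= 0.0:
        lam_max = 1.0
    return np.geomspace(lam_max, lam_max * eps, n_lambda)


def _stratified_folds(
    treatment: np.ndarray, n_folds: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Fold index arrays, stratified by treatment arm, seeded."""
    folds: list[list[np.ndarray]] = [[] for _ in range(n_folds)]
    for arm in (0.0, 1.0):
        idx = np.flatnonzero(treatment == arm)
        rng.shuffle(idx)
        for k, part in enumerate(np.array_split(idx, n_folds)):
            folds[k].append(part)
    return [np.sort(np.concatenate(parts)) for parts in folds]


def _ridge_path(gram: np.ndarray, xty: np.ndarray, lambdas: np.ndarray) -> np.ndarray:
    """Ridge solutions (p x n_lambda) for all penalties via one eigendecomposition."""
    w, v = np.linalg.eigh(gram)
    w = np.maximum(w, 0.0)
    proj = v.T @ xty
    return v @ (proj[:, None] / (w[:, None] + lambdas[None, :]))


def ridge_screen(
    data: TrialDataset,
    n_folds: int = 5,
    lambda_grid: np.ndarray | None = None,
    cv_seed: int = 0,
    n_lambda: int = 100,
) -> ScreeningResult:
    """Multivariate ridge screen with treatment main effect.

    Y, T and each Xj are centered; Xj are additionally standardized to unit
    variance.  A single penalty (chosen to minimize five-fold
    cross-validated mean squared prediction error over the grid) is shared
    by the treatment and all biomarker coefficients.  Biomarkers are ranked
    by descending absolute standardized coefficient; the treatment
    coefficient never enters the ranking.  Ties break by column index.
    """
    n, m = data.n, data.m
    if n_folds < 2:
        raise ConfigurationError("ridge screening needs n_folds >= 2")
    if n < n_folds:
        raise ConfigurationError(f"n={n} smaller than n_folds={n_folds}")
    sd = data.biomarkers.std(axis=0)
    if (sd <= 0.0).any():
        bad = [data.names[j] for j in np.flatnonzero(sd <= 0.0)]
        raise ConfigurationError(f"constant biomarker column(s) cannot be standardized: {bad}")
    yc = data.outcome - data.outcome.mean()
    tc = data.treatment - data.treatment.mean()
    xs = (data.biomarkers - data.biomarkers.mean(axis=0)) / sd
    d = np.column_stack([tc, xs])

    if lambda_grid is None:
        lambdas = default_lambda_grid(d, yc, n_lambda=n_lambda)
    else:
        lambdas = np.asarray(lambda_grid, dtype=float)
    if lambdas.size == 0:
        raise ConfigurationError("lambda grid is empty")
    lambdas = np.sort(lambdas)[::-1]  # descending; earliest index = strongest penalty

    rng = np.random.default_rng(cv_seed)
    folds = _stratified_folds(data.treatment, n_folds, rng)
    for fold in folds:
        if n - fold.size < 2 or fold.size < 1:
            raise ConfigurationError("degenerate cross-validation fold (fewer than 2 rows)")

    gram = d.T @ d
    xty = d.T @ yc
    sse = np.zeros(lambdas.size)
    for fold in folds:
        d_te = d[fold]
        y_te = yc[fold]
        gram_tr = gram - d_te.T @ d_te
        xty_tr = xty - d_te.T @ y_te
        coefs = _ridge_path(gram_tr, xty_tr, lambdas)
        resid = y_te[:, None] - d_te @ coefs
        sse += np.einsum("ik,ik->k", resid, resid)
    cv_mse = sse / n
    best = int(np.argmin(cv_mse))  # ties -> largest lambda (first index)
    lam = float(lambdas[best])

    coef = _ridge_path(gram, xty, np.array([lam]))[:, 0]
    scores = coef[1:]  # drop treatment coefficient
    order = np.lexsort((np.arange(m), -np.abs(scores)))
    return ScreeningResult(
        method="ridge",
        scores=scores,
        ranking=order + 1,
        names=list(data.names),
        lambda_=lam,
        cv_seed=cv_seed,
        cv_errors=pd.DataFrame({"lambda": lambdas, "cv_mse": cv_mse}),
    )
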