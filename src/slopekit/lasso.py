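"""L1-penalized prediction of treatment slopes.

The estimator minimizes (1/2n)||y - X beta - b0||^2 + lambda * ||beta||_1 by
coordinate descent (see :mod:`slopekit._cd`).  The evaluation scheme is
leave-one-out outer CV with, inside every training fold: covariate
residualization (batch/sex/RIN, fit on the fold's training samples only),
feature standardization, a 10-fold inner CV to pick lambda from a log-spaced
grid anchored at the fold's lambda_max, and a final fit that predicts the
held-out subject.  Model significance comes from a permutation null that
reruns the entire scheme on shuffled outcomes.

Because the covariate residualization involves only the features and the
nuisance table - never the outcome - the per-fold residualized/standardized
feature blocks are precomputed once and shared across permutation
replicates; this is numerically identical to rerunning them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd

from . import preprocess
from ._cd import cd_lasso, inner_cv_fold_mse

__all__ = [
    "LassoModel",
    "CVResult",
    "PermutationNull",
    "PrioritizedSet",
    "lasso_fit",
    "lasso_objective",
    "lambda_max",
    "lambda_grid",
    "inner_cv_lambda",
    "loocv_predict",
    "permutation_test_mse",
    "prioritize_features",
]


@dataclass
class LassoModel:
    lambda_: float
    intercept: float
    coef: np.ndarray
    n_sweeps: int = 0

    @property
    def support(self) -> np.ndarray:
        return np.flatnonzero(self.coef)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.intercept + np.asarray(X, dtype=float) @ self.coef


@dataclass
class CVResult:
    predictions: pd.Series
    per_fold_lambda: np.ndarray
    mse: float
    r2: float
    per_fold_support: List[np.ndarray] = field(default_factory=list)
    seed: int | None = None


@dataclass
class PermutationNull:
    observed_mse: float
    null_mses: np.ndarray
    p: float
    B: int
    seed: int | None


@dataclass
class PrioritizedSet:
    feature_ids: list
    weights: np.ndarray
    lambda_: float


def _as_xy(X, y) -> Tuple[np.ndarray, list, np.ndarray]:
    if isinstance(X, pd.DataFrame):
        features = list(X.columns)
        Xv = X.to_numpy(dtype=float)
    else:
        Xv = np.asarray(X, dtype=float)
        features = list(range(Xv.shape[1]))
    yv = np.asarray(y, dtype=float).ravel()
    if Xv.shape[0] != yv.shape[0]:
        raise ValueError("X and y have different numbers of samples")
    if not (np.isfinite(Xv).all() and np.isfinite(yv).all()):
        raise ValueError("non-finite values in X or y")
    return Xv, features, yv


def lasso_objective(X, y, beta, intercept, lam: float) -> float:
    """(1/2n)||y - X beta - b0||^2 + lam * ||beta||_1 (for diagnostics/tests)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    r = y - intercept - X @ beta
    return float(r @ r / (2 * len(y)) + lam * np.abs(beta).sum())


def lambda_max(X, y) -> float:
    """Smallest penalty at which all coefficients are exactly zero."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    return float(np.abs(X.T @ (y - y.mean())).max() / len(y))


def lambda_grid(X, y, n_lambdas: int = 100, min_ratio: float = 1e-3) -> np.ndarray:
    """Descending log-spaced grid from lambda_max down to min_ratio*lambda_max."""
    lmax = max(lambda_max(X, y), 1e-12)
    return np.geomspace(lmax, min_ratio * lmax, n_lambdas)


def lasso_fit(
    X, y, lam: float, tol: float = 1e-7, max_iter: int = 100000
) -> LassoModel:
    """Coordinate-descent LASSO fit; X columns must be standardized upstream.

    Converged when the largest per-sweep coefficient change is below ``tol``.
    """
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    Xv, _, yv = _as_xy(X, y)
    sd = Xv.std(axis=0)
    if (sd == 0).any():
        raise ValueError(
            f"{int((sd == 0).sum())} zero-variance feature column(s); drop them "
            "before standardization"
        )
    n = len(yv)
    intercept = float(yv.mean())
    yc = yv - intercept
    XtX = Xv.T @ Xv
    Xty = Xv.T @ yc
    beta = np.zeros(Xv.shape[1])
    sweeps = cd_lasso(XtX, Xty, n, lam, beta, max_iter, tol)
    if sweeps < 0:
        raise RuntimeError(f"coordinate descent did not converge in {max_iter} sweeps")
    return LassoModel(lambda_=float(lam), intercept=intercept, coef=beta, n_sweeps=int(sweeps))


def inner_cv_lambda(
    X,
    y,
    k: int = 10,
    grid: Sequence[float] | None = None,
    seed=None,
    tol: float = 1e-5,
    max_iter: int = 1000,
) -> float:
    """Pick the grid lambda minimizing mean held-out MSE over k seeded folds.

    Ties resolve to the largest (sparsest) lambda.  The fold fits use a
    looser tolerance than the final fits: the selected lambda is insensitive
    to late-stage coefficient polishing, and the small-lambda end of the
    path converges slowly when p > n.
    """
    Xv, _, yv = _as_xy(X, y)
    n = len(yv)
    if not 2 <= k <= n:
        raise ValueError("need n >= k >= 2")
    grid_arr = _prep_grid(Xv, yv, grid, 100, 1e-3)
    rng = np.random.default_rng(seed)
    fold_id = rng.permutation(n) % k
    fold_mse = inner_cv_fold_mse(
        np.ascontiguousarray(Xv), yv, fold_id.astype(np.int64), k, grid_arr, max_iter, tol
    )
    mean_mse = fold_mse.mean(axis=0)
    return float(grid_arr[int(np.argmin(mean_mse))])


def _prep_grid(Xv, yv, grid, n_lambdas, min_ratio) -> np.ndarray:
    if grid is None:
        return lambda_grid(Xv, yv, n_lambdas, min_ratio)
    grid_arr = np.sort(np.asarray(list(grid), dtype=float))[::-1].copy()
    if grid_arr.size == 0:
        raise ValueError("empty lambda grid")
    if (grid_arr < 0).any():
        raise ValueError("lambda grid must be non-negative")
    return grid_arr


def _prepare_loocv_folds(X, covariates):
    """Per-held-out-subject residualized+standardized feature blocks.

    Depends on the features and nuisance covariates only, never on y, so the
    result can be reused across permutation replicates.  Returns a list of
    (X_train_std, x_test_std, kept_column_indices).
    """
    if isinstance(X, pd.DataFrame):
        Xdf = X.copy()
    else:
        X = np.asarray(X, dtype=float)
        Xdf = pd.DataFrame(X, columns=[str(j) for j in range(X.shape[1])])
        Xdf.index = [str(i) for i in range(X.shape[0])]
    n = len(Xdf)
    folds = []
    for i in range(n):
        tr_idx = np.r_[0:i, i + 1 : n]
        if covariates is not None:
            cov = covariates.loc[Xdf.index] if isinstance(covariates, pd.DataFrame) else None
            if cov is None:
                raise ValueError("covariates must be a DataFrame indexed by sample id")
            expr = Xdf.T  # features x samples for the preprocess contract
            tr_resid, te_resid = preprocess.residualize_covariates(
                expr.iloc[:, tr_idx], cov.iloc[tr_idx],
                expr.iloc[:, [i]], cov.iloc[[i]],
            )
            Xtr = tr_resid.to_numpy().T
            xte = te_resid.to_numpy().T[0]
        else:
            Xtr = Xdf.to_numpy(dtype=float)[tr_idx]
            xte = Xdf.to_numpy(dtype=float)[i]
        mu = Xtr.mean(axis=0)
        sd = Xtr.std(axis=0)
        keep = np.flatnonzero(sd > 0)
        Xtr_std = (Xtr[:, keep] - mu[keep]) / sd[keep]
        xte_std = (xte[keep] - mu[keep]) / sd[keep]
        folds.append((np.ascontiguousarray(Xtr_std), xte_std, keep))
    return folds


def _loocv_given_folds(
    folds,
    y: np.ndarray,
    grid,
    n_lambdas: int,
    min_ratio: float,
    k_inner: int,
    seed,
    tol: float,
    max_iter: int,
    r2_method: str,
    index=None,
    inner_tol: float = 1e-5,
    inner_max_iter: int = 1000,
):
    n = len(y)
    if np.ptp(y) == 0:
        raise ValueError("constant outcome: cross-validated R^2 is undefined")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(n)
    preds = np.empty(n)
    lams = np.empty(n)
    supports = []
    for i, (Xtr, xte, keep) in enumerate(folds):
        ytr = np.delete(y, i)
        grid_i = _prep_grid(Xtr, ytr, grid, n_lambdas, min_ratio)
        k_eff = min(k_inner, len(ytr))
        rng = np.random.default_rng(children[i])
        fold_id = rng.permutation(len(ytr)) % k_eff
        fold_mse = inner_cv_fold_mse(
            Xtr, ytr, fold_id.astype(np.int64), k_eff, grid_i, inner_max_iter, inner_tol
        )
        lam = float(grid_i[int(np.argmin(fold_mse.mean(axis=0)))])
        mu = ytr.mean()
        beta = np.zeros(Xtr.shape[1])
        XtX = Xtr.T @ Xtr
        Xty = Xtr.T @ (ytr - mu)
        cd_lasso(XtX, Xty, len(ytr), lam, beta, max_iter, tol)
        preds[i] = mu + xte @ beta
        lams[i] = lam
        supports.append(keep[np.flatnonzero(beta)])
    sse = float(np.sum((y - preds) ** 2))
    mse = sse / n
    if r2_method == "ratio":
        r2 = 1.0 - sse / float(np.sum((y - y.mean()) ** 2))
    elif r2_method == "correlation":
        if np.ptp(preds) == 0:
            r2 = 0.0
        else:
            r2 = float(np.corrcoef(y, preds)[0, 1] ** 2)
    else:
        raise ValueError("r2_method must be 'ratio' or 'correlation'")
    predictions = pd.Series(preds, index=index) if index is not None else pd.Series(preds)
    return CVResult(
        predictions=predictions,
        per_fold_lambda=lams,
        mse=float(mse),
        r2=float(r2),
        per_fold_support=supports,
    )


def loocv_predict(
    X,
    y,
    covariates: pd.DataFrame | None = None,
    grid: Sequence[float] | None = None,
    n_lambdas: int = 100,
    min_ratio: float = 1e-3,
    k_inner: int = 10,
    seed=None,
    tol: float = 1e-7,
    max_iter: int = 100000,
    r2_method: str = "ratio",
    inner_tol: float = 1e-5,
    inner_max_iter: int = 1000,
) -> CVResult:
    """Leave-one-out evaluation of the full residualize/standardize/LASSO chain.

    For every subject i the nuisance model, the feature scaling, the lambda
    grid and the inner 10-fold selection are all computed on the other n-1
    subjects; subject i is only ever scored.  R^2 defaults to 1 - SSE/SST on
    the held-out predictions (may be negative); ``r2_method='correlation'``
    gives the squared Pearson alternative.
    """
    Xv, _, yv = _as_xy(X, y)
    if len(yv) < 10:
        raise ValueError("need at least 10 subjects for LOOCV")
    folds = _prepare_loocv_folds(X, covariates)
    index = X.index if isinstance(X, pd.DataFrame) else None
    res = _loocv_given_folds(
        folds, yv, grid, n_lambdas, min_ratio, k_inner, seed, tol, max_iter,
        r2_method, index=index, inner_tol=inner_tol, inner_max_iter=inner_max_iter,
    )
    res.seed = seed
    return res


def permutation_test_mse(
    X,
    y,
    covariates: pd.DataFrame | None = None,
    B: int = 1000,
    seed=None,
    grid: Sequence[float] | None = None,
    n_lambdas: int = 100,
    min_ratio: float = 1e-3,
    k_inner: int = 10,
    tol: float = 1e-7,
    max_iter: int = 100000,
    inner_tol: float = 1e-5,
    inner_max_iter: int = 1000,
) -> PermutationNull:
    """Permutation null for the cross-validated MSE.

    Every replicate shuffles the raw outcomes and reruns the complete LOOCV
    scheme (the feature-side preprocessing is outcome-free and therefore
    shared); p = (1 + #{null <= observed}) / (B + 1).
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    Xv, _, yv = _as_xy(X, y)
    folds = _prepare_loocv_folds(X, covariates)
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(B + 1)
    observed = _loocv_given_folds(
        folds, yv, grid, n_lambdas, min_ratio, k_inner, children[0], tol,
        max_iter, "ratio", inner_tol=inner_tol, inner_max_iter=inner_max_iter,
    ).mse
    null = np.empty(B)
    for b in range(B):
        rng = np.random.default_rng(children[b + 1])
        y_b = rng.permutation(yv)
        null[b] = _loocv_given_folds(
            folds, y_b, grid, n_lambdas, min_ratio, k_inner, children[b + 1],
            tol, max_iter, "ratio", inner_tol=inner_tol, inner_max_iter=inner_max_iter,
        ).mse
    p = (1.0 + np.count_nonzero(null <= observed)) / (B + 1.0)
    return PermutationNull(
        observed_mse=float(observed), null_mses=null, p=float(p), B=B, seed=seed
    )


def prioritize_features(
    X,
    y,
    covariates: pd.DataFrame | None = None,
    grid: Sequence[float] | None = None,
    n_lambdas: int = 100,
    min_ratio: float = 1e-3,
    k: int = 10,
    seed=None,
    tol: float = 1e-7,
    max_iter: int = 100000,
) -> PrioritizedSet:
    """Single full-data refit: residualize and standardize on all subjects,
    pick lambda by k-fold CV, fit once, return the nonzero features."""
    Xv, features, yv = _as_xy(X, y)
    if covariates is not None:
        if isinstance(X, pd.DataFrame):
            expr = X.T
            cov = covariates.loc[X.index]
        else:
            raise ValueError("covariates require a DataFrame X indexed by sample id")
        resid, _ = preprocess.residualize_covariates(expr, cov)
        Xv = resid.to_numpy().T
    mu = Xv.mean(axis=0)
    sd = Xv.std(axis=0)
    keep = np.flatnonzero(sd > 0)
    Xs = (Xv[:, keep] - mu[keep]) / sd[keep]
    grid_arr = _prep_grid(Xs, yv, grid, n_lambdas, min_ratio)
    lam = inner_cv_lambda(Xs, yv, k=min(k, len(yv)), grid=grid_arr, seed=seed,
                          tol=tol, max_iter=max_iter)
    model = lasso_fit(Xs, yv, lam, tol=tol, max_iter=max_iter)
    nz = model.support
    return PrioritizedSet(
        feature_ids=[features[keep[j]] for j in nz],
        weights=model.coef[nz],
        lambda_=lam,
    )
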