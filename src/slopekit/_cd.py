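"""Numba coordinate-descent kernels for the L1 path.

All kernels work on Gram matrices (covariance updates), minimizing

    (1/2n) * ||y - X beta||^2 + lam * sum_j |beta_j|

with the intercept handled by centering y outside the kernel.  A running
gradient g = X'y - X'X beta makes each coordinate update O(p) only when the
coefficient actually moves.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def cd_lasso(XtX, Xty, n, lam, beta, max_iter, tol):
    """In-place coordinate descent; returns the number of sweeps used
    (negative if the tolerance was not reached)."""
    p = beta.shape[0]
    grad = Xty - XtX @ beta
    thr = lam * n
    for sweep in range(max_iter):
        max_change = 0.0
        for j in range(p):
            old = beta[j]
            rho = grad[j] + XtX[j, j] * old  # x_j' (y - X beta_{-j})
            if rho > thr:
                new = (rho - thr) / XtX[j, j]
            elif rho < -thr:
                new = (rho + thr) / XtX[j, j]
            else:
                new = 0.0
            d = new - old
            if d != 0.0:
                beta[j] = new
                for k in range(p):
                    grad[k] -= XtX[k, j] * d
                ad = abs(d)
                if ad > max_change:
                    max_change = ad
        if max_change < tol:
            return sweep + 1
    return -max_iter


@njit(cache=True)
def cd_path(XtX, Xty, n, lams, max_iter, tol):
    """Warm-started path over a (descending) lambda grid; returns the
    (n_lambda, p) coefficient array."""
    p = Xty.shape[0]
    betas = np.zeros((lams.shape[0], p))
    beta = np.zeros(p)
    for i in range(lams.shape[0]):
        cd_lasso(XtX, Xty, n, lams[i], beta, max_iter, tol)
        betas[i] = beta
    return betas


@njit(cache=True)
def inner_cv_fold_mse(X, y, fold_id, k, lams, max_iter, tol):
    """Mean held-out squared error per lambda across k prebuilt folds.

    Each fold fits the full warm-started path on its training part (y
    centered on the training mean) and scores the held-out part.  Returns
    the (k, n_lambda) per-fold MSE matrix.
    """
    n, p = X.shape
    n_lam = lams.shape[0]
    fold_mse = np.zeros((k, n_lam))
    for f in range(k):
        n_tr = 0
        n_te = 0
        for i in range(n):
            if fold_id[i] == f:
                n_te += 1
            else:
                n_tr += 1
        Xtr = np.empty((n_tr, p))
        ytr = np.empty(n_tr)
        Xte = np.empty((n_te, p))
        yte = np.empty(n_te)
        a = 0
        b = 0
        for i in range(n):
            if fold_id[i] == f:
                Xte[b] = X[i]
                yte[b] = y[i]
                b += 1
            else:
                Xtr[a] = X[i]
                ytr[a] = y[i]
                a += 1
        mu = ytr.mean()
        yc = ytr - mu
        XtX = Xtr.T @ Xtr
        Xty = Xtr.T @ yc
        beta = np.zeros(p)
        for li in range(n_lam):
            cd_lasso(XtX, Xty, n_tr, lams[li], beta, max_iter, tol)
            err = 0.0
            for i in range(n_te):
                pred = mu
                for j in range(p):
                    if beta[j] != 0.0:
                        pred += Xte[i, j] * beta[j]
                err += (yte[i] - pred) ** 2
            fold_mse[f, li] = err / n_te
    return fold_mse
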