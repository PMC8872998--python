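"""Expression-matrix preprocessing: quantile normalization, top-fraction
variance filtering, and train-fit/test-apply covariate residualization.

Matrices are pandas DataFrames shaped features x samples (log2 scale).
Sample covariates are a DataFrame indexed by sample id with columns
``batch`` (categorical), ``sex`` (categorical) and ``rin`` (continuous).
Residualization estimates nuisance effects on the *training* samples only
and applies the fitted model to held-out samples, so no test information
leaks into the fit.
"""

from __future__ import annotations

import math
from typing import Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "quantile_normalize",
    "variance_filter",
    "covariate_design",
    "residualize_covariates",
]


def _check_finite(df: pd.DataFrame, what: str = "expression matrix") -> None:
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError(f"empty {what}")
    vals = df.to_numpy()
    if not np.isfinite(vals).all():
        raise ValueError(f"{what} contains missing or non-finite values")


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every sample (column) onto the common reference distribution.

    The reference is the across-sample mean of the column-sorted values.
    Ties within a column receive the mean of the reference values spanned
    by the tied ranks.  Row and column labels are preserved.

    Note: with tied values the output columns are no longer an exact
    permutation of the reference, so idempotency is exact only for
    tie-free input (the generic case for continuous intensities).
    """
    _check_finite(matrix)
    vals = matrix.to_numpy(dtype=float)
    n_rows, n_cols = vals.shape
    order = np.argsort(vals, axis=0, kind="stable")
    ref = np.mean(np.take_along_axis(vals, order, axis=0), axis=1)

    out = np.empty_like(vals)
    for j in range(n_cols):
        o = order[:, j]
        sorted_col = vals[o, j]
        # run-length group equal values; each run gets the mean reference value
        change = np.empty(n_rows, dtype=bool)
        change[0] = True
        np.not_equal(sorted_col[1:], sorted_col[:-1], out=change[1:])
        starts = np.flatnonzero(change)
        run_means = np.add.reduceat(ref, starts) / np.diff(np.append(starts, n_rows))
        out[o, j] = run_means[np.cumsum(change) - 1]
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def variance_filter(matrix: pd.DataFrame, keep_fraction: float = 0.5) -> pd.DataFrame:
    """Keep the ``ceil(keep_fraction * n_features)`` rows with highest variance.

    Variance uses denominator n-1.  Surviving rows keep their original order.
    The result is invariant to sample (column) reordering.
    """
    _check_finite(matrix)
    if not 0 < keep_fraction <= 1:
        raise ValueError("keep_fraction must be in (0, 1]")
    n = matrix.shape[0]
    k = math.ceil(keep_fraction * n)
    variances = matrix.to_numpy(dtype=float).var(axis=1, ddof=1)
    top = np.argsort(-variances, kind="stable")[:k]
    keep = np.zeros(n, dtype=bool)
    keep[top] = True
    return matrix.loc[keep]


def covariate_design(
    covariates: pd.DataFrame,
    batch_levels: Sequence | None = None,
    sex_levels: Sequence | None = None,
) -> np.ndarray:
    """Build the nuisance design: intercept + batch dummies + sex dummies + RIN.

    Reference (first) levels are dropped.  When ``batch_levels``/``sex_levels``
    are given (the training levels), unseen categories raise.
    """
    required = {"batch", "sex", "rin"}
    missing = required - set(covariates.columns)
    if missing:
        raise ValueError(f"covariate table missing columns: {sorted(missing)}")
    cols = [np.ones(len(covariates))]
    for field, levels in (("batch", batch_levels), ("sex", sex_levels)):
        observed = covariates[field].astype(str)
        if levels is None:
            levels = sorted(observed.unique())
        else:
            levels = [str(l) for l in levels]
            unseen = set(observed) - set(levels)
            if unseen:
                raise ValueError(
                    f"unseen {field} level(s) in test samples: {sorted(unseen)}; "
                    "fold construction must stratify"
                )
        for level in levels[1:]:
            cols.append((observed == level).to_numpy(dtype=float))
    rin = covariates["rin"].to_numpy(dtype=float)
    if not np.isfinite(rin).all() or (rin < 0).any():
        raise ValueError("rin must be finite and non-negative")
    cols.append(rin)
    return np.column_stack(cols)


def residualize_covariates(
    train: pd.DataFrame,
    train_cov: pd.DataFrame,
    test: pd.DataFrame | None = None,
    test_cov: pd.DataFrame | None = None,
) -> Tuple[pd.DataFrame, pd.DataFrame | None]:
    """Remove batch/sex/RIN variance, fitting on training samples only.

    Per feature, expression is regressed on the nuisance design by least
    squares using the training samples; residuals = value - fitted for both
    the training and (optionally) the test matrix.  Training residuals are
    exactly orthogonal to the training design.
    """
    _check_finite(train)
    train_cov = train_cov.loc[train.columns]
    batch_levels = sorted(train_cov["batch"].astype(str).unique())
    sex_levels = sorted(train_cov["sex"].astype(str).unique())
    design = covariate_design(train_cov, batch_levels, sex_levels)
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        raise ValueError(
            f"covariate design is rank deficient on training samples "
            f"(rank {rank} < {design.shape[1]} columns)"
        )
    y = train.to_numpy(dtype=float).T  # samples x features
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    train_resid = pd.DataFrame(
        (y - design @ coef).T, index=train.index, columns=train.columns
    )
    if test is None:
        return train_resid, None
    _check_finite(test, "test expression matrix")
    if test_cov is None:
        raise ValueError("test_cov required when a test matrix is given")
    test_cov = test_cov.loc[test.columns]
    test_design = covariate_design(test_cov, batch_levels, sex_levels)
    y_test = test.to_numpy(dtype=float).T
    test_resid = pd.DataFrame(
        (y_test - test_design @ coef).T, index=test.index, columns=test.columns
    )
    return train_resid, test_resid
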