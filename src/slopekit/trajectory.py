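"""Random-intercept/random-slope linear mixed models for longitudinal
outcomes, subject-level treatment-slope extraction (fixed slope + BLUP
deviation), the covariate-adjusted start-group model, and a permutation
test for group differences in slope variability.

Estimation is REML with the fixed effects and residual variance profiled
out, optimizing over the scaled random-effect covariance Lambda = G/sigma2
through its log-Cholesky factor.  With V_i = sigma2 * (I + Z_i Lambda Z_i')
per subject, the push-through identity reduces every objective evaluation
to batched 2x2 algebra over precomputed per-subject cross-products:

    Vt^-1   = I - Z C Z',     C = Lambda (I_2 + Z'Z Lambda)^-1
    log|Vt| = log|I_2 + Z'Z Lambda|
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "LMMFit",
    "VarianceDiffResult",
    "LMMConvergenceError",
    "fit_lmm",
    "fit_trajectory_model",
    "extract_treatment_slopes",
    "fit_group_model",
    "sd_difference_test",
]


class LMMConvergenceError(RuntimeError):
    """REML optimization failed; ``last_fit`` carries the final iterate."""

    def __init__(self, message: str, last_fit: "LMMFit | None" = None):
        super().__init__(message)
        self.last_fit = last_fit


@dataclass
class LMMFit:
    """REML fit of y_ij = x_ij'beta + b0_i + b1_i * t_ij + e_ij."""

    beta: pd.Series
    G: np.ndarray  # 2x2 random-effect covariance (intercept, slope)
    sigma2: float
    blups: pd.DataFrame  # per subject: b0, b1 deviations
    reml_loglik: float
    fixed_tests: pd.DataFrame  # per term: F, df_num, df_den, p
    cov_beta: np.ndarray
    converged: bool
    n_obs: int
    n_subjects: int
    random_slope_col: str = "age"


@dataclass
class VarianceDiffResult:
    sd_early: float
    sd_late: float
    observed_diff: float  # sd_late - sd_early
    null_diffs: np.ndarray
    p: float
    B: int
    seed: int | None


class _Stacks:
    """Per-subject cross-products; everything the REML objective needs."""

    def __init__(self, records, design, subject_col, outcome_col, slope_col):
        y_all = records[outcome_col].to_numpy(dtype=float)
        t_all = design[slope_col].to_numpy(dtype=float)
        X_all = design.to_numpy(dtype=float)
        p = X_all.shape[1]
        groups = records.groupby(subject_col, sort=True).indices
        n_subj = len(groups)
        self.subjects = list(groups.keys())
        self.S = np.empty((n_subj, 2, 2))
        self.T = np.empty((n_subj, 2, p))
        self.u2 = np.empty((n_subj, 2))
        for i, idx in enumerate(groups.values()):
            Z = np.column_stack([np.ones(len(idx)), t_all[idx]])
            self.S[i] = Z.T @ Z
            self.T[i] = Z.T @ X_all[idx]
            self.u2[i] = Z.T @ y_all[idx]
        self.XtX = X_all.T @ X_all
        self.Xty = X_all.T @ y_all
        self.yty = float(y_all @ y_all)
        self.N = len(y_all)
        self.p = p

    def components(self, Lam: np.ndarray):
        """A = sum X'Vt^-1 X, u = sum X'Vt^-1 y, q = sum y'Vt^-1 y, log|Vt|."""
        IS = np.eye(2)[None, :, :] + self.S @ Lam
        C = np.einsum("ab,nbc->nac", Lam, np.linalg.inv(IS))
        C = 0.5 * (C + C.transpose(0, 2, 1))  # symmetric up to round-off
        _, logdets = np.linalg.slogdet(IS)
        A = self.XtX - np.einsum("nka,nkl,nlb->ab", self.T, C, self.T, optimize=True)
        u = self.Xty - np.einsum("nka,nkl,nl->a", self.T, C, self.u2, optimize=True)
        q = self.yty - float(np.einsum("nk,nkl,nl->", self.u2, C, self.u2))
        return A, u, q, float(logdets.sum()), C

    def blups(self, C: np.ndarray, beta: np.ndarray) -> np.ndarray:
        """b_i = Lambda Z' Vt^-1 (y - X beta) = C (Z'y - Z'X beta)."""
        resid2 = self.u2 - self.T @ beta
        return np.einsum("nkl,nl->nk", C, resid2)


def _lam_from_theta(theta: np.ndarray) -> np.ndarray:
    L = np.array([[np.exp(theta[0]), 0.0], [theta[1], np.exp(theta[2])]])
    return L @ L.T


def fit_lmm(
    records: pd.DataFrame,
    fixed_design: pd.DataFrame | None = None,
    subject_col: str = "subject_id",
    outcome_col: str = "outcome",
    random_slope_col: str = "age",
    fix_G: np.ndarray | None = None,
    fix_sigma2: float | None = None,
    maxiter: int = 5000,
) -> LMMFit:
    """REML fit with random intercepts and random slopes per subject.

    ``fixed_design`` is a per-record DataFrame of fixed-effect columns
    (default: intercept + the random-slope column).  Passing both ``fix_G``
    and ``fix_sigma2`` skips optimization and returns the GLS fixed effects,
    BLUPs and REML log-likelihood at those variance components.
    """
    records = records.reset_index(drop=True)
    if fixed_design is None:
        fixed_design = pd.DataFrame(
            {
                "intercept": np.ones(len(records)),
                random_slope_col: records[random_slope_col].to_numpy(dtype=float),
            }
        )
    else:
        fixed_design = fixed_design.reset_index(drop=True)
        if len(fixed_design) != len(records):
            raise ValueError("fixed_design and records have different lengths")
    if records[subject_col].nunique() < 2:
        raise ValueError("need at least 2 subjects")
    if not np.isfinite(records[random_slope_col].to_numpy(dtype=float)).all():
        raise ValueError("non-finite values in the random-slope column")

    Xmat = fixed_design.to_numpy(dtype=float)
    if np.linalg.matrix_rank(Xmat) < Xmat.shape[1]:
        raise ValueError("fixed-effect design is rank deficient")
    if (fix_G is None) != (fix_sigma2 is None):
        raise ValueError("fix_G and fix_sigma2 must be given together")

    stacks = _Stacks(records, fixed_design, subject_col, outcome_col, random_slope_col)
    N, p = stacks.N, stacks.p
    terms = list(fixed_design.columns)

    if fix_G is not None:
        G = np.asarray(fix_G, dtype=float)
        sigma2 = float(fix_sigma2)
        Lam = G / sigma2
        A, u, q, logdetVt, C = stacks.components(Lam)
        beta = np.linalg.solve(A, u)
        rss = q - float(u @ beta)
        _, logdetA = np.linalg.slogdet(A)
        loglik = -0.5 * (
            (N - p) * np.log(sigma2)
            + logdetVt
            + logdetA
            + rss / sigma2
            + (N - p) * np.log(2 * np.pi)
        )
        return _finish_fit(
            records, fixed_design, stacks, terms, beta, G, sigma2, C,
            A, loglik, subject_col, random_slope_col, converged=True,
        )

    # perfect-fit degenerate case: zero-noise data breaks the REML profile
    y_all = records[outcome_col].to_numpy(dtype=float)
    ols, *_ = np.linalg.lstsq(Xmat, y_all, rcond=None)
    if float(np.mean((y_all - Xmat @ ols) ** 2)) < 1e-12:
        blups = pd.DataFrame(
            np.zeros((len(stacks.subjects), 2)),
            index=pd.Index(stacks.subjects, name=subject_col), columns=["b0", "b1"],
        )
        A = Xmat.T @ Xmat
        cov_beta = 1e-12 * np.linalg.inv(A)
        tests = _wald_tests(terms, ols, cov_beta, records, fixed_design, subject_col)
        return LMMFit(
            beta=pd.Series(ols, index=terms), G=np.zeros((2, 2)), sigma2=0.0,
            blups=blups, reml_loglik=np.inf, fixed_tests=tests, cov_beta=cov_beta,
            converged=True, n_obs=N, n_subjects=len(stacks.subjects),
            random_slope_col=random_slope_col,
        )

    def objective(theta: np.ndarray) -> float:
        Lam = _lam_from_theta(theta)
        try:
            A, u, q, logdetVt, _ = stacks.components(Lam)
            beta = np.linalg.solve(A, u)
            rss = max(q - float(u @ beta), 1e-300)
            sigma2 = rss / (N - p)
            _, logdetA = np.linalg.slogdet(A)
            return 0.5 * (
                (N - p) * (np.log(sigma2) + 1 + np.log(2 * np.pi))
                + logdetVt
                + logdetA
            )
        except np.linalg.LinAlgError:
            return np.inf

    # bounded quasi-Newton from a few starts; the box keeps the search off
    # the flat log-scale ray where a variance component degenerates to 0
    bounds = [(-8.0, 8.0), (-40.0, 40.0), (-8.0, 8.0)]
    best = None
    for theta0 in ([0.0, 0.0, 0.0], [-2.0, 0.0, -2.0], [1.0, 0.0, 1.0]):
        res = optimize.minimize(
            objective, theta0, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": maxiter, "maxfun": maxiter},
        )
        if best is None or res.fun < best.fun:
            best = res
    if not best.success:
        # tolerances sit above the objective's cancellation noise (~1e-5)
        nm = optimize.minimize(
            objective, best.x, method="Nelder-Mead",
            options={"maxiter": maxiter, "maxfev": maxiter, "xatol": 1e-5,
                     "fatol": 1e-7},
        )
        # a converged polish at least as good (to loglik noise) wins
        if nm.success and nm.fun <= best.fun + 1e-4:
            best = nm

    Lam = _lam_from_theta(best.x)
    A, u, q, logdetVt, C = stacks.components(Lam)
    beta = np.linalg.solve(A, u)
    rss = max(q - float(u @ beta), 1e-300)
    sigma2 = rss / (N - p)
    G = sigma2 * Lam
    fit = _finish_fit(
        records, fixed_design, stacks, terms, beta, G, sigma2, C,
        A, -best.fun, subject_col, random_slope_col, converged=bool(best.success),
    )
    if not best.success:
        raise LMMConvergenceError(
            f"REML optimization did not converge within {maxiter} evaluations",
            last_fit=fit,
        )
    return fit


def _finish_fit(
    records, fixed_design, stacks, terms, beta, G, sigma2, C,
    A, loglik, subject_col, random_slope_col, converged,
):
    blups = pd.DataFrame(
        stacks.blups(C, beta),
        index=pd.Index(stacks.subjects, name=subject_col), columns=["b0", "b1"],
    )
    cov_beta = sigma2 * np.linalg.inv(A)
    tests = _wald_tests(terms, beta, cov_beta, records, fixed_design, subject_col)
    return LMMFit(
        beta=pd.Series(beta, index=terms),
        G=G,
        sigma2=float(sigma2),
        blups=blups,
        reml_loglik=float(loglik),
        fixed_tests=tests,
        cov_beta=cov_beta,
        converged=converged,
        n_obs=stacks.N,
        n_subjects=len(stacks.subjects),
        random_slope_col=random_slope_col,
    )


def _wald_tests(terms, beta, cov_beta, records, design, subject_col):
    """Per-term Wald F with containment-style denominator df: terms constant
    within every subject use between-subject df, the rest within-subject df."""
    groups = list(records.groupby(subject_col, sort=False).indices.values())
    n_subj = len(groups)
    N = len(records)
    is_between = []
    for term in terms:
        col = design[term].to_numpy(dtype=float)
        is_between.append(all(np.ptp(col[np.asarray(idx)]) == 0 for idx in groups))
    p_between = sum(is_between)
    p_within = len(terms) - p_between
    df_between = max(n_subj - p_between, 1)
    df_within = max(N - n_subj - p_within, 1)
    rows = []
    for j, term in enumerate(terms):
        var_j = max(cov_beta[j, j], 1e-300)
        F = float(beta[j] ** 2 / var_j)
        df_den = df_between if is_between[j] else df_within
        rows.append((term, F, 1, df_den, float(stats.f.sf(F, 1, df_den))))
    return pd.DataFrame(
        rows, columns=["term", "F", "df_num", "df_den", "p"]
    ).set_index("term")


def fit_trajectory_model(
    records: pd.DataFrame,
    subject_col: str = "subject_id",
    outcome_col: str = "outcome",
    age_col: str = "age",
) -> LMMFit:
    """The base model: fixed intercept + age, random intercepts and slopes."""
    return fit_lmm(
        records, subject_col=subject_col, outcome_col=outcome_col,
        random_slope_col=age_col,
    )


def extract_treatment_slopes(fit: LMMFit, slope_term: str | None = None) -> pd.Series:
    """Per-subject treatment slope = fixed slope coefficient + BLUP deviation.

    Reported on the absolute scale (a total rate of change, not a deviation).
    """
    if not fit.converged:
        raise ValueError("cannot extract slopes from an unconverged fit")
    term = slope_term or fit.random_slope_col
    slopes = fit.beta[term] + fit.blups["b1"]
    slopes.name = "treatment_slope"
    return slopes


def fit_group_model(
    records: pd.DataFrame,
    subjects: pd.DataFrame,
    cutoff: float = 24.0,
    covariate_cols: Sequence[str] = ("days_in_treatment", "hours_per_week", "msel_elc"),
    age_center: float = 24.0,
    subject_col: str = "subject_id",
    outcome_col: str = "outcome",
    age_col: str = "age",
    start_col: str = "age_start",
) -> LMMFit:
    """Start-group model: group + age + age x group + treatment covariates as
    fixed effects, random intercepts/slopes per subject.

    ``group_early`` is 1 for subjects starting before ``cutoff`` months.  Age
    is centered at ``age_center`` for conditioning (tests are unaffected).
    """
    merged = records.merge(
        subjects[[start_col, *covariate_cols]], left_on=subject_col,
        right_index=True, how="left",
    )
    if merged[start_col].isna().any():
        raise ValueError("records contain subjects missing from the covariate table")
    early = (merged[start_col] < cutoff).astype(float)
    if early.nunique() < 2:
        raise ValueError("both start groups must be non-empty")
    age_c = merged[age_col].to_numpy(dtype=float) - age_center
    design = pd.DataFrame(
        {
            "intercept": np.ones(len(merged)),
            "group_early": early.to_numpy(),
            "age": age_c,
            "age:group_early": age_c * early.to_numpy(),
        }
    )
    for col in covariate_cols:
        design[col] = merged[col].to_numpy(dtype=float)
    merged = merged.reset_index(drop=True).assign(age=age_c)
    return fit_lmm(
        merged, design, subject_col=subject_col, outcome_col=outcome_col,
        random_slope_col="age",
    )


def sd_difference_test(
    slopes: pd.Series,
    early: pd.Series,
    B: int = 10000,
    seed: int | None = None,
) -> VarianceDiffResult:
    """Permutation test of SD(late) - SD(early) treatment slopes.

    The null permutes start-group labels holding group sizes fixed;
    p = (1 + #{null_diff >= observed_diff}) / (B + 1) (add-one convention).
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    early = early.loc[slopes.index].astype(bool)
    s = slopes.to_numpy(dtype=float)
    e = early.to_numpy()
    if e.sum() < 2 or (~e).sum() < 2:
        raise ValueError("both groups need at least 2 members")
    sd_early = float(np.std(s[e], ddof=1))
    sd_late = float(np.std(s[~e], ddof=1))
    observed = sd_late - sd_early
    rng = np.random.default_rng(seed)
    null = np.empty(B)
    for b in range(B):
        pe = rng.permutation(e)
        null[b] = np.std(s[~pe], ddof=1) - np.std(s[pe], ddof=1)
    p = (1.0 + np.count_nonzero(null >= observed)) / (B + 1.0)
    return VarianceDiffResult(
        sd_early=sd_early,
        sd_late=sd_late,
        observed_diff=float(observed),
        null_diffs=null,
        p=float(p),
        B=B,
        seed=seed,
    )
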