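import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import linalg

from slopekit import synthetic, trajectory
from slopekit.trajectory import (
    LMMFit,
    extract_treatment_slopes,
    fit_group_model,
    fit_lmm,
    fit_trajectory_model,
    sd_difference_test,
)


def make_records(rng, n_subjects=40, n_visits=5, sd_b0=5.0, sd_b1=2.0, sd_e=1.0,
                 beta0=2.0, beta1=3.0):
    rows = []
    b0 = rng.normal(0, sd_b0, n_subjects)
    b1 = rng.normal(0, sd_b1, n_subjects)
    for i in range(n_subjects):
        ages = np.arange(n_visits, dtype=float) * 3 + rng.uniform(18, 26)
        y = beta0 + b0[i] + (beta1 + b1[i]) * ages + rng.normal(0, sd_e, n_visits)
        for a, v in zip(ages, y):
            rows.append((f"S{i:03d}", a, v))
    return pd.DataFrame(rows, columns=["subject_id", "age", "outcome"])


class TestZeroNoiseIdentity:
    def test_exact_line_two_subjects(self):
        rows = []
        for sid, ages in (("a", [1.0, 2, 3]), ("b", [2.0, 4, 6])):
            for t in ages:
                rows.append((sid, t, 2 + 3 * t))
        records = pd.DataFrame(rows, columns=["subject_id", "age", "outcome"])
        fit = fit_lmm(records)
        assert fit.beta["age"] == pytest.approx(3.0, abs=1e-8)
        assert fit.beta["intercept"] == pytest.approx(2.0, abs=1e-8)
        assert fit.G[1, 1] <= 1e-6
        assert np.allclose(fit.blups["b1"], 0.0, atol=1e-8)

    def test_slopes_exactly_three(self):
        rows = [(s, t, 2 + 3 * t) for s in "abc" for t in (1.0, 2.0, 4.0)]
        records = pd.DataFrame(rows, columns=["subject_id", "age", "outcome"])
        slopes = extract_treatment_slopes(fit_lmm(records))
        assert np.allclose(slopes, 3.0, atol=1e-8)


class TestParameterRecovery:
    def test_variance_components_within_15pct(self, rng):
        records = make_records(rng, n_subjects=100, n_visits=5,
                               sd_b0=5.0, sd_b1=2.0, sd_e=1.0)
        fit = fit_lmm(records)
        sd_b0, sd_b1 = np.sqrt(np.diag(fit.G))
        assert sd_b0 == pytest.approx(5.0, rel=0.15)
        assert sd_b1 == pytest.approx(2.0, rel=0.15)
        se_slope = np.sqrt(fit.cov_beta[1, 1])
        assert abs(fit.beta["age"] - 3.0) <= 2 * se_slope

    def test_matches_statsmodels_mixedlm(self, rng):
        # independent dual-route check on a modest dataset
        import statsmodels.formula.api as smf

        records = make_records(rng, n_subjects=30, n_visits=4)
        fit = fit_lmm(records)
        sm_fit = smf.mixedlm(
            "outcome ~ age", records, groups=records["subject_id"],
            re_formula="~age",
        ).fit(reml=True)
        assert fit.beta["intercept"] == pytest.approx(sm_fit.params["Intercept"], rel=1e-3)
        assert fit.beta["age"] == pytest.approx(sm_fit.params["age"], rel=1e-3)
        # the REML surface is flat in G near the optimum (log-liks agree to
        # 1e-9) so variance components only match loosely
        G_sm = (sm_fit.cov_re * sm_fit.scale).to_numpy()
        assert np.allclose(fit.G, G_sm, rtol=0.05, atol=1e-2)
        assert fit.sigma2 == pytest.approx(sm_fit.scale, rel=0.02)
        assert fit.reml_loglik == pytest.approx(sm_fit.llf, abs=1e-4)

    def test_extracted_slopes_track_truth(self):
        cfg = synthetic.CohortConfig(
            n_subjects=100, n_probes=10, n_causal=0, target_r2=0.0,
            sd_residual=1.0, late_slope_sd_inflation=1.0, seed=31,
        )
        c = synthetic.simulate_cohort(cfg)
        slopes = extract_treatment_slopes(fit_trajectory_model(c.visits))
        r = np.corrcoef(slopes.loc[c.truth.true_slope.index], c.truth.true_slope)[0, 1]
        assert r > 0.9


def dense_gls_oracle(records, G, sigma2):
    """Brute-force dense-matrix GLS + Henderson BLUPs at fixed (G, sigma2)."""
    subjects = sorted(records["subject_id"].unique())
    X = np.column_stack([np.ones(len(records)), records["age"].to_numpy()])
    y = records["outcome"].to_numpy(dtype=float)
    V = np.zeros((len(records), len(records)))
    Zs = {}
    for sid in subjects:
        idx = np.flatnonzero((records["subject_id"] == sid).to_numpy())
        Z = np.column_stack([np.ones(len(idx)), records["age"].to_numpy()[idx]])
        Zs[sid] = (idx, Z)
        V[np.ix_(idx, idx)] = Z @ G @ Z.T + sigma2 * np.eye(len(idx))
    Vinv = linalg.inv(V)
    beta = linalg.solve(X.T @ Vinv @ X, X.T @ Vinv @ y)
    resid = y - X @ beta
    blups = {}
    for sid, (idx, Z) in Zs.items():
        Vi = Z @ G @ Z.T + sigma2 * np.eye(len(idx))
        blups[sid] = G @ Z.T @ linalg.solve(Vi, resid[idx])
    return beta, blups


class TestFixedVarianceOracles:
    def test_gls_closed_form(self, rng):
        records = make_records(rng, n_subjects=12, n_visits=4)
        G = np.array([[4.0, 0.5], [0.5, 1.0]])
        sigma2 = 2.0
        fit = fit_lmm(records, fix_G=G, fix_sigma2=sigma2)
        beta, blups = dense_gls_oracle(records, G, sigma2)
        assert np.allclose(fit.beta.to_numpy(), beta, rtol=1e-8)
        for sid in fit.blups.index:
            assert np.allclose(fit.blups.loc[sid].to_numpy(), blups[sid], rtol=1e-8, atol=1e-10)

    def test_single_visit_subject_shrinkage(self, rng):
        records = make_records(rng, n_subjects=8, n_visits=4)
        lone = pd.DataFrame([("lonely", 20.0, 70.0)], columns=records.columns)
        records = pd.concat([records, lone], ignore_index=True)
        G = np.array([[9.0, 0.0], [0.0, 4.0]])
        sigma2 = 1.5
        fit = fit_lmm(records, fix_G=G, fix_sigma2=sigma2)
        _, blups = dense_gls_oracle(records, G, sigma2)
        assert np.allclose(fit.blups.loc["lonely"].to_numpy(), blups["lonely"],
                           rtol=1e-8, atol=1e-10)

    def test_reml_optimum_not_beaten_by_perturbations(self, rng):
        records = make_records(rng, n_subjects=25, n_visits=4)
        fit = fit_lmm(records)
        base = fit_lmm(records, fix_G=fit.G, fix_sigma2=fit.sigma2).reml_loglik
        assert base == pytest.approx(fit.reml_loglik, abs=1e-5)
        for scale in (0.8, 1.25):
            alt = fit_lmm(records, fix_G=fit.G * scale, fix_sigma2=fit.sigma2).reml_loglik
            assert alt <= base + 1e-6


class TestGroupModel:
    def test_degenerate_random_effects_reduce_to_ols(self, rng):
        records = make_records(rng, n_subjects=10, n_visits=4)
        design = pd.DataFrame(
            {"intercept": np.ones(len(records)), "age": records["age"].to_numpy()}
        )
        # with G=0, beta must equal plain OLS regardless of sigma2
        fit = fit_lmm(records, design, fix_G=np.zeros((2, 2)),
                      fix_sigma2=float(np.var(records["outcome"])))
        X = design.to_numpy()
        y = records["outcome"].to_numpy()
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        assert np.allclose(fit.beta.to_numpy(), ols, rtol=1e-6)

    def test_group_terms_present_and_errors(self, small_cohort):
        fit = fit_group_model(small_cohort.visits, small_cohort.subjects)
        for term in ("group_early", "age", "age:group_early"):
            assert term in fit.fixed_tests.index
            assert 0 <= fit.fixed_tests.loc[term, "p"] <= 1
        single = small_cohort.subjects.copy()
        single["age_start"] = 30.0
        with pytest.raises(ValueError):
            fit_group_model(small_cohort.visits, single)

    def test_strong_group_effect_detected(self):
        # gain large relative to all between-subject variance sources
        hits = 0
        n_rep = 40
        for seed in range(n_rep):
            cfg = synthetic.CohortConfig(
                n_subjects=40, n_probes=5, n_causal=0, target_r2=0.0,
                group_gain_effect=50.0, sd_rand_intercept=3.0, sd_rand_slope=1.0,
                sd_residual=1.0, late_slope_sd_inflation=1.0, seed=400 + seed,
            )
            c = synthetic.simulate_cohort(cfg)
            fit = fit_group_model(c.visits, c.subjects)
            if fit.fixed_tests.loc["group_early", "p"] < 0.001:
                hits += 1
        assert hits >= int(0.95 * n_rep)


class TestInvariances:
    def test_slopes_invariant_to_outcome_shift(self, rng):
        records = make_records(rng, n_subjects=20, n_visits=4)
        s1 = extract_treatment_slopes(fit_lmm(records))
        shifted = records.assign(outcome=records["outcome"] + 100.0)
        s2 = extract_treatment_slopes(fit_lmm(shifted))
        # structural invariance, up to optimizer termination noise
        assert np.allclose(s1, s2, atol=1e-2)

    def test_rank_deficient_design_rejected(self, rng):
        records = make_records(rng, n_subjects=5, n_visits=3)
        design = pd.DataFrame(
            {
                "intercept": np.ones(len(records)),
                "age": records["age"].to_numpy(),
                "age_copy": records["age"].to_numpy(),
            }
        )
        with pytest.raises(ValueError, match="rank deficient"):
            fit_lmm(records, design)


class TestSdDifferenceTest:
    def test_all_ties(self):
        slopes = pd.Series([2.0] * 10, index=[f"s{i}" for i in range(10)])
        early = pd.Series([True] * 5 + [False] * 5, index=slopes.index)
        res = sd_difference_test(slopes, early, B=200, seed=1)
        assert res.observed_diff == 0.0
        assert res.p == 1.0

    def test_exhaustive_enumeration_oracle(self):
        slopes = pd.Series([1.0, 2.0, 0.0, 10.0], index=list("abcd"))
        early = pd.Series([True, True, False, False], index=slopes.index)
        vals = slopes.to_numpy()
        observed = np.std(vals[2:], ddof=1) - np.std(vals[:2], ddof=1)
        diffs = []
        for combo in itertools.combinations(range(4), 2):
            e = np.zeros(4, bool)
            e[list(combo)] = True
            diffs.append(np.std(vals[~e], ddof=1) - np.std(vals[e], ddof=1))
        # classic permutation p over the 6 equally likely labelings
        exact_p = sum(d >= observed for d in diffs) / len(diffs)
        B = 4000
        res = sd_difference_test(slopes, early, B=B, seed=2)
        mc_se = np.sqrt(exact_p * (1 - exact_p) / B)
        assert res.observed_diff == pytest.approx(observed)
        assert abs(res.p - exact_p) <= 3 * mc_se + 2 / B

    def test_seed_reproducible_and_p_in_range(self, rng):
        slopes = pd.Series(rng.normal(size=20), index=[f"s{i}" for i in range(20)])
        early = pd.Series([True] * 10 + [False] * 10, index=slopes.index)
        r1 = sd_difference_test(slopes, early, B=500, seed=9)
        r2 = sd_difference_test(slopes, early, B=500, seed=9)
        assert np.array_equal(r1.null_diffs, r2.null_diffs)
        assert 0 < r1.p <= 1

    def test_one_sided_complement(self, rng):
        slopes = pd.Series(rng.normal(size=16), index=[f"s{i}" for i in range(16)])
        early = pd.Series([True] * 8 + [False] * 8, index=slopes.index)
        res_fwd = sd_difference_test(slopes, early, B=2000, seed=4)
        res_rev = sd_difference_test(slopes, ~early, B=2000, seed=4)
        assert res_fwd.observed_diff == pytest.approx(-res_rev.observed_diff)

    def test_degenerate_groups_rejected(self):
        slopes = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        early = pd.Series([True, False, False], index=slopes.index)
        with pytest.raises(ValueError):
            sd_difference_test(slopes, early, B=10, seed=0)
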