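"""Synthetic longitudinal treatment cohorts with the statistical structure
every downstream stage assumes: subject-specific random intercepts/slopes,
an early/late start-group structure with optional late-group slope-SD
inflation, a clinical table correlated with the true slopes, an expression
matrix carrying batch/sex/RIN nuisance structure plus a sparse causal gene
signal calibrated to a target predictive R^2, gene sets, and an interaction
network enriched among the causal probes.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
from typing import Dict, List, Tuple

import networkx as nx
import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import io as skio

__all__ = ["CohortConfig", "TruthRecord", "CohortData", "simulate_cohort", "write_cohort"]


@dataclass(frozen=True)
class CohortConfig:
    """Generator knobs.  Ages are in months, expression on the log2 scale.

    ``target_r2`` is the population fraction of random-slope variance carried
    by the causal-probe linear predictor (at unit slope-SD inflation).
    ``late_slope_sd_inflation`` multiplies the random-slope SD for subjects
    starting at or after ``early_cutoff``.
    """

    n_subjects: int = 41
    male_fraction: float = 33 / 41
    age_start_mean: float = 22.77
    age_start_sd: float = 4.08
    age_start_range: Tuple[float, float] = (13.0, 27.0)
    early_cutoff: float = 24.0
    visit_interval: float = 3.0
    final_age: float = 36.0
    fixed_intercept: float = 20.0
    fixed_slope: float = 4.0
    sd_rand_intercept: float = 5.0
    sd_rand_slope: float = 2.0
    sd_residual: float = 2.0
    group_gain_effect: float = 8.0
    late_slope_sd_inflation: float = 1.5
    n_probes: int = 200
    n_causal: int = 20
    causal_cor: float = 0.6
    target_r2: float = 0.13
    n_batches: int = 3
    batch_probs: Tuple[float, ...] | None = None
    batch_effect_sd: float = 0.5
    sex_effect_sd: float = 0.2
    rin_effect_sd: float = 0.3
    clinical_loading: Tuple[float, ...] = (0.45, -0.35, 0.4, 0.35, 0.3, 0.25, -0.2)
    seed: int = 0

    def validate(self) -> None:
        numeric = {
            f.name: getattr(self, f.name)
            for f in dataclasses.fields(self)
            if isinstance(getattr(self, f.name), (int, float))
        }
        for name, value in numeric.items():
            if not np.isfinite(value):
                raise ValueError(f"{name} must be finite, got {value!r}")
        for name in (
            "age_start_sd", "sd_rand_intercept", "sd_rand_slope", "sd_residual",
            "batch_effect_sd", "sex_effect_sd", "rin_effect_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.target_r2 < 1:
            raise ValueError("target_r2 must lie in [0, 1)")
        if not 0 <= self.causal_cor < 1:
            raise ValueError("causal_cor must lie in [0, 1)")
        if not 0 <= self.male_fraction <= 1:
            raise ValueError("male_fraction must lie in [0, 1]")
        if self.n_causal > self.n_probes:
            raise ValueError("n_causal cannot exceed n_probes")
        if self.n_subjects < 1 or self.n_probes < 1 or self.n_batches < 1:
            raise ValueError("counts must be positive")
        if self.visit_interval <= 0:
            raise ValueError("visit_interval must be positive")
        if self.late_slope_sd_inflation < 1:
            raise ValueError("late_slope_sd_inflation must be >= 1")
        lo, hi = self.age_start_range
        if not lo < hi <= self.final_age:
            raise ValueError("age_start_range must be increasing and end by final_age")
        if self.batch_probs is not None:
            if len(self.batch_probs) != self.n_batches:
                raise ValueError("batch_probs length must equal n_batches")
            if not np.isclose(sum(self.batch_probs), 1.0):
                raise ValueError("batch_probs must sum to 1")
        if self.late_slope_sd_inflation ** 2 < self.target_r2:
            raise ValueError("late_slope_sd_inflation^2 must be >= target_r2")


@dataclass
class TruthRecord:
    true_slope: pd.Series
    causal_probe_ids: List[str]
    config: CohortConfig
    causal_predictor: pd.Series | None = None  # the embedded expression signal
    intercept_dev: pd.Series | None = None  # per-subject random intercepts


@dataclass
class CohortData:
    visits: pd.DataFrame  # subject_id, age, outcome
    subjects: pd.DataFrame  # indexed by subject_id
    clinical: pd.DataFrame
    expression: pd.DataFrame  # probes x subjects
    gene_sets: Dict[str, List[str]]
    network: nx.Graph
    truth: TruthRecord

    def validate(self) -> None:
        sids = set(self.subjects.index)
        if not set(self.visits["subject_id"]) <= sids:
            raise ValueError("visit subject ids missing from the subject table")
        if list(self.expression.columns) != list(self.subjects.index):
            raise ValueError("expression column order must match subject order")
        for df in (self.visits, self.clinical, self.expression):
            if not np.isfinite(df.select_dtypes("number").to_numpy()).all():
                raise ValueError("missing or non-finite cells")
        if not set(self.truth.causal_probe_ids) <= set(self.expression.index):
            raise ValueError("causal probe ids not in the expression matrix")


@lru_cache(maxsize=64)
def _truncnorm_params(mean: float, sd: float, lo: float, hi: float):
    """Parent (loc, scale) whose truncation to [lo, hi] best matches the
    requested moments (exactly, when attainable).

    Some requests are infeasible - e.g. SD 4.08 with mean 22.77 on [13, 27]
    caps near 3.45 because a truncated normal cannot beat the near-uniform
    limit - in which case the least-squares optimum is used.
    """
    if lo <= mean - 8 * sd and hi >= mean + 8 * sd:
        return mean, sd
    if not lo < mean < hi:
        raise ValueError("age_start_mean must lie inside age_start_range")

    def moments(loc, scale):
        a, b = (lo - loc) / scale, (hi - loc) / scale
        m, v = stats.truncnorm.stats(a, b, loc=loc, scale=scale, moments="mv")
        return float(m), float(np.sqrt(v))

    def loc_for_mean(scale):
        # truncated mean is increasing in loc and spans (lo, hi)
        span = 50 * (scale + sd)
        return optimize.brentq(
            lambda loc: moments(loc, scale)[0] - mean, lo - span, hi + span, xtol=1e-12
        )

    def sd_gap(log_scale):
        scale = float(np.exp(log_scale))
        return (moments(loc_for_mean(scale), scale)[1] - sd) ** 2

    res = optimize.minimize_scalar(
        sd_gap, bounds=(np.log(sd / 20), np.log(sd * 50)), method="bounded",
        options={"xatol": 1e-10},
    )
    scale = float(np.exp(res.x))
    return float(loc_for_mean(scale)), scale


def simulate_cohort(config: CohortConfig) -> CohortData:
    """Draw one cohort; identical config (including seed) is byte-identical."""
    config.validate()
    # one named child stream per component: changing how one component draws
    # can never shift another component's values
    ss = np.random.SeedSequence(config.seed)
    streams = {
        name: np.random.default_rng(child)
        for name, child in zip(
            ("ages", "demo", "treat", "traj", "causal", "visits", "clinical",
             "expr", "sets", "net"),
            ss.spawn(10),
        )
    }
    n = config.n_subjects
    subject_ids = [f"S{i + 1:04d}" for i in range(n)]

    # --- subject covariates -------------------------------------------------
    lo, hi = config.age_start_range
    loc, scale = _truncnorm_params(config.age_start_mean, config.age_start_sd, lo, hi)
    a, b = (lo - loc) / scale, (hi - loc) / scale
    age_start = stats.truncnorm.rvs(a, b, loc=loc, scale=scale, size=n, random_state=streams["ages"])
    male = streams["demo"].random(n) < config.male_fraction
    probs = config.batch_probs or tuple(1 / config.n_batches for _ in range(config.n_batches))
    batch = streams["demo"].choice(config.n_batches, size=n, p=probs)
    rin = streams["demo"].uniform(7.0, 10.0, size=n)
    hours = np.clip(streams["treat"].normal(9.0, 1.5, size=n), 1.0, None)
    # enrollment duration varies independently of start age, else the group
    # indicator becomes collinear with it and its fixed-effect SE explodes
    days = np.clip(streams["treat"].normal(365.0, 60.0, size=n), 90.0, None)
    early = age_start < config.early_cutoff

    # --- true trajectories --------------------------------------------------
    b0 = streams["traj"].normal(0.0, config.sd_rand_intercept, size=n)
    probe_ids = [f"P{i + 1:05d}" for i in range(config.n_probes)]
    causal_idx = np.sort(streams["causal"].choice(config.n_probes, size=config.n_causal, replace=False))
    causal_ids = [probe_ids[i] for i in causal_idx]
    # causal-module scores: marginally standard normal, pairwise correlation
    # causal_cor through a shared factor (a co-regulated module), so the
    # module's signal is redundantly visible in every causal probe
    cc = config.causal_cor
    factor = streams["causal"].standard_normal(n)
    idio = streams["causal"].standard_normal((config.n_causal, n))
    causal_scores = np.sqrt(cc) * factor + np.sqrt(1.0 - cc) * idio
    # positive magnitudes bounded away from 0: consistent-direction module
    weights = streams["causal"].uniform(0.5, 1.5, size=config.n_causal)
    if config.n_causal > 0 and config.target_r2 > 0 and config.sd_rand_slope > 0:
        raw = weights @ causal_scores
        # analytic population SD: Var = (1-cc)*sum(w^2) + cc*(sum w)^2
        raw_sd = float(
            np.sqrt((1 - cc) * np.sum(weights**2) + cc * np.sum(weights) ** 2)
        )
        causal_term = raw * (config.sd_rand_slope * np.sqrt(config.target_r2) / raw_sd)
        causal_part_var = config.target_r2
    else:
        causal_term = np.zeros(n)
        causal_part_var = 0.0
    infl = np.where(early, 1.0, config.late_slope_sd_inflation)
    noise_sd = config.sd_rand_slope * np.sqrt(infl**2 - causal_part_var)
    b1 = causal_term + streams["traj"].standard_normal(n) * noise_sd
    true_slope = config.fixed_slope + b1

    # --- visits -------------------------------------------------------------
    rows = []
    for i, sid in enumerate(subject_ids):
        n_visits = int(np.floor((config.final_age - age_start[i]) / config.visit_interval)) + 1
        ages = age_start[i] + config.visit_interval * np.arange(n_visits)
        eps = streams["visits"].normal(0.0, config.sd_residual, size=n_visits)
        outcome = (
            config.fixed_intercept
            + b0[i]
            + config.group_gain_effect * float(early[i])
            + true_slope[i] * ages
            + eps
        )
        for age, y in zip(ages, outcome):
            rows.append((sid, float(age), float(y)))
    visits = pd.DataFrame(rows, columns=["subject_id", "age", "outcome"])

    # --- clinical table correlated with the true slopes ---------------------
    z_slope = (true_slope - true_slope.mean()) / max(true_slope.std(), 1e-12)
    clinical_cols = {}
    for k, rho in enumerate(config.clinical_loading):
        noise = streams["clinical"].standard_normal(n)
        z = rho * z_slope + np.sqrt(max(1 - rho**2, 0.0)) * noise
        clinical_cols[f"clin_{k + 1:02d}"] = 50.0 + 10.0 * (k + 1) / 10.0 + 10.0 * z
    clinical = pd.DataFrame(clinical_cols, index=pd.Index(subject_ids, name="subject_id"))
    msel = 74.0 + 15.0 * (0.3 * z_slope + np.sqrt(1 - 0.3**2) * streams["clinical"].standard_normal(n))

    subjects = pd.DataFrame(
        {
            "sex": np.where(male, "M", "F"),
            "batch": [f"batch{b + 1}" for b in batch],
            "rin": rin,
            "age_start": age_start,
            "days_in_treatment": days,
            "hours_per_week": hours,
            "msel_elc": msel,
        },
        index=pd.Index(subject_ids, name="subject_id"),
    )

    # --- expression with nuisance structure ---------------------------------
    baseline = streams["expr"].normal(8.0, 1.0, size=config.n_probes)
    expr = baseline[:, None] + streams["expr"].standard_normal((config.n_probes, n))
    expr[causal_idx] = baseline[causal_idx, None] + causal_scores
    batch_shift = streams["expr"].normal(0.0, config.batch_effect_sd, size=(config.n_probes, config.n_batches))
    expr += batch_shift[:, batch]
    sex_coef = streams["expr"].normal(0.0, config.sex_effect_sd, size=config.n_probes)
    expr += np.outer(sex_coef, male.astype(float))
    rin_coef = streams["expr"].normal(0.0, config.rin_effect_sd, size=config.n_probes)
    expr += np.outer(rin_coef, rin - 8.5)
    expression = pd.DataFrame(
        expr, index=pd.Index(probe_ids, name="probe_id"), columns=subject_ids
    )

    # --- gene sets and network ----------------------------------------------
    n_extra = max(5, config.n_causal // 2)
    others = [p for p in probe_ids if p not in set(causal_ids)]
    gene_sets: Dict[str, List[str]] = {
        "causal_set": sorted(
            set(causal_ids)
            | set(streams["sets"].choice(others, size=min(n_extra, len(others)), replace=False))
        ),
        "random_set_1": sorted(
            streams["sets"].choice(probe_ids, size=min(25, config.n_probes), replace=False)
        ),
        "random_set_2": sorted(
            streams["sets"].choice(probe_ids, size=min(40, config.n_probes), replace=False)
        ),
    }
    network = nx.Graph()
    network.add_nodes_from(probe_ids)
    m_background = 3 * config.n_probes
    u = streams["net"].integers(0, config.n_probes, size=2 * m_background)
    v = streams["net"].integers(0, config.n_probes, size=2 * m_background)
    for a_, b_ in zip(u, v):
        if a_ != b_:
            network.add_edge(probe_ids[a_], probe_ids[b_])
    for i in range(config.n_causal):  # denser wiring among causal probes
        for j in range(i + 1, config.n_causal):
            if streams["net"].random() < 0.3:
                network.add_edge(causal_ids[i], causal_ids[j])

    cohort = CohortData(
        visits=visits,
        subjects=subjects,
        clinical=clinical,
        expression=expression,
        gene_sets=gene_sets,
        network=network,
        truth=TruthRecord(
            true_slope=pd.Series(true_slope, index=subjects.index, name="true_slope"),
            causal_probe_ids=causal_ids,
            config=config,
            causal_predictor=pd.Series(
                causal_term, index=subjects.index, name="causal_predictor"
            ),
            intercept_dev=pd.Series(b0, index=subjects.index, name="intercept_dev"),
        ),
    )
    cohort.validate()
    return cohort


def write_cohort(cohort: CohortData, outdir: str | os.PathLike) -> None:
    """Write all cohort components as plain-text files under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort.visits.to_csv(outdir / "visits.tsv", sep="\t", index=False)
    skio.write_table(cohort.subjects, outdir / "subjects.tsv")
    skio.write_table(cohort.clinical, outdir / "clinical.tsv")
    skio.write_matrix(cohort.expression, outdir / "expression.tsv")
    skio.write_gmt(cohort.gene_sets, outdir / "gene_sets.gmt")
    skio.write_edge_list(cohort.network, outdir / "network.tsv")
    truth = {
        "true_slope": {k: float(v) for k, v in cohort.truth.true_slope.items()},
        "causal_probe_ids": list(cohort.truth.causal_probe_ids),
        "config": dataclasses.asdict(cohort.truth.config),
    }
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1)
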