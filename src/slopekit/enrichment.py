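"""Gene-set enrichment (2x2 odds ratio + hypergeometric tail + BH-FDR) and a
network edge-count permutation test."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EnrichmentResult",
    "EdgeEnrichmentResult",
    "enrichment_test",
    "enrich_many",
    "bh_fdr",
    "edge_enrichment_test",
]


@dataclass
class EnrichmentResult:
    """2x2 overlap of a query set against an annotation list within a universe.

    a = |query & list|, b = |query \\ list|, c = |list \\ query|, d = rest.
    """

    name: str
    a: int
    b: int
    c: int
    d: int
    odds_ratio: float
    p: float
    q: float | None = None

    @property
    def counts(self) -> tuple:
        return (self.a, self.b, self.c, self.d)


@dataclass
class EdgeEnrichmentResult:
    observed_edges: int
    expected_edges: float
    null_counts: np.ndarray
    p: float
    B: int
    seed: int | None
    n_mapped: int = 0

    def __repr__(self) -> str:  # keep the null vector out of reprs
        return (
            f"EdgeEnrichmentResult(observed={self.observed_edges}, "
            f"expected={self.expected_edges:.2f}, p={self.p:.4g}, B={self.B})"
        )


def enrichment_test(
    query: Iterable,
    annotation: Iterable,
    universe: Iterable,
    name: str = "",
    alternative: str = "greater",
) -> EnrichmentResult:
    """Hypergeometric over-representation test of ``query`` in ``annotation``.

    The annotation is intersected with the universe before counting; the query
    must be a subset of the universe.  The odds ratio is (a*d)/(b*c), with a
    Haldane-Anscombe 0.5 added to every cell only when some cell is zero.
    ``alternative='greater'`` gives the upper tail P(overlap >= a);
    ``'less'`` gives the depletion tail.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    query = set(query)
    if not query <= universe:
        raise ValueError("query must be a subset of the universe")
    annotation = set(annotation) & universe
    a = len(query & annotation)
    b = len(query - annotation)
    c = len(annotation - query)
    d = len(universe) - a - b - c
    if min(a, b, c, d) == 0:
        aa, bb, cc, dd = (x + 0.5 for x in (a, b, c, d))
    else:
        aa, bb, cc, dd = a, b, c, d
    odds_ratio = (aa * dd) / (bb * cc)
    hg = stats.hypergeom(len(universe), len(annotation), len(query))
    if alternative == "greater":
        p = float(hg.sf(a - 1))
    elif alternative == "less":
        p = float(hg.cdf(a))
    else:
        raise ValueError("alternative must be 'greater' or 'less'")
    return EnrichmentResult(name, a, b, c, d, odds_ratio, min(p, 1.0))


def enrich_many(
    query: Iterable,
    annotations: Dict[str, Iterable],
    universe: Iterable,
    alternative: str = "greater",
) -> pd.DataFrame:
    """Run :func:`enrichment_test` per annotation list and BH-adjust the p's."""
    universe = set(universe)
    results = [
        enrichment_test(query, members, universe, name=name, alternative=alternative)
        for name, members in annotations.items()
    ]
    qvals = bh_fdr(np.array([r.p for r in results])) if results else np.array([])
    for r, q in zip(results, qvals):
        r.q = float(q)
    return pd.DataFrame(
        {
            "name": [r.name for r in results],
            "a": [r.a for r in results],
            "b": [r.b for r in results],
            "c": [r.c for r in results],
            "d": [r.d for r in results],
            "odds_ratio": [r.odds_ratio for r in results],
            "p": [r.p for r in results],
            "q": [r.q for r in results],
        }
    ).set_index("name")


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values), clipped at 1.

    q_(i) = min_{j >= i} p_(j) * m / j over the sorted p's, returned in the
    original input order.  Output is never below the raw p and is invariant
    to input permutation.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m, dtype=float)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def _count_internal_edges(member: np.ndarray, e0: np.ndarray, e1: np.ndarray) -> int:
    return int(np.count_nonzero(member[e0] & member[e1]))


def edge_enrichment_test(
    gene_set: Iterable,
    network: nx.Graph,
    B: int = 1000,
    seed: int | None = None,
    null: str = "uniform",
    n_degree_bins: int = 10,
) -> EdgeEnrichmentResult:
    """Test whether a gene set carries more network edges than random sets.

    Observed statistic: number of edges with both endpoints in the (mapped)
    set.  The null redraws same-size node sets uniformly without replacement
    B times; ``expected`` is the null mean and p = (1 + #{null >= obs})/(B+1).
    ``null='degree'`` instead resamples within degree bins (quantile strata),
    matching the query's per-bin composition, to guard against hub bias.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    nodes = np.array(list(network.nodes()))
    index = {n: i for i, n in enumerate(nodes)}
    mapped = sorted({g for g in gene_set if g in index})
    if len(mapped) < 2:
        raise ValueError(
            f"gene set maps to {len(mapped)} network node(s); need at least 2"
        )
    e0 = np.array([index[u] for u, v in network.edges()], dtype=np.int64)
    e1 = np.array([index[v] for u, v in network.edges()], dtype=np.int64)
    member = np.zeros(len(nodes), dtype=bool)
    member[[index[g] for g in mapped]] = True
    observed = _count_internal_edges(member, e0, e1)

    rng = np.random.default_rng(seed)
    null_counts = np.empty(B, dtype=np.int64)
    if null == "uniform":
        for b in range(B):
            draw = rng.choice(len(nodes), size=len(mapped), replace=False)
            mb = np.zeros(len(nodes), dtype=bool)
            mb[draw] = True
            null_counts[b] = _count_internal_edges(mb, e0, e1)
    elif null == "degree":
        degrees = np.array([network.degree(n) for n in nodes], dtype=float)
        edges_of = np.quantile(degrees, np.linspace(0, 1, n_degree_bins + 1))
        bin_id = np.clip(np.searchsorted(edges_of, degrees, side="right") - 1, 0, n_degree_bins - 1)
        query_idx = np.flatnonzero(member)
        per_bin = np.bincount(bin_id[query_idx], minlength=n_degree_bins)
        pools = [np.flatnonzero(bin_id == k) for k in range(n_degree_bins)]
        for b in range(B):
            mb = np.zeros(len(nodes), dtype=bool)
            for k in range(n_degree_bins):
                if per_bin[k]:
                    mb[rng.choice(pools[k], size=per_bin[k], replace=False)] = True
            null_counts[b] = _count_internal_edges(mb, e0, e1)
    else:
        raise ValueError("null must be 'uniform' or 'degree'")

    p = (1.0 + np.count_nonzero(null_counts >= observed)) / (B + 1.0)
    return EdgeEnrichmentResult(
        observed_edges=observed,
        expected_edges=float(null_counts.mean()),
        null_counts=null_counts,
        p=float(p),
        B=B,
        seed=seed,
        n_mapped=len(mapped),
    )
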