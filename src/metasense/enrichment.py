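"""COG functional-category enrichment of antisense-enriched genes.

For each category, the number of antisense-enriched genes carrying it is
compared against the whole expressed-gene population with an exact
hypergeometric test. One-tailed over- and under-representation p-values are
BH-corrected across categories (separately per tail) to call a direction;
the two-sided p is the doubled smaller tail, capped at 1. Genes without a
COG letter form their own "unannotated" category, and a gene with several
letters contributes once to each.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .asrna_stats import bh_adjust

UNANNOTATED = "unannotated"


@dataclass(frozen=True)
class EnrichmentResult:
    category: str
    N: int  # population size
    K: int  # category size in population
    n: int  # subset size
    k: int  # category size in subset
    p_over: float
    p_under: float
    p_two: float
    p_two_adj: float
    direction: str  # enriched / reduced / none


def hypergeom_tails(N: int, K: int, n: int, k: int) -> tuple[float, float]:
    """Exact tails of Hypergeometric(N, K, n): (P(X >= k), P(X <= k))."""
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k <= min(K, n)):
        raise ValueError(f"inconsistent sizes N={N}, K={K}, n={n}, k={k}")
    p_over = float(stats.hypergeom.sf(k - 1, N, K, n))
    p_under = float(stats.hypergeom.cdf(k, N, K, n))
    return min(p_over, 1.0), min(p_under, 1.0)


def two_tailed(p_over: float, p_under: float) -> float:
    """Two-sided p as twice the smaller one-sided tail, capped at 1."""
    return min(1.0, 2.0 * min(p_over, p_under))


def _gene_categories(genes, cog_map: Mapping[str, str]) -> dict[str, set[str]]:
    out = {}
    for g in genes:
        letters = cog_map.get(g, "")
        out[g] = set(letters) if letters else {UNANNOTATED}
    return out


def cog_enrichment(
    calls: pd.DataFrame,
    cog_map: Mapping[str, str],
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Test every observed COG category (plus "unannotated") for enrichment
    or reduction among antisense-enriched genes.

    Population = all genes above the detection limit (present in ``calls``);
    subset = genes flagged antisense-enriched in at least one sample. The
    direction is set by one-tailed BH-adjusted p-values at ``alpha``.
    """
    population = sorted(calls["gene_id"].unique())
    subset = sorted(calls.loc[calls["antisense_enriched"], "gene_id"].unique())
    if not subset:
        warnings.warn("no antisense-enriched genes; all directions 'none'")
    cats_of = _gene_categories(population, cog_map)
    subset_set = set(subset)

    categories = sorted({c for cats in cats_of.values() for c in cats})
    N, n = len(population), len(subset)
    rows = []
    for cat in categories:
        K = sum(1 for g in population if cat in cats_of[g])
        k = sum(1 for g in subset if cat in cats_of[g])
        p_over, p_under = hypergeom_tails(N, K, n, k)
        rows.append((cat, K, k, p_over, p_under))

    p_over_adj = bh_adjust([r[3] for r in rows])
    p_under_adj = bh_adjust([r[4] for r in rows])
    p_two = [two_tailed(r[3], r[4]) for r in rows]
    p_two_adj = bh_adjust(p_two)

    results = []
    for i, (cat, K, k, p_over, p_under) in enumerate(rows):
        if n and p_over_adj[i] < alpha:
            direction = "enriched"
        elif n and p_under_adj[i] < alpha:
            direction = "reduced"
        else:
            direction = "none"
        results.append(
            EnrichmentResult(
                category=cat,
                N=N,
                K=K,
                n=n,
                k=k,
                p_over=p_over,
                p_under=p_under,
                p_two=p_two[i],
                p_two_adj=float(p_two_adj[i]),
                direction=direction,
            )
        )
    return results


def enrichment_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])
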