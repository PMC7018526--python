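"""Antisense RNA statistics.

The central test: for a gene with k antisense reads out of n total, is the
antisense fraction larger than the technical strand-flip error rate q?
p = P(X >= k), X ~ Binomial(n, q), one-tailed, Benjamini-Hochberg corrected
within each sample. A gene is *antisense-enriched* when its antisense
fraction is at least 95% regardless of the test.

Also here: the descriptive summaries — percent antisense per sample,
rank-abundance (cumulative-dominance) curves, per-genome fractions of
significant genes, and the binned antisense-fraction histogram used for the
DNA-contamination analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core_io import GeneRecord, validate_counts


@dataclass
class BinomialTestConfig:
    q: float = 0.01  # technical false-antisense rate (alternative: 0.05)
    alpha_adj: float = 0.05  # BH-adjusted significance cutoff (alternative: 0.01)
    enrichment_threshold: float = 0.95
    bh_family: str = "sample"  # or "global"

    def __post_init__(self) -> None:
        if not (0.0 < self.q < 1.0):
            raise ValueError("q must be in (0, 1)")
        if not (0.0 < self.alpha_adj < 1.0):
            raise ValueError("alpha_adj must be in (0, 1)")
        if self.bh_family not in ("sample", "global"):
            raise ValueError("bh_family must be 'sample' or 'global'")


def binom_upper_p(k, n, q: float):
    """Exact upper-tail P(X >= k) for X ~ Binomial(n, q).

    Accepts scalars or arrays; uses the survival function for numerical
    stability in the far tail.
    """
    if not (0.0 < q < 1.0):
        raise ValueError("q must be in (0, 1)")
    k = np.asarray(k)
    n = np.asarray(n)
    if np.any(k < 0) or np.any(k > n) or np.any(n < 1):
        raise ValueError("require 0 <= k <= n and n >= 1")
    p = stats.binom.sf(k - 1, n, q)
    return float(p) if p.ndim == 0 else p


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_asrna(table: pd.DataFrame, config: BinomialTestConfig | None = None) -> pd.DataFrame:
    """Per-observation antisense calls.

    Returns one row per (gene, sample): k (antisense), n (total), raw and
    BH-adjusted p, the significance flag (p_adj < alpha_adj) and the
    antisense-enrichment flag (k/n >= enrichment_threshold).
    """
    config = config or BinomialTestConfig()
    validate_counts(table)
    calls = table[["gene_id", "sample_id"]].copy()
    calls["k"] = table["antisense"].to_numpy()
    calls["n"] = (table["sense"] + table["antisense"]).to_numpy()
    if (calls["n"] == 0).any():
        raise ValueError("observations with zero total count must be filtered first")
    calls["p_raw"] = binom_upper_p(calls["k"].to_numpy(), calls["n"].to_numpy(), config.q)
    if config.bh_family == "sample":
        calls["p_adj"] = (
            calls.groupby("sample_id")["p_raw"].transform(lambda p: bh_adjust(p.to_numpy()))
        )
    else:
        calls["p_adj"] = bh_adjust(calls["p_raw"].to_numpy())
    calls["significant"] = calls["p_adj"] < config.alpha_adj
    calls["antisense_enriched"] = calls["k"] / calls["n"] >= config.enrichment_threshold
    return calls


def percent_asrna_per_sample(table: pd.DataFrame) -> pd.Series:
    """Percentage of reads that are antisense, per sample."""
    validate_counts(table)
    if len(table) == 0:
        raise ValueError("empty count table")
    g = table.groupby("sample_id")[["sense", "antisense"]].sum()
    return g["antisense"] / (g["sense"] + g["antisense"]) * 100


def rank_abundance(
    table: pd.DataFrame, strand: str = "antisense", top_n_removed: int = 0
) -> pd.DataFrame:
    """Per-sample cumulative-percentage rank-abundance curves.

    Genes are sorted per sample in descending order of the chosen strand's
    counts (gene_id breaks ties, stable); the curve is the cumulative percent
    of that strand's sample total, ending at 100. With ``top_n_removed`` the
    globally most antisense-expressing genes (summed over samples) are
    removed before ranking.
    """
    if strand not in ("sense", "antisense"):
        raise ValueError("strand must be 'sense' or 'antisense'")
    validate_counts(table)
    t = table
    if top_n_removed > 0:
        totals = t.groupby("gene_id")["antisense"].sum().sort_values(ascending=False)
        drop = set(totals.index[:top_n_removed])
        t = t[~t["gene_id"].isin(drop)]
    frames = []
    for sample_id, sub in t.groupby("sample_id"):
        sub = sub.sort_values([strand, "gene_id"], ascending=[False, True])
        total = sub[strand].sum()
        if total == 0:
            continue
        cum = sub[strand].cumsum() / total * 100
        frames.append(
            pd.DataFrame(
                {
                    "sample_id": sample_id,
                    "rank": np.arange(1, len(sub) + 1),
                    "gene_id": sub["gene_id"].to_numpy(),
                    "cumulative_pct": cum.to_numpy(),
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=["sample_id", "rank", "gene_id", "cumulative_pct"])
    return pd.concat(frames, ignore_index=True)


def genome_fraction_significant(
    calls: pd.DataFrame, records: Sequence[GeneRecord]
) -> pd.DataFrame:
    """Percentage of tested genes with significant antisense expression, per
    (genome, sample). Pairs with no tested genes emit no row."""
    genome_of = {r.gene_id: r.genome_id for r in records}
    c = calls.copy()
    c["genome_id"] = c["gene_id"].map(genome_of)
    g = c.groupby(["genome_id", "sample_id"]).agg(
        n_tested=("gene_id", "nunique"),
        n_significant=("significant", "sum"),
    )
    g["pct_significant"] = g["n_significant"] / g["n_tested"] * 100
    return g.reset_index()


def asrna_fraction_histogram(
    table: pd.DataFrame,
    bins: Sequence[float] = tuple(range(0, 101, 10)),
    coverage: pd.Series | None = None,
    coverage_facets: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Binned distribution of per-observation antisense percentages.

    Observations at exactly 0% and exactly 100% get dedicated end bins;
    interior bins are left-open/right-closed, e.g. 50% falls in (40, 50]
    with edges every 10. With ``coverage`` (per gene_id) and
    ``coverage_facets`` the table is faceted by DNA-coverage bins and
    fractions sum to 1 within each facet.
    """
    validate_counts(table)
    t = table.copy()
    total = t["sense"] + t["antisense"]
    if (total == 0).any():
        raise ValueError("observations with zero total count must be filtered first")
    pct = t["antisense"] / total * 100

    edges = list(bins)
    if edges[0] != 0 or edges[-1] != 100:
        raise ValueError("bins must span [0, 100]")
    labels = ["0"] + [f"({edges[i]:g},{edges[i+1]:g}]" for i in range(len(edges) - 1)] + ["100"]

    def bin_of(x: float) -> str:
        if x == 0:
            return "0"
        if x == 100:
            return "100"
        i = int(np.searchsorted(edges, x, side="left")) - 1
        return labels[i + 1]

    t["bin"] = [bin_of(x) for x in pct]

    if coverage is not None and coverage_facets is not None:
        cov = t["gene_id"].map(coverage)
        if cov.isna().any():
            raise ValueError("DNA coverage missing for some genes")
        facet_idx = np.clip(
            np.searchsorted(coverage_facets, cov, side="right") - 1,
            0,
            len(coverage_facets) - 2,
        )
        t["facet"] = [
            f"[{coverage_facets[i]:g},{coverage_facets[i+1]:g})" for i in facet_idx
        ]
    else:
        t["facet"] = "all"

    counts = t.groupby(["facet", "bin"]).size().rename("count").reset_index()
    counts["fraction"] = counts["count"] / counts.groupby("facet")["count"].transform("sum")
    counts["bin"] = pd.Categorical(counts["bin"], categories=labels, ordered=True)
    return counts.sort_values(["facet", "bin"]).reset_index(drop=True)
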