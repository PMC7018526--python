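"""Filtering cascade and TPM normalization.

Two data sets are built from the raw stranded counts: the *sample-wide* set
(read-depth, protein-coding, prevalence and per-observation depth filters)
and the *genome-wide* set (additionally gated on assembly quality and on a
minimum number of detected genes per genome per sample).

Inequalities are applied exactly as stated by the thresholds: samples are
kept when total reads exceed ``min_sample_reads``; genes are dropped when
zero in strictly more than ``max_zero_sample_frac`` of retained samples;
observations are dropped below ``min_obs_total`` reads; genomes are kept at
completeness >= ``min_completeness`` and contamination strictly below
``max_contamination``; per sample, genomes need at least
``min_genes_detected`` genes above the detection limit.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core_io import GeneRecord, GenomeMeta, records_frame, validate_counts

logger = logging.getLogger(__name__)


@dataclass
class FilterConfig:
    min_sample_reads: int = 1_000_000
    max_zero_sample_frac: float = 0.75
    min_obs_total: int = 10
    min_completeness: float = 50.0
    max_contamination: float = 10.0
    min_genes_detected: int = 50

    def __post_init__(self) -> None:
        if not (0.0 <= self.max_zero_sample_frac <= 1.0):
            raise ValueError("max_zero_sample_frac must be in [0, 1]")
        for name in (
            "min_sample_reads",
            "min_obs_total",
            "min_completeness",
            "max_contamination",
            "min_genes_detected",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def filter_sample_wide(
    table: pd.DataFrame,
    records: Sequence[GeneRecord],
    config: FilterConfig | None = None,
    report: list | None = None,
) -> pd.DataFrame:
    """Build the sample-wide data set. Filters, in order:

    1. drop samples whose total (sense+antisense) reads are <= min_sample_reads;
    2. keep protein-coding (CDS) genes only;
    3. drop genes with zero total counts in strictly more than
       max_zero_sample_frac of the retained samples (missing rows count as
       zeros);
    4. drop individual observations with sense+antisense < min_obs_total.
    """
    config = config or FilterConfig()
    validate_counts(table)
    t = table.copy()
    t["total"] = t["sense"] + t["antisense"]

    sample_totals = t.groupby("sample_id")["total"].sum()
    keep_samples = sample_totals.index[sample_totals > config.min_sample_reads]
    n0 = len(t)
    t = t[t["sample_id"].isin(keep_samples)]
    if report is not None:
        report.append({"rule": "min_sample_reads", "dropped": n0 - len(t)})

    coding = {r.gene_id for r in records if r.feature_type == "CDS"}
    n0 = len(t)
    t = t[t["gene_id"].isin(coding)]
    if report is not None:
        report.append({"rule": "protein_coding_only", "dropped": n0 - len(t)})

    n_samples = len(keep_samples)
    if n_samples:
        nonzero = t[t["total"] > 0].groupby("gene_id")["sample_id"].nunique()
        nonzero = nonzero.reindex(t["gene_id"].unique(), fill_value=0)
        zero_frac = 1.0 - nonzero / n_samples
        keep_genes = zero_frac.index[zero_frac <= config.max_zero_sample_frac]
        n0 = len(t)
        t = t[t["gene_id"].isin(keep_genes)]
        if report is not None:
            report.append({"rule": "max_zero_sample_frac", "dropped": n0 - len(t)})

    n0 = len(t)
    t = t[t["total"] >= config.min_obs_total]
    if report is not None:
        report.append({"rule": "min_obs_total", "dropped": n0 - len(t)})

    if len(t) == 0:
        warnings.warn("sample-wide filtering removed every observation")
    return t.drop(columns="total").reset_index(drop=True)


def filter_genome_wide(
    table: pd.DataFrame,
    records: Sequence[GeneRecord],
    meta: Sequence[GenomeMeta],
    config: FilterConfig | None = None,
    report: list | None = None,
) -> pd.DataFrame:
    """Build the genome-wide data set from a sample-wide-filtered table.

    Genomes failing medium-quality MAG criteria (completeness >= 50%,
    contamination < 10%) are removed globally; then, per sample, genomes
    with fewer than min_genes_detected genes above the detection limit
    (total >= min_obs_total) are removed for that sample only.
    """
    config = config or FilterConfig()
    validate_counts(table)
    genome_of = {r.gene_id: r.genome_id for r in records}
    meta_by_id = {m.genome_id: m for m in meta}

    t = table.copy()
    t["genome_id"] = t["gene_id"].map(genome_of)
    unknown = set(t["genome_id"].dropna().unique()) - set(meta_by_id)
    if unknown:
        raise ValueError(f"genome(s) in table absent from metadata: {sorted(unknown)}")

    good = {
        g
        for g, m in meta_by_id.items()
        if m.completeness_pct >= config.min_completeness
        and m.contamination_pct < config.max_contamination
    }
    n0 = len(t)
    t = t[t["genome_id"].isin(good)]
    if report is not None:
        report.append({"rule": "mag_quality", "dropped": n0 - len(t)})

    detected = t[(t["sense"] + t["antisense"]) >= config.min_obs_total]
    genes_per = detected.groupby(["genome_id", "sample_id"])["gene_id"].nunique()
    keep_pairs = set(genes_per.index[genes_per >= config.min_genes_detected])
    n0 = len(t)
    mask = [
        (gid, sid) in keep_pairs
        for gid, sid in zip(t["genome_id"], t["sample_id"])
    ]
    t = t[np.array(mask, dtype=bool)] if len(t) else t
    if report is not None:
        report.append({"rule": "min_genes_detected", "dropped": n0 - len(t)})

    if len(t) == 0:
        warnings.warn("genome-wide filtering removed every observation")
    return t.drop(columns="genome_id").reset_index(drop=True)


def tpm(
    table: pd.DataFrame,
    records: Sequence[GeneRecord],
    mode: str = "combined",
) -> pd.DataFrame:
    """Transcripts per million for each (gene, strand, sample) feature.

    rate = count / gene length; TPM = rate / sum(rates) x 1e6. In
    ``combined`` mode the normalizing sum runs over both strand features of
    all genes in the sample (sense and antisense of one gene are two
    comparable features); ``per_strand`` normalizes each strand separately.
    """
    if mode not in ("combined", "per_strand"):
        raise ValueError(f"unknown TPM mode {mode!r}")
    validate_counts(table)
    lengths = records_frame(list(records)).set_index("gene_id")["length_bp"]
    long = table.melt(
        id_vars=["gene_id", "sample_id"],
        value_vars=["sense", "antisense"],
        var_name="strand",
        value_name="count",
    )
    long["rate"] = long["count"] / long["gene_id"].map(lengths)
    if long["rate"].isna().any():
        missing = long.loc[long["rate"].isna(), "gene_id"].unique()
        raise ValueError(f"gene length unavailable for: {sorted(missing)[:5]}")
    group_cols = ["sample_id"] if mode == "combined" else ["sample_id", "strand"]
    denom = long.groupby(group_cols)["rate"].transform("sum")
    zero = denom == 0
    if zero.any():
        warnings.warn("zero total rate in at least one sample; TPM set to 0 there")
    with np.errstate(invalid="ignore", divide="ignore"):
        long["tpm"] = np.where(zero, 0.0, long["rate"] / denom * 1e6)
    return long[["gene_id", "sample_id", "strand", "tpm"]]
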