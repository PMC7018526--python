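"""Sequence-derived genome covariates.

AT content, Pribnow (-10 promoter hexamer, TATAAT) motif density on both
strands, and per-megabase sense/antisense expression — the covariates used
to ask what drives genome-wide antisense levels. AT-rich genomes carry more
spurious Pribnow boxes by simple combinatorics, which is the mechanistic
hypothesis these features probe.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import GeneRecord, GenomeMeta, records_frame

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def at_content(sequences: Sequence[str] | str) -> float:
    """(A+T) / (A+C+G+T) over the concatenated sequences; ambiguous bases are
    excluded from both numerator and denominator."""
    if isinstance(sequences, str):
        sequences = [sequences]
    at = acgt = 0
    for seq in sequences:
        s = seq.upper()
        a, c, g, t = s.count("A"), s.count("C"), s.count("G"), s.count("T")
        at += a + t
        acgt += a + c + g + t
    if acgt == 0:
        raise ValueError("no unambiguous bases in sequence")
    return at / acgt


def _count_matches(seq: str, motif: str, max_mismatch: int) -> int:
    """Overlapping occurrences of motif in seq with <= max_mismatch mismatches."""
    L, m = len(seq), len(motif)
    if L < m:
        return 0
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    pat = np.frombuffer(motif.upper().encode(), dtype=np.uint8)
    n_win = L - m + 1
    mism = np.zeros(n_win, dtype=np.int32)
    for j in range(m):
        mism += arr[j : j + n_win] != pat[j]
    return int((mism <= max_mismatch).sum())


def pribnow_count(
    sequences: Sequence[str] | str | Mapping[str, str],
    motif: str = "TATAAT",
    max_mismatch: int = 0,
) -> tuple[int, float]:
    """Count motif occurrences on both strands and their per-Mbp density.

    Overlapping matches count; the reverse strand is scanned by searching the
    motif's reverse complement on the forward sequence. For a palindromic
    motif both strand hits are still counted separately.
    """
    if set(motif.upper()) - set("ACGT"):
        raise ValueError("motif must be over {A, C, G, T}")
    if isinstance(sequences, Mapping):
        sequences = list(sequences.values())
    elif isinstance(sequences, str):
        sequences = [sequences]
    rc = reverse_complement(motif)
    count = 0
    total_len = 0
    for seq in sequences:
        count += _count_matches(seq, motif, max_mismatch)
        count += _count_matches(seq, rc, max_mismatch)
        total_len += len(seq)
    if total_len == 0:
        raise ValueError("empty sequence")
    return count, count / (total_len / 1e6)


def per_mbp_expression(
    table: pd.DataFrame,
    records: Sequence[GeneRecord],
    meta: Sequence[GenomeMeta],
) -> pd.DataFrame:
    """Sense and antisense read counts per genome megabase, per (genome, sample)."""
    genome_of = {r.gene_id: r.genome_id for r in records}
    length_of = {m.genome_id: m.length_bp for m in meta}
    t = table.copy()
    t["genome_id"] = t["gene_id"].map(genome_of)
    g = t.groupby(["genome_id", "sample_id"])[["sense", "antisense"]].sum().reset_index()
    mbp = g["genome_id"].map(length_of) / 1e6
    g["sense_per_mbp"] = g["sense"] / mbp
    g["antisense_per_mbp"] = g["antisense"] / mbp
    return g[["genome_id", "sample_id", "sense_per_mbp", "antisense_per_mbp"]]


def genome_summary(
    table: pd.DataFrame,
    calls: pd.DataFrame,
    records: Sequence[GeneRecord],
    meta: Sequence[GenomeMeta],
    sequences: Mapping[str, str],
    motif: str = "TATAAT",
) -> pd.DataFrame:
    """Assemble the per-(genome, sample) covariate table used by the
    association analysis: fraction of significant-asRNA genes, AT content,
    Pribnow density, expression per Mbp and DNA coverage."""
    from .asrna_stats import genome_fraction_significant

    contigs_of: dict[str, list[str]] = {}
    for r in records:
        contigs_of.setdefault(r.genome_id, [])
        if r.contig_id not in contigs_of[r.genome_id]:
            contigs_of[r.genome_id].append(r.contig_id)

    seq_stats = []
    for m in meta:
        seqs = [sequences[c] for c in contigs_of.get(m.genome_id, []) if c in sequences]
        if not seqs:
            continue
        _, density = pribnow_count(seqs, motif=motif)
        seq_stats.append(
            {
                "genome_id": m.genome_id,
                "at_content": at_content(seqs),
                "pribnow_per_mbp": density,
                "dna_coverage": m.dna_coverage,
            }
        )
    seq_df = pd.DataFrame(seq_stats)
    frac = genome_fraction_significant(calls, records)
    expr = per_mbp_expression(table, records, meta)
    out = frac.merge(expr, on=["genome_id", "sample_id"], how="left").merge(
        seq_df, on="genome_id", how="left"
    )
    out["rna_per_mbp"] = out["sense_per_mbp"] + out["antisense_per_mbp"]
    return out
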