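"""Synthetic stranded metatranscriptome communities.

Generates genomes, gene annotations and stranded count tables with the
statistical structure the downstream analysis assumes:

* per-genome antisense propensity pi_g drawn from a Beta prior — the true
  antisense fraction baseline of every gene on that genome;
* a handful of "hyper-asRNA" genes per community (true antisense fraction
  >= 0.95, top-percentile expression) that dominate the antisense read pool;
* a strand-flip technical error: every read's strand label flips
  independently with probability q_true, the false-antisense rate the
  binomial test is calibrated against;
* genomic-DNA contamination: strand-balanced extra reads whose intensity is
  proportional to gene length x genome DNA coverage, scaled so that ``rho``
  is the expected contamination share of all reads.

Counts are generated directly at the gene level (no read-level FASTQ); a
small SAM emitter exists solely to exercise the alignment-counting path.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core_io import (
    GeneRecord,
    GenomeMeta,
    write_contig_map,
    write_cog_map,
    write_counts,
    write_fasta,
    write_genome_meta,
    write_gff,
)

# COG single-letter functional categories (X = mobilome), used for the
# synthetic annotation model.
COG_LETTERS = "JKLDVTMNUOCGEFHIPQRSX"


@dataclass
class SimConfig:
    """Parameters of the synthetic community generator.

    Rates are probabilities in [0, 1]; lengths in bp. ``rho`` is the DNA
    contamination fraction expressed as the expected share of total reads
    contributed by contamination.
    """

    n_genomes: int = 8
    genes_per_genome: int = 120
    gene_length: tuple[int, int] = (300, 1500)
    intergenic_length: tuple[int, int] = (20, 200)
    genome_length_bp: int | None = None  # derived from tiling when None
    at_content: Sequence[float] | None = None  # per genome; default spread 0.35-0.65
    expr_mu: float = 0.0
    expr_sigma: float = 1.5  # heavy tail: a few genes dominate expression
    asrna_beta: tuple[float, float] = (1.0, 19.0)  # pi_g prior, mean 0.05
    pi_fixed: float | None = None  # overrides the Beta draw (0.0 -> null community)
    n_hyper_asrna_genes: int = 3
    hyper_asrna_fraction: float = 0.98
    hyper_expr_quantile: float = 0.99
    q_true: float = 0.01
    rho: float = 0.0
    dna_coverage: Sequence[float] | None = None  # per genome; default lognormal
    mean_reads_per_gene: float = 200.0
    library_size_cv: float = 0.2
    cog_annotated_frac: float = 0.55
    hyper_cog_category: str | None = None  # None -> hyper genes unannotated

    def validate(self) -> None:
        for name in ("q_true", "rho", "hyper_asrna_fraction", "cog_annotated_frac"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.rho >= 1.0:
            raise ValueError("rho must be < 1")
        if self.pi_fixed is not None and not (0.0 <= self.pi_fixed <= 1.0):
            raise ValueError("pi_fixed must be in [0, 1]")
        if self.n_genomes < 0 or self.genes_per_genome < 0:
            raise ValueError("n_genomes and genes_per_genome must be nonnegative")
        if self.gene_length[0] > self.gene_length[1] or self.gene_length[0] <= 0:
            raise ValueError("invalid gene_length range")
        if self.genome_length_bp is not None:
            if self.genes_per_genome * self.gene_length[1] > self.genome_length_bp:
                raise ValueError(
                    "genes_per_genome x max gene length exceeds genome_length_bp"
                )


@dataclass
class SimTruth:
    """Ground truth of a simulated community, for parameter-recovery checks."""

    genes: pd.DataFrame  # gene_id, genome_id, f (true antisense fraction), theta
    genomes: pd.DataFrame  # genome_id, pi, at_content, dna_coverage
    q_true: float
    rho: float


def _genome_at_targets(config: SimConfig) -> np.ndarray:
    if config.at_content is not None:
        at = np.asarray(config.at_content, dtype=float)
        if len(at) != config.n_genomes:
            raise ValueError("at_content must have one value per genome")
        return at
    if config.n_genomes == 1:
        return np.array([0.5])
    return np.linspace(0.35, 0.65, config.n_genomes)


def _random_sequence(length: int, at: float, rng: np.random.Generator) -> str:
    probs = [at / 2, at / 2, (1 - at) / 2, (1 - at) / 2]
    bases = rng.choice(np.array(["A", "T", "C", "G"]), size=length, p=probs)
    return "".join(bases)


def simulate_genomes(
    config: SimConfig, rng: np.random.Generator
) -> tuple[dict[str, str], list[GeneRecord], list[GenomeMeta]]:
    """Generate genome sequences, tiled gene annotations and metadata.

    Genes tile each genome's single contig on alternating strands without
    overlap, separated by random intergenic gaps. Sequence bases are drawn
    i.i.d. with P(A)=P(T)=at/2 so the realized AT content concentrates on
    the per-genome target.
    """
    config.validate()
    at_targets = _genome_at_targets(config)
    if config.dna_coverage is not None:
        coverage = np.asarray(config.dna_coverage, dtype=float)
        if len(coverage) != config.n_genomes:
            raise ValueError("dna_coverage must have one value per genome")
    else:
        coverage = rng.lognormal(mean=np.log(10.0), sigma=0.6, size=config.n_genomes)

    sequences: dict[str, str] = {}
    records: list[GeneRecord] = []
    meta: list[GenomeMeta] = []
    for g in range(config.n_genomes):
        genome_id = f"genome{g:03d}"
        contig_id = f"{genome_id}_ctg"
        lo, hi = config.gene_length
        lengths = rng.integers(lo, hi + 1, size=config.genes_per_genome)
        gaps = rng.integers(
            config.intergenic_length[0],
            config.intergenic_length[1] + 1,
            size=config.genes_per_genome + 1,
        )
        pos = 0
        for i in range(config.genes_per_genome):
            pos += int(gaps[i])
            start, end = pos, pos + int(lengths[i])
            records.append(
                GeneRecord(
                    gene_id=f"{genome_id}_g{i:04d}",
                    genome_id=genome_id,
                    contig_id=contig_id,
                    start=start,
                    end=end,
                    strand="+" if i % 2 == 0 else "-",
                )
            )
            pos = end
        genome_len = pos + int(gaps[-1])
        if config.genome_length_bp is not None:
            if genome_len > config.genome_length_bp:
                raise ValueError(
                    f"{genome_id}: tiled genes ({genome_len} bp) exceed "
                    f"genome_length_bp ({config.genome_length_bp})"
                )
            genome_len = config.genome_length_bp
        sequences[contig_id] = _random_sequence(genome_len, at_targets[g], rng)
        meta.append(
            GenomeMeta(
                genome_id=genome_id,
                length_bp=genome_len,
                completeness_pct=float(rng.uniform(70, 100)),
                contamination_pct=float(rng.uniform(0, 5)),
                dna_coverage=float(coverage[g]),
            )
        )
    return sequences, records, meta


def simulate_truth(
    config: SimConfig, records: Sequence[GeneRecord], meta: Sequence[GenomeMeta],
    rng: np.random.Generator,
) -> SimTruth:
    """Draw the latent per-genome propensities and per-gene truth."""
    genome_ids = [m.genome_id for m in meta]
    if config.pi_fixed is not None:
        pi = np.full(len(genome_ids), config.pi_fixed)
    else:
        a, b = config.asrna_beta
        pi = rng.beta(a, b, size=len(genome_ids))
    pi_by_genome = dict(zip(genome_ids, pi))

    gene_ids = [r.gene_id for r in records]
    gene_genomes = [r.genome_id for r in records]
    f = np.array([pi_by_genome[g] for g in gene_genomes])
    theta = rng.lognormal(mean=config.expr_mu, sigma=config.expr_sigma, size=len(records))

    n_hyper = min(config.n_hyper_asrna_genes, len(records))
    hyper_idx = rng.choice(len(records), size=n_hyper, replace=False) if n_hyper else np.array([], dtype=int)
    if n_hyper:
        f[hyper_idx] = config.hyper_asrna_fraction
        # hyper genes sit in the top expression percentile so they dominate
        # the antisense pool, as a few genes do in real communities
        floor = np.quantile(theta, config.hyper_expr_quantile)
        theta[hyper_idx] = floor * rng.uniform(2.0, 5.0, size=n_hyper)

    is_hyper = np.zeros(len(records), dtype=bool)
    is_hyper[hyper_idx] = True
    genes = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "genome_id": gene_genomes,
            "f": f,
            "theta": theta,
            "hyper": is_hyper,
        }
    )
    genomes = pd.DataFrame(
        {
            "genome_id": genome_ids,
            "pi": pi,
            "at_content": _genome_at_targets(config),
            "dna_coverage": [m.dna_coverage for m in meta],
        }
    )
    return SimTruth(genes=genes, genomes=genomes, q_true=config.q_true, rho=config.rho)


def simulate_cogs(
    config: SimConfig, truth: SimTruth, rng: np.random.Generator
) -> dict[str, str]:
    """Assign COG letters: a fixed annotated fraction spread over the letter
    alphabet; hyper-asRNA genes are unannotated unless ``hyper_cog_category``
    redirects them to one category (e.g. X, the mobilome)."""
    letters = list(COG_LETTERS)
    out: dict[str, str] = {}
    for row in truth.genes.itertuples(index=False):
        if row.hyper:
            out[row.gene_id] = config.hyper_cog_category or ""
        elif rng.random() < config.cog_annotated_frac:
            out[row.gene_id] = letters[rng.integers(len(letters))]
        else:
            out[row.gene_id] = ""
    return out


def simulate_counts(
    records: Sequence[GeneRecord],
    truth: SimTruth,
    config: SimConfig,
    n_samples: int,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Generate the stranded count table.

    Per gene i and sample s: biological reads n_is ~ Poisson(theta_i * L_s);
    antisense before error ~ Binomial(n_is, f_i); every read's strand label
    flips independently with probability q_true; contamination adds
    c_is ~ Poisson(rho' * lambda_is) reads split Binomial(c_is, 1/2) between
    strands, with lambda proportional to gene length x genome DNA coverage
    and rho' = rho / (1 - rho) so that rho is the expected contamination
    share of all reads.
    """
    config.validate()
    genes = truth.genes.set_index("gene_id")
    order = [r.gene_id for r in records]
    f = genes.loc[order, "f"].to_numpy()
    theta = genes.loc[order, "theta"].to_numpy()
    lengths = np.array([r.length for r in records], dtype=float)
    cov_by_genome = dict(zip(truth.genomes["genome_id"], truth.genomes["dna_coverage"]))
    cov = np.array([cov_by_genome[r.genome_id] for r in records], dtype=float)

    # scale expression so the mean biological depth per gene is the target
    rate = theta / theta.mean() * config.mean_reads_per_gene
    total_bio = rate.sum()
    weights = lengths * cov
    if config.rho > 0 and weights.sum() > 0:
        lam_contam = weights / weights.sum() * total_bio * config.rho / (1.0 - config.rho)
    else:
        lam_contam = np.zeros_like(weights)

    frames = []
    for s in range(n_samples):
        lib = rng.lognormal(
            mean=-0.5 * np.log1p(config.library_size_cv**2),
            sigma=np.sqrt(np.log1p(config.library_size_cv**2)),
        )
        n = rng.poisson(rate * lib)
        anti = rng.binomial(n, f)
        # independent per-read strand-label flips with probability q
        flips_to_sense = rng.binomial(anti, config.q_true)
        flips_to_anti = rng.binomial(n - anti, config.q_true)
        anti = anti - flips_to_sense + flips_to_anti
        c = rng.poisson(lam_contam * lib)
        c_anti = rng.binomial(c, 0.5)
        frames.append(
            pd.DataFrame(
                {
                    "gene_id": order,
                    "sample_id": f"sample{s:02d}",
                    "sense": (n - anti) + (c - c_anti),
                    "antisense": anti + c_anti,
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=["gene_id", "sample_id", "sense", "antisense"])
    return pd.concat(frames, ignore_index=True)


def simulate_community(
    config: SimConfig, n_samples: int, seed: int
) -> tuple[dict[str, str], list[GeneRecord], list[GenomeMeta], SimTruth, dict[str, str], pd.DataFrame]:
    """One-call generator: genomes, records, metadata, truth, COGs, counts."""
    rng = np.random.default_rng(seed)
    sequences, records, meta = simulate_genomes(config, rng)
    truth = simulate_truth(config, records, meta, rng)
    cogs = simulate_cogs(config, truth, rng)
    counts = simulate_counts(records, truth, config, n_samples, rng)
    return sequences, records, meta, truth, cogs, counts


def write_community(
    outdir: str | Path,
    sequences: dict[str, str],
    records: Sequence[GeneRecord],
    meta: Sequence[GenomeMeta],
    truth: SimTruth,
    cogs: dict[str, str],
    counts: pd.DataFrame,
) -> dict[str, Path]:
    """Write all community artifacts as plain text files; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": outdir / "genomes.fasta",
        "gff": outdir / "genes.gff3",
        "counts": outdir / "counts.tsv",
        "meta": outdir / "genome_meta.tsv",
        "contig_map": outdir / "contig_map.tsv",
        "cogs": outdir / "cog_map.tsv",
        "truth_genes": outdir / "truth_genes.tsv",
        "truth_genomes": outdir / "truth_genomes.tsv",
    }
    write_fasta(sequences, paths["fasta"])
    write_gff(records, paths["gff"])
    write_counts(counts, paths["counts"])
    write_genome_meta(meta, paths["meta"])
    write_contig_map({r.contig_id: r.genome_id for r in records}, paths["contig_map"])
    write_cog_map(cogs, paths["cogs"])
    truth.genes.to_csv(paths["truth_genes"], sep="\t", index=False)
    truth.genomes.to_csv(paths["truth_genomes"], sep="\t", index=False)
    return paths


def emit_sam(
    records: Sequence[GeneRecord],
    counts: pd.DataFrame,
    sequences: dict[str, str],
    path: str | Path,
    sample_id: str | None = None,
    read_length: int = 50,
    reverse_stranded: bool = True,
) -> None:
    """Write one SAM alignment per counted read, placed inside its gene.

    Exists solely so the alignment-counting path can be tested against
    directly simulated counts; reads never extend past gene boundaries, so
    with non-overlapping genes the counter must recover the table exactly.
    """
    sub = counts if sample_id is None else counts[counts["sample_id"] == sample_id]
    by_gene = {r.gene_id: r for r in records}
    contig_lengths = {c: len(s) for c, s in sequences.items()}
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        for contig, length in contig_lengths.items():
            fh.write(f"@SQ\tSN:{contig}\tLN:{length}\n")
        i = 0
        for row in sub.itertuples(index=False):
            gene = by_gene[row.gene_id]
            rlen = min(read_length, gene.length)
            for strand_label, count in (("sense", row.sense), ("antisense", row.antisense)):
                transcript_strand = gene.strand
                if strand_label == "antisense":
                    transcript_strand = "-" if gene.strand == "+" else "+"
                # reverse-stranded chemistry: read 1 aligns opposite the transcript
                aligned = transcript_strand
                if reverse_stranded:
                    aligned = "-" if aligned == "+" else "+"
                flag = 16 if aligned == "-" else 0
                for _ in range(int(count)):
                    fh.write(
                        f"read{i}\t{flag}\t{gene.contig_id}\t{gene.start + 1}\t60\t"
                        f"{rlen}M\t*\t0\t0\t*\t*\n"
                    )
                    i += 1
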