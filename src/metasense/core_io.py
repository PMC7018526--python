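"""Domain types and readers/writers for the text formats used across the pipeline.

Coordinates are 0-based half-open everywhere inside the package; files keep
their native conventions (GFF3 is 1-based inclusive on disk). Count tables,
genome metadata, contig->genome maps and COG assignments travel as TSV.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from gffutils import feature as _gff_feature

logger = logging.getLogger(__name__)

COUNT_COLUMNS = ["gene_id", "sample_id", "sense", "antisense"]
META_COLUMNS = ["genome_id", "length_bp", "completeness_pct", "contamination_pct"]


@dataclass(frozen=True)
class GeneRecord:
    """One annotated protein-coding gene (0-based half-open coordinates)."""

    gene_id: str
    genome_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    feature_type: str = "CDS"
    cog_category: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"gene {self.gene_id}: require 0 <= start < end, "
                f"got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GenomeMeta:
    """Assembly-level metadata for one genome or MAG."""

    genome_id: str
    length_bp: int
    completeness_pct: float
    contamination_pct: float
    dna_coverage: float | None = None

    def __post_init__(self) -> None:
        if self.length_bp <= 0:
            raise ValueError(f"genome {self.genome_id}: length_bp must be positive")
        if not (0 <= self.completeness_pct <= 100):
            raise ValueError(f"genome {self.genome_id}: completeness outside [0, 100]")
        if not (0 <= self.contamination_pct <= 100):
            raise ValueError(f"genome {self.genome_id}: contamination outside [0, 100]")


def validate_counts(table: pd.DataFrame) -> pd.DataFrame:
    """Validate a stranded count table: required columns, nonnegative integer
    counts, unique (gene_id, sample_id) keys."""
    missing = [c for c in COUNT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"count table missing column(s): {missing}")
    for col in ("sense", "antisense"):
        if len(table) and (table[col] < 0).any():
            bad = table.loc[table[col] < 0].iloc[0]
            raise ValueError(
                f"negative {col} count for ({bad['gene_id']}, {bad['sample_id']})"
            )
    dup = table.duplicated(subset=["gene_id", "sample_id"])
    if dup.any():
        bad = table.loc[dup].iloc[0]
        raise ValueError(f"duplicate key ({bad['gene_id']}, {bad['sample_id']})")
    return table


def read_counts(path: str | Path) -> pd.DataFrame:
    """Read a stranded count table (TSV with header gene_id, sample_id, sense,
    antisense)."""
    table = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "sample_id": str})
    if len(table) == 0:
        # preserve schema for an empty file that has the header
        table = table.reindex(columns=COUNT_COLUMNS if not len(table.columns) else table.columns)
    validate_counts(table)
    table = table[COUNT_COLUMNS + [c for c in table.columns if c not in COUNT_COLUMNS]]
    table["sense"] = table["sense"].astype("int64")
    table["antisense"] = table["antisense"].astype("int64")
    return table.reset_index(drop=True)


def write_counts(table: pd.DataFrame, path: str | Path) -> None:
    validate_counts(table)
    table.to_csv(path, sep="\t", index=False)


def read_genome_meta(path: str | Path) -> list[GenomeMeta]:
    df = pd.read_csv(path, sep="\t", dtype={"genome_id": str})
    missing = [c for c in META_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"genome metadata missing column(s): {missing}")
    has_cov = "dna_coverage" in df.columns
    out = []
    for row in df.itertuples(index=False):
        cov = getattr(row, "dna_coverage", None) if has_cov else None
        if cov is not None and pd.isna(cov):
            cov = None
        out.append(
            GenomeMeta(
                genome_id=row.genome_id,
                length_bp=int(row.length_bp),
                completeness_pct=float(row.completeness_pct),
                contamination_pct=float(row.contamination_pct),
                dna_coverage=None if cov is None else float(cov),
            )
        )
    return out


def write_genome_meta(meta: Sequence[GenomeMeta], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "genome_id": [m.genome_id for m in meta],
            "length_bp": [m.length_bp for m in meta],
            "completeness_pct": [m.completeness_pct for m in meta],
            "contamination_pct": [m.contamination_pct for m in meta],
            "dna_coverage": [m.dna_coverage for m in meta],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_contig_map(path: str | Path) -> dict[str, str]:
    """Read a 2-column TSV (contig_id, genome_id) into a dict."""
    df = pd.read_csv(path, sep="\t", header=None, names=["contig_id", "genome_id"], dtype=str)
    return dict(zip(df["contig_id"], df["genome_id"]))


def write_contig_map(contig_map: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for contig, genome in contig_map.items():
            fh.write(f"{contig}\t{genome}\n")


def read_cog_map(path: str | Path) -> dict[str, str]:
    """Read COG assignments (TSV: gene_id, single-letter categories as a string).

    Genes absent from the file, or with an empty / '-' category field, are
    unannotated.
    """
    df = pd.read_csv(path, sep="\t", header=None, names=["gene_id", "letters"], dtype=str)
    out: dict[str, str] = {}
    for row in df.itertuples(index=False):
        letters = "" if pd.isna(row.letters) or row.letters == "-" else row.letters
        out[row.gene_id] = letters
    return out


def write_cog_map(cog_map: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gene, letters in cog_map.items():
            fh.write(f"{gene}\t{letters or '-'}\n")


def read_gff(
    path: str | Path,
    feature_filter: Iterable[str] = ("CDS",),
    genome_attribute: str | None = None,
    contig_map: Mapping[str, str] | None = None,
) -> list[GeneRecord]:
    """Read gene records from a GFF3 file.

    File coordinates (1-based inclusive) are converted to 0-based half-open.
    Only features whose type is in ``feature_filter`` are kept. genome_id is
    resolved from, in order of precedence: the ``genome_attribute`` GFF
    attribute, the ``contig_map`` (contig -> genome), or the file stem.
    """
    wanted = set(feature_filter)
    stem = Path(path).stem
    records: list[GeneRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                if line.startswith("##FASTA"):
                    break
                continue
            if len(line.split("\t")) != 9:
                raise ValueError(
                    f"{path}: malformed GFF line {lineno}: expected 9 tab-separated fields"
                )
            try:
                feat = _gff_feature.feature_from_line(line)
            except Exception as exc:
                raise ValueError(f"{path}: malformed GFF line {lineno}: {exc}") from exc
            if feat.featuretype not in wanted:
                continue
            if feat.end < feat.start:
                raise ValueError(
                    f"{path}: line {lineno}: end ({feat.end}) < start ({feat.start})"
                )
            attrs = feat.attributes
            gene_id = attrs["ID"][0] if "ID" in attrs else f"{feat.seqid}:{feat.start}-{feat.end}"
            if genome_attribute and genome_attribute in attrs:
                genome_id = attrs[genome_attribute][0]
            elif contig_map and feat.seqid in contig_map:
                genome_id = contig_map[feat.seqid]
            else:
                genome_id = stem
            records.append(
                GeneRecord(
                    gene_id=gene_id,
                    genome_id=genome_id,
                    contig_id=feat.seqid,
                    start=feat.start - 1,
                    end=feat.end,
                    strand=feat.strand,
                    feature_type=feat.featuretype,
                )
            )
    seen: set[str] = set()
    for rec in records:
        if rec.gene_id in seen:
            raise ValueError(f"{path}: duplicate gene_id {rec.gene_id}")
        seen.add(rec.gene_id)
    return records


def write_gff(records: Sequence[GeneRecord], path: str | Path, source: str = "metasense") -> None:
    """Write gene records as GFF3 (restores 1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for rec in records:
            fh.write(
                f"{rec.contig_id}\t{source}\t{rec.feature_type}\t"
                f"{rec.start + 1}\t{rec.end}\t.\t{rec.strand}\t0\t"
                f"ID={rec.gene_id};genome={rec.genome_id}\n"
            )


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    recs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(recs, str(path), "fasta")


def records_frame(records: Sequence[GeneRecord]) -> pd.DataFrame:
    """Tabular view of gene records, used for joins against count tables."""
    return pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in records],
            "genome_id": [r.genome_id for r in records],
            "contig_id": [r.contig_id for r in records],
            "start": [r.start for r in records],
            "end": [r.end for r in records],
            "strand": [r.strand for r in records],
            "feature_type": [r.feature_type for r in records],
            "length_bp": [r.length for r in records],
        }
    )
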