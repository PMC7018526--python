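"""Per-gene sense/antisense read counting from strand-specific alignments.

A read is *sense* for a gene when its effective strand — the aligned strand,
flipped once for reverse-stranded library chemistry and once more for the
second mate of a pair — equals the gene's annotated strand; otherwise it is
*antisense* (the read matches the template strand). Every alignment
increments exactly one counter of every gene it overlaps by at least
``min_overlap`` bases.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd
import pysam
from intervaltree import IntervalTree

from .core_io import GeneRecord, validate_counts

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AlignmentRecord:
    """A single strand-aware alignment (0-based half-open)."""

    query_id: str
    contig_id: str
    start: int
    end: int
    aligned_strand: str
    is_secondary: bool = False
    mate: int | str = "unpaired"  # 1, 2 or "unpaired"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"alignment {self.query_id}: start must be < end")
        if self.aligned_strand not in ("+", "-"):
            raise ValueError(f"alignment {self.query_id}: bad strand {self.aligned_strand!r}")


@dataclass(frozen=True)
class LibraryLayout:
    """Strandedness of the sequencing library.

    reverse_stranded (dUTP/TruSeq-style): read 1 aligns opposite the
    transcript; forward_stranded: read 1 aligns with the transcript.
    """

    orientation: str = "reverse_stranded"
    paired: bool = False

    def __post_init__(self) -> None:
        if self.orientation not in ("reverse_stranded", "forward_stranded"):
            raise ValueError(f"unknown orientation {self.orientation!r}")


def _flip(strand: str) -> str:
    return "-" if strand == "+" else "+"


def classify_strandness(
    aln: AlignmentRecord, gene: GeneRecord, layout: LibraryLayout
) -> str:
    """Classify an overlapping alignment as 'sense' or 'antisense' for a gene."""
    if aln.contig_id != gene.contig_id or aln.end <= gene.start or aln.start >= gene.end:
        raise ValueError(
            f"alignment {aln.query_id} does not overlap gene {gene.gene_id}; "
            "caller must pre-filter"
        )
    effective = aln.aligned_strand
    if layout.orientation == "reverse_stranded":
        effective = _flip(effective)
    if aln.mate == 2:
        effective = _flip(effective)
    return "sense" if effective == gene.strand else "antisense"


def count_stranded(
    alignments: Iterable[AlignmentRecord],
    records: Sequence[GeneRecord],
    layout: LibraryLayout,
    sample_id: str = "sample",
    min_overlap: int = 1,
    include_secondary: bool = True,
) -> pd.DataFrame:
    """Count sense and antisense alignments per gene.

    Each qualifying alignment increments exactly one counter (sense or
    antisense) of every gene it overlaps by >= ``min_overlap`` bases; the
    result is order-independent. Alignments on contigs absent from the
    annotation are tallied as unassigned (logged, and stored in the result's
    ``attrs['unassigned']``), not an error.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    trees: dict[str, IntervalTree] = {}
    for rec in records:
        trees.setdefault(rec.contig_id, IntervalTree()).addi(rec.start, rec.end, rec)

    sense: dict[str, int] = {r.gene_id: 0 for r in records}
    antisense: dict[str, int] = {r.gene_id: 0 for r in records}
    unassigned = 0
    for aln in alignments:
        if aln.is_secondary and not include_secondary:
            continue
        tree = trees.get(aln.contig_id)
        if tree is None:
            unassigned += 1
            continue
        hit_any = False
        for iv in tree.overlap(aln.start, aln.end):
            gene: GeneRecord = iv.data
            overlap = min(aln.end, gene.end) - max(aln.start, gene.start)
            if overlap < min_overlap:
                continue
            hit_any = True
            if classify_strandness(aln, gene, layout) == "sense":
                sense[gene.gene_id] += 1
            else:
                antisense[gene.gene_id] += 1
        if not hit_any:
            unassigned += 1
    if unassigned:
        logger.info("%d alignments not assigned to any gene", unassigned)
    table = pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in records],
            "sample_id": sample_id,
            "sense": [sense[r.gene_id] for r in records],
            "antisense": [antisense[r.gene_id] for r in records],
        }
    )
    validate_counts(table)
    table.attrs["unassigned"] = unassigned
    return table


def iter_sam(path: str | Path, paired_hint: bool | None = None) -> Iterator[AlignmentRecord]:
    """Stream alignments from a SAM/BAM file as AlignmentRecord objects.

    Unmapped records are skipped; mate is 1/2 for paired reads and
    'unpaired' otherwise.
    """
    mode = "rb" if str(path).endswith(".bam") else "r"
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as fh:
        for read in fh:
            if read.is_unmapped:
                continue
            if read.is_paired:
                mate = 2 if read.is_read2 else 1
            else:
                mate = "unpaired"
            yield AlignmentRecord(
                query_id=read.query_name,
                contig_id=read.reference_name,
                start=read.reference_start,
                end=read.reference_end,
                aligned_strand="-" if read.is_reverse else "+",
                is_secondary=read.is_secondary,
                mate=mate,
            )


def count_sam(
    path: str | Path,
    records: Sequence[GeneRecord],
    layout: LibraryLayout,
    sample_id: str = "sample",
    min_overlap: int = 1,
    include_secondary: bool = True,
) -> pd.DataFrame:
    """Convenience wrapper: stream a SAM/BAM file through count_stranded."""
    return count_stranded(
        iter_sam(path),
        records,
        layout,
        sample_id=sample_id,
        min_overlap=min_overlap,
        include_secondary=include_secondary,
    )
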