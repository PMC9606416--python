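"""Targeted Cas9 nanopore read analysis for knock-in verification.

Reads from a Cas9-targeted sequencing run are triaged by their alignment to
the transgene (eGFP) reference; the genomic alignments of those
transgene-bearing reads are then filtered (primary, MAPQ >= 20) and each
read is classified as *site-specific* (its alignment falls at the intended
integration locus, within a tolerance window) or *random*.  The summary
reports integration specificity — the fraction of classified reads that are
site-specific — and the fold enrichment of the targeted protocol over
untargeted shotgun expectation::

    fold_enrichment = n_targeted / (2 * gene_copies * bases_sequenced / genome_size)

i.e. observed transgene-spanning reads over the number expected at the
run's genome-equivalent depth given the relative transgene copy number.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .intervals import GenomicInterval

__all__ = [
    "ReadAlignmentRecord",
    "TargetedReadSet",
    "ReadLabel",
    "ClassificationResult",
    "NoOnTargetReadsError",
    "select_targeted_reads",
    "filter_genomic_alignments",
    "classify_read",
    "specificity",
    "fold_enrichment",
    "analyze_pool",
    "read_sam",
    "read_alignment_tsv",
    "write_alignment_tsv",
    "split_by_reference",
]

CATEGORIES = ("primary", "secondary", "supplementary")


class NoOnTargetReadsError(ValueError):
    """No reads could be classified (specificity undefined, not zero)."""


@dataclass(frozen=True)
class ReadAlignmentRecord:
    """One alignment of one read: the facts classification needs."""

    read_id: str
    reference: str
    start: int  # 0-based half-open
    end: int
    mapq: int
    category: str = "primary"
    read_length: int = 0

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"alignment {self.read_id}: start >= end")
        if self.mapq < 0:
            raise ValueError(f"alignment {self.read_id}: negative MAPQ")
        if self.category not in CATEGORIES:
            raise ValueError(f"alignment {self.read_id}: bad category {self.category!r}")


@dataclass
class TargetedReadSet:
    """All inputs for one pool: alignments split by reference space plus
    run-level scalars for the enrichment computation."""

    transgene_alignments: list[ReadAlignmentRecord]
    genomic_alignments: list[ReadAlignmentRecord]
    total_bases: int
    genome_size: int
    gene_copies: float
    site: GenomicInterval

    def __post_init__(self) -> None:
        if self.total_bases <= 0 or self.genome_size <= 0 or self.gene_copies <= 0:
            raise ValueError("total_bases, genome_size and gene_copies must be > 0")


@dataclass(frozen=True)
class ReadLabel:
    read_id: str
    label: str  # "site-specific" | "random"
    contig: str
    start: int
    offset: int  # signed alignment start - site start (same contig only)


@dataclass
class ClassificationResult:
    n_specific: int
    n_random: int
    n_unclassifiable: int
    specificity: float
    fold_enrichment: float
    labels: list[ReadLabel] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (l.read_id, l.label, l.contig, l.start, l.offset)
                for l in self.labels
            ],
            columns=["read_id", "label", "contig", "start", "offset"],
        )


def select_targeted_reads(alignments: Iterable[ReadAlignmentRecord]) -> set[str]:
    """IDs of reads with >= 1 alignment (of any category) to the transgene.

    The triage is deliberately permissive: a secondary or supplementary hit
    on the transgene still flags the read as transgene-bearing; the strict
    primary/MAPQ filter applies only to the *genomic* alignment used for
    classification.
    """
    return {a.read_id for a in alignments}


def filter_genomic_alignments(
    records: Iterable[ReadAlignmentRecord], min_mapq: int = 20
) -> list[ReadAlignmentRecord]:
    """Keep primary alignments with MAPQ >= ``min_mapq``; discard
    secondary/supplementary alignments and low-MAPQ placements."""
    return [
        r for r in records if r.category == "primary" and r.mapq >= min_mapq
    ]


def classify_read(
    aln: ReadAlignmentRecord, site: GenomicInterval, tolerance: int = 1000
) -> ReadLabel:
    """Label one genomic alignment site-specific or random.

    Site-specific iff the alignment overlaps the intended site widened by
    ``tolerance`` bp on each side (observed knock-in junctions can sit some
    hundred bp off the cut site).  The offset reported is the signed
    distance from alignment start to site start.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be non-negative")
    on_site = (
        aln.reference == site.contig
        and aln.start < site.end + tolerance
        and aln.end > site.start - tolerance
    )
    offset = aln.start - site.start if aln.reference == site.contig else 0
    return ReadLabel(
        aln.read_id,
        "site-specific" if on_site else "random",
        aln.reference,
        aln.start,
        offset,
    )


def specificity(labels: Sequence[ReadLabel]) -> float:
    """Fraction of classified reads labeled site-specific, in [0, 1]."""
    if not labels:
        raise NoOnTargetReadsError("no classified reads: specificity undefined")
    n_spec = sum(1 for l in labels if l.label == "site-specific")
    return n_spec / len(labels)


def fold_enrichment(
    n_targeted: int, gene_copies: float, bases_sequenced: int, genome_size: int
) -> float:
    """Observed over expected transgene-spanning reads.

    The factor 2 follows the published formula for the expected insert
    count; the depth fraction ``bases_sequenced / genome_size`` scales the
    expectation to the run's genome coverage.
    """
    if min(n_targeted, gene_copies, bases_sequenced, genome_size) <= 0:
        raise ValueError("all fold_enrichment arguments must be positive")
    return n_targeted / (2.0 * gene_copies * (bases_sequenced / genome_size))


def analyze_pool(
    pool: TargetedReadSet, tolerance: int = 1000, min_mapq: int = 20
) -> ClassificationResult:
    """End-to-end per-pool computation.

    Composes read triage, genomic-alignment filtering, per-read
    classification, specificity, and fold enrichment.  Reads whose genomic
    alignments are all filtered out are counted unclassifiable and excluded
    from the specificity denominator.  Raises
    :class:`NoOnTargetReadsError` when nothing survives.
    """
    targeted = select_targeted_reads(pool.transgene_alignments)
    candidates = [a for a in pool.genomic_alignments if a.read_id in targeted]
    surviving = filter_genomic_alignments(candidates, min_mapq)
    by_read: dict[str, ReadAlignmentRecord] = {}
    for a in surviving:
        best = by_read.get(a.read_id)
        if best is None or a.mapq > best.mapq:
            by_read[a.read_id] = a
    reads_with_genomic = {a.read_id for a in candidates}
    n_unclassifiable = len(reads_with_genomic - set(by_read))
    labels = [
        classify_read(a, pool.site, tolerance) for a in by_read.values()
    ]
    labels.sort(key=lambda l: l.read_id)
    if not labels:
        raise NoOnTargetReadsError(
            "no on-target reads: every transgene-bearing read lost its "
            "genomic alignment to the MAPQ/supplementary filter"
        )
    frac = specificity(labels)
    n_spec = sum(1 for l in labels if l.label == "site-specific")
    fe = fold_enrichment(
        len(labels), pool.gene_copies, pool.total_bases, pool.genome_size
    )
    return ClassificationResult(
        n_specific=n_spec,
        n_random=len(labels) - n_spec,
        n_unclassifiable=n_unclassifiable,
        specificity=frac,
        fold_enrichment=fe,
        labels=labels,
    )


# ---------------------------------------------------------------------------
# IO: SAM and the 7-column TSV dialect
# ---------------------------------------------------------------------------

TSV_COLUMNS = ["read_id", "ref", "start", "end", "mapq", "category", "read_length"]


def _category_from_flag(flag: int) -> str:
    if flag & 0x800:
        return "supplementary"
    if flag & 0x100:
        return "secondary"
    return "primary"


def read_sam(path: str | Path) -> list[ReadAlignmentRecord]:
    """Read alignment records from a SAM file (unmapped records skipped)."""
    import pysam

    records: list[ReadAlignmentRecord] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for aln in sam:
            if aln.is_unmapped:
                continue
            records.append(
                ReadAlignmentRecord(
                    read_id=aln.query_name,
                    reference=aln.reference_name,
                    start=aln.reference_start,
                    end=aln.reference_end,
                    mapq=aln.mapping_quality,
                    category=_category_from_flag(aln.flag),
                    read_length=aln.infer_read_length() or 0,
                )
            )
    return records


def read_alignment_tsv(path: str | Path) -> list[ReadAlignmentRecord]:
    """Read the 7-column TSV alignment dialect
    (read_id, ref, start, end, mapq, category, read_length)."""
    df = pd.read_csv(path, sep="\t", dtype={"read_id": str, "ref": str})
    missing = set(TSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return [
        ReadAlignmentRecord(
            read_id=row.read_id,
            reference=row.ref,
            start=int(row.start),
            end=int(row.end),
            mapq=int(row.mapq),
            category=row.category,
            read_length=int(row.read_length),
        )
        for row in df.itertuples(index=False)
    ]


def write_alignment_tsv(
    records: Iterable[ReadAlignmentRecord], path: str | Path
) -> None:
    pd.DataFrame(
        [
            (r.read_id, r.reference, r.start, r.end, r.mapq, r.category, r.read_length)
            for r in records
        ],
        columns=TSV_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


def split_by_reference(
    records: Iterable[ReadAlignmentRecord], transgene_ref: str
) -> tuple[list[ReadAlignmentRecord], list[ReadAlignmentRecord]]:
    """Split records into (transgene-space, genome-space) lists."""
    transgene, genomic = [], []
    for r in records:
        (transgene if r.reference == transgene_ref else genomic).append(r)
    return transgene, genomic
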