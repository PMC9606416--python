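"""Genomic interval data model, interval algebra, and BED/GTF/FASTA IO.

All coordinates are 0-based half-open (BED-native): an interval ``(contig,
start, end)`` covers bases ``start .. end-1``.  Annotation formats using
1-based inclusive coordinates (GTF/GFF) are converted on read.

The algebra here deliberately mirrors the record-level semantics of the
bedtools suite as used in peak post-processing pipelines, with one
documented difference: :func:`merge` joins intervals whose gap is *strictly*
smaller than ``max_gap``.
"""

from __future__ import annotations

import logging
from bisect import bisect_left
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VALID_STRANDS = {"+", "-", "."}

__all__ = [
    "GenomicInterval",
    "IntervalSet",
    "TssIndex",
    "BedParseError",
    "read_bed",
    "write_bed",
    "read_tss_index",
    "merge",
    "intersect",
    "union",
    "anti_join",
    "tss_distance",
    "extract_sequences",
]


class BedParseError(ValueError):
    """A malformed line in a BED file (bad coordinates, too few columns)."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A strand-aware half-open genomic span.

    Parameters
    ----------
    contig : str
        Reference sequence name (chromosome or scaffold).
    start, end : int
        0-based half-open coordinates, ``0 <= start < end``.
    strand : str
        One of ``+``, ``-`` or ``.`` (unstranded).
    name : str, optional
        Free-text label (BED column 4).
    score : float, optional
        BED column 5.
    """

    contig: str
    start: int
    end: int
    strand: str = "."
    name: str | None = field(default=None, compare=False)
    score: float | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.contig}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True if the two spans share at least one base."""
        return (
            self.contig == other.contig
            and self.start < other.end
            and other.start < self.end
        )

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.contig}:{self.start}-{self.end}"


class IntervalSet:
    """An immutable, sorted, deduplicated collection of :class:`GenomicInterval`.

    Sorting key is ``(contig, start, end)``; duplicates on that key are
    collapsed (set semantics — the first occurrence's name/score win).
    """

    __slots__ = ("_intervals", "_by_contig")

    def __init__(self, intervals: Iterable[GenomicInterval] = ()) -> None:
        seen: dict[tuple[str, int, int], GenomicInterval] = {}
        for iv in intervals:
            seen.setdefault((iv.contig, iv.start, iv.end), iv)
        self._intervals: tuple[GenomicInterval, ...] = tuple(
            seen[k] for k in sorted(seen)
        )
        by: dict[str, list[GenomicInterval]] = {}
        for iv in self._intervals:
            by.setdefault(iv.contig, []).append(iv)
        self._by_contig = {c: tuple(v) for c, v in by.items()}

    def __len__(self) -> int:
        return len(self._intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self._intervals)

    def __getitem__(self, i: int) -> GenomicInterval:
        return self._intervals[i]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        return [(iv.contig, iv.start, iv.end) for iv in self] == [
            (iv.contig, iv.start, iv.end) for iv in other
        ]

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"IntervalSet({len(self)} intervals, {len(self._by_contig)} contigs)"

    @property
    def contigs(self) -> tuple[str, ...]:
        return tuple(self._by_contig)

    def on_contig(self, contig: str) -> tuple[GenomicInterval, ...]:
        return self._by_contig.get(contig, ())

    def total_bases(self) -> int:
        """Number of bases covered, counting overlapping intervals once."""
        return sum(iv.length for iv in merge(self, 0))


# ---------------------------------------------------------------------------
# BED IO
# ---------------------------------------------------------------------------


def read_bed(path: str | Path) -> IntervalSet:
    """Read a BED file (>=3 tab-separated columns, 0-based half-open).

    ``track``, ``browser`` and ``#`` comment lines and blank lines are
    skipped.  Malformed data lines raise :class:`BedParseError` naming the
    line number.
    """
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(
                    f"{path}:{lineno}: expected >=3 tab-separated columns"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from exc
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score: float | None = None
            if len(fields) > 4 and fields[4] not in (".", ""):
                try:
                    score = float(fields[4])
                except ValueError as exc:
                    raise BedParseError(f"{path}:{lineno}: bad score") from exc
            strand = fields[5] if len(fields) > 5 and fields[5] in VALID_STRANDS else "."
            try:
                intervals.append(
                    GenomicInterval(fields[0], start, end, strand, name, score)
                )
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: {exc}") from exc
    return IntervalSet(intervals)


def write_bed(intervals: IntervalSet, path: str | Path) -> None:
    """Write an :class:`IntervalSet` as BED (sorted; 3–6 columns as needed)."""
    with open(path, "w") as fh:
        for iv in intervals:
            cols = [iv.contig, str(iv.start), str(iv.end)]
            if iv.name is not None or iv.score is not None or iv.strand != ".":
                cols.append(iv.name if iv.name is not None else ".")
            if iv.score is not None or iv.strand != ".":
                cols.append(f"{iv.score:g}" if iv.score is not None else ".")
            if iv.strand != ".":
                cols.append(iv.strand)
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# Annotation / TSS index
# ---------------------------------------------------------------------------


class TssIndex:
    """Per-contig sorted transcription start sites plus gene bodies.

    The TSS of a ``+``-strand gene is its (0-based) start; for a ``-``-strand
    gene it is the last covered base, ``end - 1``.  Nearest-TSS queries are
    strand-agnostic.
    """

    def __init__(
        self,
        tss: Iterable[tuple[str, int, str, str]],
        gene_bodies: IntervalSet,
        skipped: int = 0,
    ) -> None:
        by: dict[str, list[tuple[int, str, str]]] = {}
        for contig, pos, strand, gene_id in tss:
            by.setdefault(contig, []).append((pos, strand, gene_id))
        self._tss = {
            c: sorted(entries) for c, entries in by.items()
        }
        self._positions = {
            c: np.array([p for p, _, _ in entries], dtype=np.int64)
            for c, entries in self._tss.items()
        }
        self.gene_bodies = gene_bodies
        #: records dropped on read (e.g. missing strand)
        self.skipped = skipped

    @property
    def contigs(self) -> tuple[str, ...]:
        return tuple(self._tss)

    def __len__(self) -> int:
        return sum(len(v) for v in self._tss.values())

    def tss_on_contig(self, contig: str) -> tuple[tuple[int, str, str], ...]:
        return tuple(self._tss.get(contig, ()))

    def positions(self, contig: str) -> np.ndarray:
        return self._positions.get(contig, np.empty(0, dtype=np.int64))


def _parse_gene_id(attributes: str) -> str | None:
    # GTF: gene_id "X"; GFF3: ID=gene-X or gene_id=X
    attributes = attributes.strip()
    if "gene_id" in attributes:
        after = attributes.split("gene_id", 1)[1].lstrip(" =\"")
        for sep in ('"', ";", " "):
            if sep in after:
                after = after.split(sep, 1)[0]
        return after or None
    for token in attributes.split(";"):
        token = token.strip()
        if token.startswith("ID="):
            return token[3:] or None
    return None


def read_tss_index(path: str | Path) -> TssIndex:
    """Build a :class:`TssIndex` from a GTF/GFF2.5/GFF3 annotation.

    ``gene`` features are preferred; if the file has none, ``transcript``
    (or ``mRNA``) features are used instead.  1-based inclusive coordinates
    are converted to the internal 0-based half-open convention.  Features
    without a strand are skipped and counted in ``TssIndex.skipped``.
    """
    cols = [
        "contig", "source", "feature", "start", "end",
        "score", "strand", "frame", "attributes",
    ]
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None, names=cols,
        dtype={"contig": str}, na_filter=False,
    )
    if df.empty:
        return TssIndex([], IntervalSet(), 0)
    feature_types = set(df["feature"])
    if "gene" in feature_types:
        use = df[df["feature"] == "gene"]
    else:
        use = df[df["feature"].isin(["transcript", "mRNA"])]
    tss: list[tuple[str, int, str, str]] = []
    bodies: list[GenomicInterval] = []
    skipped = 0
    for i, row in enumerate(use.itertuples(index=False)):
        strand = row.strand
        if strand not in ("+", "-"):
            skipped += 1
            continue
        start0 = int(row.start) - 1          # 1-based inclusive -> 0-based
        end0 = int(row.end)                  # inclusive end -> half-open end
        gene_id = _parse_gene_id(row.attributes) or f"gene_{i}"
        pos = start0 if strand == "+" else end0 - 1
        tss.append((row.contig, pos, strand, gene_id))
        bodies.append(GenomicInterval(row.contig, start0, end0, strand, gene_id))
    if skipped:
        logger.warning("read_tss_index: skipped %d features without strand", skipped)
    return TssIndex(tss, IntervalSet(bodies), skipped)


# ---------------------------------------------------------------------------
# Interval algebra
# ---------------------------------------------------------------------------


def merge(intervals: IntervalSet, max_gap: int = 0) -> IntervalSet:
    """Merge overlapping/nearby intervals on the same contig.

    Two intervals are joined iff they overlap or the gap between them is
    *strictly* less than ``max_gap`` (so with ``max_gap=150`` a 149 bp gap
    closes and a 150 bp gap does not; with ``max_gap=0`` only genuinely
    overlapping intervals merge and book-ended intervals stay apart).
    Idempotent: the output has pairwise gaps >= ``max_gap``.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be non-negative")
    out: list[GenomicInterval] = []
    for contig in intervals.contigs:
        cur_start = cur_end = None
        for iv in intervals.on_contig(contig):
            if cur_end is None:
                cur_start, cur_end = iv.start, iv.end
            elif iv.start - cur_end < max_gap or iv.start < cur_end:
                cur_end = max(cur_end, iv.end)
            else:
                out.append(GenomicInterval(contig, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        if cur_end is not None:
            out.append(GenomicInterval(contig, cur_start, cur_end))
    return IntervalSet(out)


def intersect(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    """Base-level intersection: every returned base is covered by both sets."""
    out: list[GenomicInterval] = []
    for contig in a.contigs:
        xs = merge(IntervalSet(a.on_contig(contig)), 0)
        ys = merge(IntervalSet(b.on_contig(contig)), 0)
        i = j = 0
        xs_l, ys_l = list(xs), list(ys)
        while i < len(xs_l) and j < len(ys_l):
            lo = max(xs_l[i].start, ys_l[j].start)
            hi = min(xs_l[i].end, ys_l[j].end)
            if lo < hi:
                out.append(GenomicInterval(contig, lo, hi))
            if xs_l[i].end <= ys_l[j].end:
                i += 1
            else:
                j += 1
    return IntervalSet(out)


def union(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    """Base-level union (overlaps collapsed)."""
    return merge(IntervalSet(list(a) + list(b)), 0)


def anti_join(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    """Record-level difference: intervals of ``a`` with zero overlap to ``b``.

    Intervals are kept or dropped whole, never trimmed (bedtools
    ``intersect -v`` semantics).
    """
    out: list[GenomicInterval] = []
    for contig in a.contigs:
        blockers = merge(IntervalSet(b.on_contig(contig)), 0)
        starts = [x.start for x in blockers]
        blocks = list(blockers)
        for iv in a.on_contig(contig):
            # candidate blockers are the one left of iv.end and neighbors
            k = bisect_left(starts, iv.end)
            hit = any(
                blocks[m].start < iv.end and iv.start < blocks[m].end
                for m in range(max(0, k - 1), min(len(blocks), k + 1))
            )
            if not hit:
                out.append(iv)
    return IntervalSet(out)


class ContigNotIndexedError(KeyError):
    """Raised when a nearest-TSS query hits a contig absent from the index."""


def tss_distance(iv: GenomicInterval, index: TssIndex) -> int:
    """Distance in bp from an interval to the nearest TSS on its contig.

    0 if any TSS lies inside the interval; otherwise the gap to the closest
    TSS (``start - tss`` on the left, ``tss - end`` on the right).  Strand
    of gene and interval is ignored.  Raises :class:`ContigNotIndexedError`
    if the contig has no TSS in the index.
    """
    pos = index.positions(iv.contig)
    if pos.size == 0:
        raise ContigNotIndexedError(iv.contig)
    k = int(np.searchsorted(pos, iv.start))
    best = None
    for m in (k - 1, k, int(np.searchsorted(pos, iv.end))):
        if 0 <= m < pos.size:
            p = int(pos[m])
            if iv.start <= p < iv.end:
                return 0
            d = iv.start - p if p < iv.start else p - iv.end
            best = d if best is None else min(best, d)
    return max(best, 0)


# ---------------------------------------------------------------------------
# Sequence extraction
# ---------------------------------------------------------------------------


def extract_sequences(intervals: IntervalSet, genome: str | Path):
    """Extract per-interval sequences from a FASTA file.

    Returns a list of Bio.SeqRecord objects, one per interval, with headers
    ``contig:start-end``.  Minus-strand intervals are reverse-complemented.
    Raises :class:`IndexError` if an interval runs past its contig end and
    :class:`KeyError` if the contig is absent.
    """
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    from pyfaidx import Fasta

    records = []
    with Fasta(str(genome)) as fa:
        for iv in intervals:
            if iv.contig not in fa:
                raise KeyError(f"contig {iv.contig!r} not in genome {genome}")
            if iv.end > len(fa[iv.contig]):
                raise IndexError(
                    f"interval {iv} extends past end of contig "
                    f"({len(fa[iv.contig])} bp)"
                )
            seq = Seq(str(fa[iv.contig][iv.start : iv.end]))
            if iv.strand == "-":
                seq = seq.reverse_complement()
            records.append(
                SeqRecord(seq, id=f"{iv.contig}:{iv.start}-{iv.end}", description="")
            )
    return records
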