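"""Safe-harbor integration-site prediction from histone-modification peaks.

The screen looks for broad intergenic regions that carry the activating
marks H3K4me3 and H3K27ac at both sampled growth phases while being free of
the heterochromatin mark H3K9me3 — the chromatin signature used to nominate
transgene "safe harbors" in CHO cells.  The filter chain:

1. per activating mark, keep regions marked at *both* timepoints;
2. drop peaks overlapping a gene body or closer than ``min_tss_distance``
   to any transcription start site;
3. intersect the surviving regions across all activating marks;
4. remove (whole) regions touching any repressive-mark peak from either
   timepoint;
5. merge neighbors closer than ``merge_max_gap``;
6. discard candidates shorter than ``min_site_length``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from functools import reduce
from pathlib import Path
from typing import Mapping, Sequence

from .intervals import (
    ContigNotIndexedError,
    GenomicInterval,
    IntervalSet,
    TssIndex,
    anti_join,
    extract_sequences,
    intersect,
    merge,
    tss_distance,
    union,
    write_bed,
)

logger = logging.getLogger(__name__)

__all__ = [
    "HarborParams",
    "IntegrationSite",
    "common_peaks",
    "intergenic_filter",
    "identify_sites",
    "export_sites",
]


@dataclass(frozen=True)
class HarborParams:
    """Thresholds of the integration-site screen.

    Defaults are the study conditions: intergenic candidates at least
    5000 bp from the nearest TSS, neighbors within 150 bp merged, and sites
    shorter than 600 bp removed.
    """

    min_tss_distance: int = 5000
    merge_max_gap: int = 150
    min_site_length: int = 600
    require_both_timepoints: bool = True
    activating_marks: tuple[str, ...] = ("H3K4me3", "H3K27ac")
    repressive_marks: tuple[str, ...] = ("H3K9me3",)
    #: keep peaks on contigs without any annotated gene (common on
    #: fragmented assemblies); set False to drop them instead.
    keep_unannotated_contigs: bool = True

    def __post_init__(self) -> None:
        if min(self.min_tss_distance, self.merge_max_gap, self.min_site_length) < 0:
            raise ValueError("distances and lengths must be non-negative")
        if not self.activating_marks:
            raise ValueError("at least one activating mark is required")


@dataclass(frozen=True)
class IntegrationSite:
    """A predicted safe-harbor region with provenance."""

    interval: GenomicInterval
    nearest_tss_distance: float  # bp; inf on contigs without annotation
    contributing_marks: tuple[str, ...]

    @property
    def length(self) -> int:
        return self.interval.length


def common_peaks(peaks_t1: IntervalSet, peaks_t2: IntervalSet) -> IntervalSet:
    """Regions carrying a mark at both timepoints (base-level intersection).

    Stand-in for differential-caller "common peak" output: users holding
    such output can feed it directly and skip this step.
    """
    return intersect(peaks_t1, peaks_t2)


def intergenic_filter(
    peaks: IntervalSet,
    index: TssIndex,
    min_tss_distance: int = 5000,
    keep_unannotated_contigs: bool = True,
) -> IntervalSet:
    """Keep peaks that overlap no gene body and sit >= ``min_tss_distance``
    bp from every TSS.

    Peaks on contigs without annotated genes are kept by default (they
    trivially overlap nothing) with a logged count; pass
    ``keep_unannotated_contigs=False`` to drop them.
    """
    intergenic = anti_join(peaks, index.gene_bodies)
    kept: list[GenomicInterval] = []
    n_unannotated = 0
    for iv in intergenic:
        try:
            d = tss_distance(iv, index)
        except ContigNotIndexedError:
            n_unannotated += 1
            if keep_unannotated_contigs:
                kept.append(iv)
            continue
        if d >= min_tss_distance:
            kept.append(iv)
    if n_unannotated:
        logger.warning(
            "intergenic_filter: %d peaks on contigs without annotation (%s)",
            n_unannotated,
            "kept" if keep_unannotated_contigs else "dropped",
        )
    return IntervalSet(kept)


def identify_sites(
    peaks: Mapping[str, tuple[IntervalSet, IntervalSet]],
    index: TssIndex,
    params: HarborParams = HarborParams(),
) -> list[IntegrationSite]:
    """Run the full screen and return sorted :class:`IntegrationSite` list.

    ``peaks`` maps each mark name to its (timepoint-1, timepoint-2) peak
    sets; every mark named in ``params`` must be present.  An empty result
    is a valid outcome, not an error.
    """
    for mark in (*params.activating_marks, *params.repressive_marks):
        if mark not in peaks:
            raise KeyError(f"no peak sets supplied for mark {mark!r}")

    per_mark: list[IntervalSet] = []
    for mark in params.activating_marks:
        t1, t2 = peaks[mark]
        if params.require_both_timepoints:
            common = common_peaks(t1, t2)
        else:
            common = union(t1, t2)
        filtered = intergenic_filter(
            common, index, params.min_tss_distance, params.keep_unannotated_contigs
        )
        logger.info(
            "%s: %d+%d peaks -> %d common -> %d intergenic",
            mark, len(t1), len(t2), len(common), len(filtered),
        )
        per_mark.append(filtered)

    active = reduce(intersect, per_mark)
    repressive = IntervalSet(
        iv
        for mark in params.repressive_marks
        for ts in peaks[mark]
        for iv in ts
    )
    clean = anti_join(active, repressive)
    merged = merge(clean, params.merge_max_gap)
    sites: list[IntegrationSite] = []
    for iv in merged:
        if iv.length < params.min_site_length:
            continue
        try:
            d: float = tss_distance(iv, index)
        except ContigNotIndexedError:
            d = math.inf
        sites.append(
            IntegrationSite(iv, d, tuple(params.activating_marks))
        )
    logger.info(
        "identify_sites: %d active ∩ -> %d after anti-join -> %d merged -> %d sites",
        len(active), len(clean), len(merged), len(sites),
    )
    return sites


def export_sites(
    sites: Sequence[IntegrationSite],
    bed_path: str | Path,
    fasta_path: str | Path | None = None,
    genome: str | Path | None = None,
) -> None:
    """Write predicted sites as BED and, if a genome is given, as FASTA."""
    named = IntervalSet(
        GenomicInterval(
            s.interval.contig,
            s.interval.start,
            s.interval.end,
            name=f"site_{i + 1}",
        )
        for i, s in enumerate(sites)
    )
    write_bed(named, bed_path)
    if fasta_path is not None:
        if genome is None:
            raise ValueError("fasta_path given without a genome FASTA")
        from Bio import SeqIO

        records = extract_sequences(named, genome)
        SeqIO.write(records, str(fasta_path), "fasta")
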