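"""Shared fixtures and independent brute-force oracles."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from safeharbor.intervals import GenomicInterval, IntervalSet

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


# ---------------------------------------------------------------------------
# Per-base brute-force oracles, kept deliberately independent of the
# sweep-based implementations they check.
# ---------------------------------------------------------------------------


def cover_mask(intervals, contig: str, length: int) -> np.ndarray:
    """Boolean per-base coverage mask of one contig."""
    mask = np.zeros(length, dtype=bool)
    for iv in intervals:
        if iv.contig == contig:
            mask[iv.start : iv.end] = True
    return mask


def mask_to_intervals(mask: np.ndarray, contig: str) -> list[tuple[str, int, int]]:
    """Maximal runs of True in a mask, as (contig, start, end) tuples."""
    out = []
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    for i in range(0, edges.size, 2):
        out.append((contig, int(edges[i]), int(edges[i + 1])))
    return out


def coords(intervals) -> list[tuple[str, int, int]]:
    return [(iv.contig, iv.start, iv.end) for iv in intervals]


def brute_force_merge(
    intervals: IntervalSet, max_gap: int
) -> list[tuple[str, int, int]]:
    """Fixpoint pairwise merging: join any two intervals on one contig that
    overlap or whose gap is strictly below ``max_gap``, until stable."""
    spans = [[iv.contig, iv.start, iv.end] for iv in intervals]
    changed = True
    while changed:
        changed = False
        for i in range(len(spans)):
            for j in range(i + 1, len(spans)):
                a, b = spans[i], spans[j]
                if a[0] != b[0]:
                    continue
                gap = max(a[1], b[1]) - min(a[2], b[2])
                if gap < max_gap or (a[1] < b[2] and b[1] < a[2]):
                    spans[i] = [a[0], min(a[1], b[1]), max(a[2], b[2])]
                    del spans[j]
                    changed = True
                    break
            if changed:
                break
    return sorted((c, s, e) for c, s, e in spans)


def random_interval_set(
    rng: np.random.Generator,
    n: int,
    contig: str = "c",
    length: int = 100_000,
    max_width: int = 5_000,
) -> IntervalSet:
    starts = rng.integers(0, length - 1, size=n)
    widths = rng.integers(1, max_width, size=n)
    return IntervalSet(
        GenomicInterval(contig, int(s), int(min(s + w, length)))
        for s, w in zip(starts, widths)
        if s < min(s + w, length)
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260927)
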