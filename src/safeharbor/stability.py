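"""Long-term transgene expression stability metrics.

Expression is tracked as fluorescence normalized to relative gene copy
number, ``NF(t) = F(t) / GCN(t)``, which separates epigenetic silencing
(falling F at constant copies) from copy loss (falling copies).  Retention
is ``R(t) = NF(t) / NF(0)``.  Elapsed generations are accumulated from
piecewise-constant specific growth rates, ``g = sum(dt * mu) / ln 2``, and
a pool is called stable when it retains at least 70% of its initial
normalized expression over at least 70 generations (both bounds
inclusive).  The mPlum:eGFP fluorescence ratio is a quick indicator of
integration type: the donor's mPlum cassette sits outside the homology
arms, so site-specific knock-ins carry eGFP only (ratio well below 1)
while random vector integrations carry both (ratio near 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MuWindow",
    "StabilitySeries",
    "StabilityVerdict",
    "normalized_fluorescence",
    "generations",
    "stability_verdict",
    "mplum_egfp_ratio",
    "read_series_csv",
]

LN2 = math.log(2.0)


@dataclass(frozen=True)
class MuWindow:
    """A specific-growth-rate assessment window [start_day, end_day)."""

    start_day: float
    end_day: float
    mu: float  # per day

    def __post_init__(self) -> None:
        if not self.start_day < self.end_day:
            raise ValueError("mu window must have start_day < end_day")
        if self.mu <= 0:
            raise ValueError("growth rate mu must be positive")


@dataclass
class StabilitySeries:
    """Per-pool long-term culture measurements.

    ``fluorescence`` and ``gene_copies`` are background-corrected eGFP
    signal and relative transgene copy number at each timepoint (days,
    first must be 0).  Optional SD arrays enable first-order error
    propagation onto retention; the optional mPlum channel feeds the
    integration-type ratio.
    """

    pool: str
    condition: str  # "with selection" | "without selection"
    days: np.ndarray
    fluorescence: np.ndarray
    gene_copies: np.ndarray
    mu_windows: tuple[MuWindow, ...] = ()
    mplum: np.ndarray | None = None
    fluorescence_sd: np.ndarray | None = None
    gene_copies_sd: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        self.gene_copies = np.asarray(self.gene_copies, dtype=float)
        if self.days.size < 2 or self.days[0] != 0 or np.any(np.diff(self.days) <= 0):
            raise ValueError(
                f"pool {self.pool}: timepoints must start at 0 and strictly increase"
            )
        if self.fluorescence.size != self.days.size:
            raise ValueError(f"pool {self.pool}: fluorescence/timepoint length mismatch")
        if self.gene_copies.size != self.days.size:
            missing = np.setdiff1d(
                np.arange(self.days.size), np.arange(self.gene_copies.size)
            )
            raise ValueError(
                f"pool {self.pool}: missing gene copy number at timepoint "
                f"index {missing.tolist()}"
            )
        if np.any(self.fluorescence <= 0) or np.any(self.gene_copies <= 0):
            raise ValueError(f"pool {self.pool}: fluorescence and copies must be > 0")


@dataclass
class StabilityVerdict:
    pool: str
    condition: str
    retention_end: float
    generations: float
    stable: bool
    retention_series: np.ndarray
    retention_sd: np.ndarray | None = None


def normalized_fluorescence(series: StabilitySeries) -> np.ndarray:
    """Retention R(t) = (F(t)/GCN(t)) / (F(0)/GCN(0)); R(0) = 1.

    Invariant to rescaling either the fluorescence or the copy-number
    units.
    """
    nf = series.fluorescence / series.gene_copies
    return nf / nf[0]


def retention_sd(series: StabilitySeries) -> np.ndarray | None:
    """First-order error propagation of measurement SDs onto R(t).

    Relative variances of F(t), F(0), GCN(t), GCN(0) add; returns ``None``
    when the series carries no SDs.
    """
    if series.fluorescence_sd is None and series.gene_copies_sd is None:
        return None
    r = normalized_fluorescence(series)
    rel_var = np.zeros_like(r)
    for values, sds in (
        (series.fluorescence, series.fluorescence_sd),
        (series.gene_copies, series.gene_copies_sd),
    ):
        if sds is None:
            continue
        sds = np.asarray(sds, dtype=float)
        rel = (sds / values) ** 2
        rel_var += rel + rel[0]
    rel_var[0] = 0.0  # R(0) is identically 1
    return r * np.sqrt(rel_var)


def generations(days: float, mu_windows: Sequence[MuWindow]) -> float:
    """Population doublings over ``days`` from piecewise-constant rates.

    ``g = sum over windows of dt * mu / ln 2``; the windows must tile
    [0, days] without gaps (overlap-free coverage).
    """
    if days <= 0:
        raise ValueError("days must be positive")
    windows = sorted(mu_windows, key=lambda w: w.start_day)
    if not windows or windows[0].start_day > 0:
        raise ValueError("growth-rate windows do not cover day 0")
    total = 0.0
    covered = 0.0
    for w in windows:
        if w.start_day > covered:
            raise ValueError(
                f"gap in growth-rate coverage at day {covered:g}..{w.start_day:g}"
            )
        lo = max(w.start_day, covered)
        hi = min(w.end_day, days)
        if hi > lo:
            total += (hi - lo) * w.mu
        covered = max(covered, w.end_day)
        if covered >= days:
            break
    if covered < days:
        raise ValueError(f"growth-rate windows end at day {covered:g} < {days:g}")
    return total / LN2


def stability_verdict(
    series: StabilitySeries,
    retention_threshold: float = 0.70,
    generation_threshold: float = 70.0,
    strict_monotone: bool = False,
) -> StabilityVerdict:
    """Apply the 70%-over-70-generations stability criterion.

    The verdict uses retention at the *last* timepoint; intermediate dips
    do not fail the call unless ``strict_monotone`` is set, in which case
    every timepoint must clear the threshold.  Both bounds are inclusive:
    retention exactly at the threshold over exactly the threshold number
    of generations counts as stable.
    """
    r = normalized_fluorescence(series)
    g = generations(float(series.days[-1]), series.mu_windows)
    meets_retention = (
        bool(np.all(r >= retention_threshold))
        if strict_monotone
        else bool(r[-1] >= retention_threshold)
    )
    return StabilityVerdict(
        pool=series.pool,
        condition=series.condition,
        retention_end=float(r[-1]),
        generations=g,
        stable=meets_retention and g >= generation_threshold,
        retention_series=r,
        retention_sd=retention_sd(series),
    )


def mplum_egfp_ratio(mplum_signal: float, egfp_signal: float) -> float:
    """mPlum:eGFP fluorescence ratio (autofluorescence-corrected inputs).

    Ratios well below 1 (about 0.05-0.2 in practice) indicate predominantly
    site-specific integration; ratios near 1 indicate random vector
    integration.  This is guidance, not a hard classification.
    """
    if egfp_signal <= 0:
        raise ValueError("eGFP signal must be positive")
    if mplum_signal < 0:
        raise ValueError("mPlum signal must be non-negative")
    return mplum_signal / egfp_signal


def read_series_csv(path) -> list[StabilitySeries]:
    """Read long-format stability CSV.

    Columns: pool, condition, day, egfp_fluor, gene_copies and optionally
    mplum_fluor, mu (specific growth rate for the window *starting* at
    that day; the last value extends to the final day).
    """
    df = pd.read_csv(path)
    required = {"pool", "condition", "day", "egfp_fluor", "gene_copies"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: need columns {sorted(required)}")
    out = []
    for (pool, condition), grp in df.groupby(["pool", "condition"], sort=False):
        grp = grp.sort_values("day")
        days = grp["day"].to_numpy(dtype=float)
        windows: tuple[MuWindow, ...] = ()
        if "mu" in grp.columns and grp["mu"].notna().all():
            mus = grp["mu"].to_numpy(dtype=float)
            windows = tuple(
                MuWindow(days[i], days[i + 1], mus[i])
                for i in range(days.size - 1)
            )
        out.append(
            StabilitySeries(
                pool=str(pool),
                condition=str(condition),
                days=days,
                fluorescence=grp["egfp_fluor"].to_numpy(dtype=float),
                gene_copies=grp["gene_copies"].to_numpy(dtype=float),
                mu_windows=windows,
                mplum=(
                    grp["mplum_fluor"].to_numpy(dtype=float)
                    if "mplum_fluor" in grp.columns
                    else None
                ),
            )
        )
    return out
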