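"""qPCR crossing-point calling and relative quantification.

CP (crossing point) values are called by the second-derivative-maximum
method: the amplification curve is smoothed with a local quadratic
polynomial (Savitzky–Golay), the discrete second difference is taken, and
its maximum — refined to sub-cycle precision by quadratic interpolation —
is the CP.  For a logistic amplification curve with inflection c0 the SDM
lies at ``c0 - ln(2 + sqrt(3))`` (about 1.32 cycles before inflection).

Relative quantities follow the efficiency model ``E**(CP_ref - CP_target)``
with a dual-reference design: each target replicate is paired with the mean
reference CP per reference gene ("all to mean"), every ratio is normalized
to an inter-run calibrator, and the mean and SD over
{replicates x references} are reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

__all__ = [
    "AmplificationCurve",
    "QuantResult",
    "SDM_OFFSET",
    "call_cp_sdm",
    "relative_quantity",
    "normalize_to_calibrator",
    "quantify",
    "quantify_from_cp_table",
    "cp_table",
    "read_curves_csv",
    "read_cp_table",
]

#: cycles between a logistic curve's inflection point and its
#: second-derivative maximum: ln(2 + sqrt(3))
SDM_OFFSET = math.log(2.0 + math.sqrt(3.0))

ROLES = ("target", "reference", "calibrator-target", "calibrator-reference")


@dataclass
class AmplificationCurve:
    """Fluorescence-vs-cycle series for one well (cycle 1..C)."""

    well: str
    sample: str
    gene: str
    role: str
    fluorescence: np.ndarray

    def __post_init__(self) -> None:
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.fluorescence.size < 15:
            raise ValueError(f"well {self.well}: need >= 15 cycles")
        if not np.all(np.isfinite(self.fluorescence)):
            raise ValueError(f"well {self.well}: non-finite fluorescence")
        if self.role not in ROLES:
            raise ValueError(f"well {self.well}: bad role {self.role!r}")


@dataclass
class QuantResult:
    """Calibrator-normalized relative quantity for one sample x target."""

    sample: str
    target: str
    relative_amount: float
    sd: float
    per_reference: dict[str, float]  # mean normalized ratio per reference gene
    cp_means: dict[str, float]  # mean CP per gene for this sample


def call_cp_sdm(
    curve: AmplificationCurve | np.ndarray | Sequence[float],
    smooth_window: int = 5,
) -> float | None:
    """Crossing point by the second-derivative-maximum method.

    Returns the CP in cycle units (cycle 1 is the first measurement), or
    ``None`` for curves with no amplification signal (flat or linear
    drift).  Ties in the discrete maximum break toward the earliest cycle.
    Translation-equivariant and invariant to positive rescaling of the
    fluorescence axis.
    """
    f = np.asarray(
        curve.fluorescence if isinstance(curve, AmplificationCurve) else curve,
        dtype=float,
    )
    if smooth_window % 2 == 0 or smooth_window < 3:
        raise ValueError("smooth_window must be an odd integer >= 3")
    if smooth_window >= f.size:
        raise ValueError("smooth_window must be smaller than the cycle count")
    rng = float(f.max() - f.min())
    if rng <= 1e-9 * max(1.0, float(np.abs(f).max())):
        return None  # flat line: no amplification
    # robust per-cycle noise estimate from the second differences (the
    # sigmoid contributes to only a few of them; the median ignores those)
    d2_raw = np.diff(f, 2)
    sigma = float(
        np.median(np.abs(d2_raw - np.median(d2_raw))) / (0.6745 * math.sqrt(6.0))
    )
    if sigma > 0.01 * rng:  # visibly noisy: pre-smooth before the spline fit
        f = savgol_filter(f, smooth_window, polyorder=2)
    # quintic smoothing spline, residual budget matched to the noise level;
    # for a clean curve this interpolates and the second-derivative maximum
    # is essentially exact
    from scipy.interpolate import UnivariateSpline

    cycles = np.arange(1, f.size + 1, dtype=float)
    s_budget = 0.0 if sigma <= 1e-9 * rng else f.size * sigma**2
    spline = UnivariateSpline(cycles, f, k=5, s=s_budget)
    fine = np.linspace(cycles[1], cycles[-2], 40 * (f.size - 2) * 25 + 1)
    d2 = spline.derivative(2)(fine)
    j = int(np.argmax(d2))  # first maximum: ties break toward earliest cycle
    if d2[j] <= 1e-6 * rng:
        return None  # monotone drift without an amplification upswing
    return float(fine[j])


def relative_quantity(
    cp_target: float | None, cp_reference: float | None, efficiency: float = 2.0
) -> float | None:
    """Efficiency-model ratio ``E**(CP_ref - CP_target)``.

    ``None`` CPs (no amplification) propagate to ``None``.
    """
    if efficiency <= 1.0:
        raise ValueError("amplification efficiency must be > 1")
    if cp_target is None or cp_reference is None:
        return None
    return float(efficiency ** (cp_reference - cp_target))


def normalize_to_calibrator(sample_ratio: float, calibrator_ratio: float) -> float:
    """Divide by the inter-run calibrator ratio to cancel run offsets."""
    if calibrator_ratio <= 0:
        raise ValueError("calibrator ratio must be positive")
    return sample_ratio / calibrator_ratio


def cp_table(
    curves: Iterable[AmplificationCurve], smooth_window: int = 5
) -> pd.DataFrame:
    """Call CPs for every curve; long-format (well, sample, gene, role, cp).

    Wells without amplification get NaN CPs.
    """
    rows = []
    for c in curves:
        cp = call_cp_sdm(c, smooth_window)
        rows.append((c.well, c.sample, c.gene, c.role, np.nan if cp is None else cp))
    return pd.DataFrame(rows, columns=["well", "sample", "gene", "role", "cp"])


def quantify_from_cp_table(
    cps: pd.DataFrame,
    target: str,
    references: Sequence[str],
    efficiency: float = 2.0,
    calibrator: str = "CAL",
    max_cp_spread: float = 1.0,
) -> list[QuantResult]:
    """Relative quantification from a pre-called CP table.

    ``cps`` needs columns (sample, gene, cp).  Per sample and reference
    gene, each target-replicate CP is paired with the *mean* reference CP;
    the resulting ratios are normalized to the calibrator sample's ratios
    (computed identically) and pooled over {replicates x references} for
    the mean and SD.  A replicate CP spread above ``max_cp_spread`` cycles
    is logged, never removed.
    """
    import logging

    logger = logging.getLogger(__name__)
    required = {"sample", "gene", "cp"}
    if not required <= set(cps.columns):
        raise ValueError(f"CP table needs columns {sorted(required)}")
    cps = cps.dropna(subset=["cp"])

    def reps(sample: str, gene: str) -> np.ndarray:
        vals = cps.loc[(cps["sample"] == sample) & (cps["gene"] == gene), "cp"]
        return vals.to_numpy(dtype=float)

    samples = [s for s in cps["sample"].unique() if s != calibrator]
    if calibrator not in set(cps["sample"]):
        raise ValueError(f"calibrator sample {calibrator!r} absent from CP table")

    # calibrator ratio per reference gene
    cal_ratio: dict[str, float] = {}
    for ref in references:
        cal_refs = reps(calibrator, ref)
        cal_targets = reps(calibrator, target)
        if cal_refs.size == 0 or cal_targets.size == 0:
            raise ValueError(
                f"calibrator {calibrator!r} missing gene "
                f"{ref if cal_refs.size == 0 else target!r}"
            )
        cal_ratio[ref] = float(
            np.mean(
                [relative_quantity(cp, float(cal_refs.mean()), efficiency)
                 for cp in cal_targets]
            )
        )

    results: list[QuantResult] = []
    for sample in samples:
        target_reps = reps(sample, target)
        if target_reps.size == 0:
            raise ValueError(f"sample {sample!r}: no CPs for target {target!r}")
        if target_reps.size > 1 and np.ptp(target_reps) > max_cp_spread:
            logger.warning(
                "sample %s gene %s: replicate CP spread %.2f cycles",
                sample, target, np.ptp(target_reps),
            )
        pooled: list[float] = []
        per_ref: dict[str, float] = {}
        cp_means: dict[str, float] = {target: float(target_reps.mean())}
        for ref in references:
            ref_reps = reps(sample, ref)
            if ref_reps.size == 0:
                raise ValueError(
                    f"sample {sample!r}: reference gene {ref!r} entirely missing"
                )
            ref_mean = float(ref_reps.mean())
            cp_means[ref] = ref_mean
            ratios = [
                normalize_to_calibrator(
                    relative_quantity(cp, ref_mean, efficiency), cal_ratio[ref]
                )
                for cp in target_reps
            ]
            per_ref[ref] = float(np.mean(ratios))
            pooled.extend(ratios)
        arr = np.asarray(pooled)
        results.append(
            QuantResult(
                sample=sample,
                target=target,
                relative_amount=float(arr.mean()),
                sd=float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
                per_reference=per_ref,
                cp_means=cp_means,
            )
        )
    return results


def quantify(
    curves: Iterable[AmplificationCurve],
    target: str,
    references: Sequence[str],
    efficiency: float = 2.0,
    calibrator: str = "CAL",
    smooth_window: int = 5,
) -> list[QuantResult]:
    """CP calling plus relative quantification in one step."""
    return quantify_from_cp_table(
        cp_table(curves, smooth_window), target, references, efficiency, calibrator
    )


# ---------------------------------------------------------------------------
# CSV IO
# ---------------------------------------------------------------------------


def read_curves_csv(path: str | Path) -> list[AmplificationCurve]:
    """Read long-format curves CSV: well, sample, gene, role, cycle, fluorescence."""
    df = pd.read_csv(path)
    required = {"well", "sample", "gene", "role", "cycle", "fluorescence"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: need columns {sorted(required)}")
    curves = []
    for (well, sample, gene, role), grp in df.groupby(
        ["well", "sample", "gene", "role"], sort=False
    ):
        grp = grp.sort_values("cycle")
        cycles = grp["cycle"].to_numpy()
        if not np.array_equal(cycles, np.arange(1, cycles.size + 1)):
            raise ValueError(f"{path}: well {well}: cycles must run 1..C")
        curves.append(
            AmplificationCurve(
                str(well), str(sample), str(gene), str(role),
                grp["fluorescence"].to_numpy(dtype=float),
            )
        )
    return curves


def read_cp_table(path: str | Path) -> pd.DataFrame:
    """Read a pre-called CP CSV with columns (sample, gene, role, cp)."""
    df = pd.read_csv(path)
    if not {"sample", "gene", "cp"} <= set(df.columns):
        raise ValueError(f"{path}: need columns sample, gene, cp")
    return df
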