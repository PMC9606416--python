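"""Ground-truth synthetic data for every pipeline stage.

Each generator emulates the statistical structure its downstream analysis
assumes, with the truth recorded alongside:

* :func:`plant_harbors` — per-mark/per-timepoint peak sets over a toy
  annotated genome with planted harbor regions plus decoys that each
  violate exactly one screening criterion;
* :func:`simulate_targeted_reads` — targeted Cas9 alignment records at a
  known integration specificity with positional offsets and deliberately
  filterable alignments;
* :func:`simulate_qpcr_plate` — logistic amplification curves encoding
  known copy-number ratios, with replicate CP noise and an optional
  inter-run shift;
* :func:`simulate_stability` — exponential-silencing fluorescence series
  with known retention and the ramping growth rates seen in long-term CHO
  culture.

One scenario seed fans out to independent per-generator streams, so adding
or re-running one generator never perturbs another's output.  Fixing the
seed fixes every output byte-for-byte.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .harbor import HarborParams
from .intervals import GenomicInterval, IntervalSet, TssIndex, write_bed
from .qpcr import SDM_OFFSET, AmplificationCurve
from .reads import ReadAlignmentRecord, TargetedReadSet, write_alignment_tsv
from .stability import MuWindow, StabilitySeries

__all__ = [
    "SimScenario",
    "GenerationError",
    "PlantedHarborData",
    "plant_harbors",
    "simulate_targeted_reads",
    "simulate_qpcr_plate",
    "simulate_stability",
    "write_gtf",
]

_BLOCK = 20_000  # toy-genome layout unit: genes in even blocks, features in odd


class GenerationError(RuntimeError):
    """Infeasible scenario (e.g. genome too small for the requested features)."""


@dataclass
class SimScenario:
    """Study conditions for the synthetic generators.

    Defaults mirror the study scale where it is stated (5 kb TSS exclusion,
    150 bp merge gap, 600 bp minimum width, 2600–3900 bp harbor widths,
    ~5 kb mean read length with ~12.6 kb targeted reads, observed
    specificities around 0.23–0.73, 40-cycle qPCR with triplicates, 49-day
    cultures with growth rates ramping 0.90 to 1.05 per day) and otherwise
    use a desk-scale toy genome of 3 x 1 Mb contigs with 50 genes each.
    """

    seed: int = 0

    # --- toy genome / harbor planting -------------------------------------
    contig_lengths: dict[str, int] = field(
        default_factory=lambda: {f"contig_{i}": 1_000_000 for i in (1, 2, 3)}
    )
    genes_per_contig: int = 50
    gene_width_range: tuple[int, int] = (2_000, 8_000)
    n_harbors: int = 20
    harbor_width_range: tuple[int, int] = (2_600, 3_900)
    n_gene_proximal_decoys: int = 20
    n_repressive_decoys: int = 20
    n_short_decoys: int = 20
    short_decoy_width_range: tuple[int, int] = (300, 599)
    harbor_params: HarborParams = field(default_factory=HarborParams)

    # --- targeted-read model ----------------------------------------------
    n_reads: int = 2_000
    true_specificity: float = 0.73
    offset_sd: float = 300.0
    tolerance: int = 1_000
    frac_filtered: float = 0.05
    n_untargeted_reads: int = 200
    mean_read_length: int = 12_600
    mean_background_read_length: int = 5_000
    gene_copies: float = 1.0
    site: GenomicInterval = field(
        default_factory=lambda: GenomicInterval("contig_1", 500_000, 503_000)
    )

    # --- qPCR plate model --------------------------------------------------
    true_ratios: tuple[float, ...] = (0.5, 1.0, 2.0, 4.0, 8.0)
    efficiency: float = 2.0
    cp_noise_sd: float = 0.1
    fluor_noise_sd: float = 0.0
    n_replicates: int = 3
    n_cycles: int = 40
    target_gene: str = "eGFP"
    reference_cps: dict[str, float] = field(
        default_factory=lambda: {"GAPDH": 18.0, "B2m": 20.0}
    )
    base_target_cp: float = 24.0
    calibrator_sample: str = "CAL"
    inter_run_shift: float | None = None

    # --- stability model ---------------------------------------------------
    pool_retention: dict[str, float] = field(
        default_factory=lambda: {
            "Pool-A": 0.97,
            "Pool-B": 0.26,
            "Pool-C": 0.72,
            "Random": 0.40,
        }
    )
    stability_days: tuple[float, ...] = (0.0, 21.0, 49.0)
    mu_start: float = 0.90
    mu_end: float = 1.05
    stability_noise_sd: float = 0.0
    base_fluorescence: float = 100.0
    base_gene_copies: float = 2.0
    #: optional per-pool multiplicative copy-number change at the final
    #: timepoint, to emulate copy loss instead of silencing
    gcn_end_factor: dict[str, float] = field(default_factory=dict)

    def _streams(self) -> list[np.random.Generator]:
        return [
            np.random.default_rng(s)
            for s in np.random.SeedSequence(self.seed).spawn(4)
        ]

    def rng_harbors(self) -> np.random.Generator:
        return self._streams()[0]

    def rng_reads(self) -> np.random.Generator:
        return self._streams()[1]

    def rng_qpcr(self) -> np.random.Generator:
        return self._streams()[2]

    def rng_stability(self) -> np.random.Generator:
        return self._streams()[3]


# ---------------------------------------------------------------------------
# Harbor planting
# ---------------------------------------------------------------------------


@dataclass
class PlantedHarborData:
    """Peak sets, annotation and truth for one planted-harbor scenario."""

    peaks: dict[str, tuple[IntervalSet, IntervalSet]]
    tss_index: TssIndex
    genes: IntervalSet
    truth: IntervalSet
    contig_lengths: dict[str, int]
    decoys: dict[str, IntervalSet]

    def write(self, outdir: str | Path, genome_rng: np.random.Generator | None = None) -> None:
        """Write BEDs, GTF and truth BED (plus a random-sequence FASTA when
        a generator is supplied) under ``outdir``."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for mark, (t1, t2) in self.peaks.items():
            write_bed(t1, outdir / f"{mark}_t1.bed")
            write_bed(t2, outdir / f"{mark}_t2.bed")
        write_gtf(self.genes, outdir / "genes.gtf")
        write_bed(self.truth, outdir / "truth_sites.bed")
        if genome_rng is not None:
            alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
            with open(outdir / "genome.fa", "w") as fh:
                for contig, length in self.contig_lengths.items():
                    seq = alphabet[genome_rng.integers(0, 4, size=length)]
                    fh.write(f">{contig}\n")
                    raw = seq.tobytes().decode()
                    for i in range(0, length, 80):
                        fh.write(raw[i : i + 80] + "\n")


def write_gtf(genes: IntervalSet, path: str | Path) -> None:
    """Write gene features as GTF (converting to 1-based inclusive)."""
    with open(path, "w") as fh:
        for iv in genes:
            gene_id = iv.name or f"{iv.contig}_{iv.start}"
            fh.write(
                f"{iv.contig}\tsim\tgene\t{iv.start + 1}\t{iv.end}\t.\t"
                f"{iv.strand}\t.\tgene_id \"{gene_id}\";\n"
            )


def plant_harbors(scenario: SimScenario) -> PlantedHarborData:
    """Generate peak sets with planted harbors and single-violation decoys.

    The toy genome is tiled in 20 kb blocks: even blocks carry two genes
    each, odd blocks carry at most one intergenic feature placed >= 6 kb
    from the block edges, which guarantees every intergenic feature sits
    beyond the TSS-distance threshold by construction.  Decoy classes:
    gene-proximal activating peaks (fail the intergenic filter),
    repressive-overlapped regions (fail the anti-join), and sub-minimum
    fragments (fail the length filter).  The truth set is exactly the
    expected :func:`safeharbor.harbor.identify_sites` output.
    """
    rng = scenario.rng_harbors()
    p = scenario.harbor_params
    lo_w, hi_w = scenario.harbor_width_range
    if lo_w < p.min_site_length:
        raise GenerationError("harbor widths must be >= min_site_length")

    # -- genes: two per even block ------------------------------------------
    genes: list[GenomicInterval] = []
    for contig, length in scenario.contig_lengths.items():
        n_blocks = length // _BLOCK
        even_blocks = [b * _BLOCK for b in range(0, n_blocks, 2)]
        needed_blocks = -(-scenario.genes_per_contig // 2)
        if needed_blocks > len(even_blocks):
            raise GenerationError(
                f"contig {contig} too small for {scenario.genes_per_contig} genes"
            )
        count = 0
        for s in even_blocks:
            for slot in (1_000, 11_000):
                if count >= scenario.genes_per_contig:
                    break
                start = s + slot + int(rng.integers(0, 1_000))
                width = int(rng.integers(*scenario.gene_width_range, endpoint=True))
                strand = "+" if rng.random() < 0.5 else "-"
                count += 1
                genes.append(
                    GenomicInterval(
                        contig, start, start + width, strand,
                        name=f"gene_{contig}_{count:03d}",
                    )
                )
    gene_set = IntervalSet(genes)
    tss_index = TssIndex(
        [
            (g.contig, g.start if g.strand == "+" else g.end - 1, g.strand, g.name)
            for g in genes
        ],
        gene_set,
    )

    # -- intergenic feature slots: odd blocks -------------------------------
    slots: list[tuple[str, int]] = []
    for contig, length in scenario.contig_lengths.items():
        n_blocks = length // _BLOCK
        slots.extend((contig, b * _BLOCK) for b in range(1, n_blocks, 2))
    n_features = (
        scenario.n_harbors + scenario.n_repressive_decoys + scenario.n_short_decoys
    )
    if n_features > len(slots):
        raise GenerationError(
            f"genome too small: {n_features} intergenic features requested "
            f"but only {len(slots)} slots available"
        )
    order = rng.permutation(len(slots))

    def place(slot: tuple[str, int], width: int) -> GenomicInterval:
        contig, s = slot
        margin = 6_000
        start = s + margin + int(rng.integers(0, _BLOCK - 2 * margin - width + 1))
        return GenomicInterval(contig, start, start + width)

    harbors: list[GenomicInterval] = []
    repressive_decoys: list[GenomicInterval] = []
    short_decoys: list[GenomicInterval] = []
    k = 0
    for _ in range(scenario.n_harbors):
        harbors.append(place(slots[order[k]], int(rng.integers(lo_w, hi_w, endpoint=True))))
        k += 1
    for _ in range(scenario.n_repressive_decoys):
        repressive_decoys.append(
            place(slots[order[k]], int(rng.integers(p.min_site_length, hi_w, endpoint=True)))
        )
        k += 1
    for _ in range(scenario.n_short_decoys):
        short_decoys.append(
            place(
                slots[order[k]],
                int(rng.integers(*scenario.short_decoy_width_range, endpoint=True)),
            )
        )
        k += 1

    # -- gene-proximal decoys: activating peaks straddling a gene start -----
    gene_proximal: list[GenomicInterval] = []
    if scenario.n_gene_proximal_decoys:
        if scenario.n_gene_proximal_decoys > len(genes):
            raise GenerationError("more gene-proximal decoys than genes")
        pick = rng.choice(len(genes), size=scenario.n_gene_proximal_decoys, replace=False)
        for gi in pick:
            g = genes[int(gi)]
            start = max(0, g.start - 500)
            gene_proximal.append(GenomicInterval(g.contig, start, g.start + 1_000))

    # -- assemble peak sets ---------------------------------------------------
    activating_material = harbors + repressive_decoys + short_decoys + gene_proximal
    repressive_t1: list[GenomicInterval] = []
    repressive_t2: list[GenomicInterval] = []
    for i, dec in enumerate(repressive_decoys):
        overlap = 1 if i % 2 == 0 else int(rng.integers(1, min(200, dec.length) + 1))
        k9 = GenomicInterval(dec.contig, dec.end - overlap, dec.end - overlap + 300)
        (repressive_t1 if i % 2 == 0 else repressive_t2).append(k9)

    peaks: dict[str, tuple[IntervalSet, IntervalSet]] = {}
    for mark in p.activating_marks:
        peaks[mark] = (
            IntervalSet(activating_material),
            IntervalSet(activating_material),
        )
    for mark in p.repressive_marks:
        peaks[mark] = (IntervalSet(repressive_t1), IntervalSet(repressive_t2))

    truth = IntervalSet(harbors)
    data = PlantedHarborData(
        peaks=peaks,
        tss_index=tss_index,
        genes=gene_set,
        truth=truth,
        contig_lengths=dict(scenario.contig_lengths),
        decoys={
            "gene_proximal": IntervalSet(gene_proximal),
            "repressive_overlapped": IntervalSet(repressive_decoys),
            "sub_minimum": IntervalSet(short_decoys),
        },
    )
    _self_check_harbors(data, scenario)
    return data


def _self_check_harbors(data: PlantedHarborData, scenario: SimScenario) -> None:
    """Post-generation validation of the scenario invariants."""
    from .intervals import tss_distance

    p = scenario.harbor_params
    prev: GenomicInterval | None = None
    for h in data.truth:
        if h.length < p.min_site_length:
            raise GenerationError(f"planted harbor {h} shorter than minimum")
        if tss_distance(h, data.tss_index) < p.min_tss_distance:
            raise GenerationError(f"planted harbor {h} too close to a TSS")
        if prev is not None and prev.contig == h.contig and h.start - prev.end < max(
            p.merge_max_gap, 1
        ):
            raise GenerationError(f"planted harbors {prev} and {h} too close")
        prev = h


# ---------------------------------------------------------------------------
# Targeted reads
# ---------------------------------------------------------------------------


def simulate_targeted_reads(
    scenario: SimScenario,
) -> tuple[TargetedReadSet, pd.DataFrame]:
    """Simulate one pool's targeted Cas9 alignment records with truth labels.

    Each transgene-bearing read is site-specific with probability
    ``true_specificity``; site-specific genomic starts are offset from the
    intended site by N(0, offset_sd) truncated inside the tolerance window,
    random reads land uniformly outside it.  A ``frac_filtered`` fraction
    get MAPQ < 20 or a supplementary flag (truth label "unclassifiable");
    untargeted background reads carry genome-only alignments (truth
    "untargeted").  Truth columns: read_id, truth_label.
    """
    if not 0.0 <= scenario.true_specificity <= 1.0:
        raise ValueError("true_specificity must lie in [0, 1]")
    rng = scenario.rng_reads()
    site = scenario.site
    tol = scenario.tolerance
    contigs = list(scenario.contig_lengths)
    lengths = scenario.contig_lengths

    transgene: list[ReadAlignmentRecord] = []
    genomic: list[ReadAlignmentRecord] = []
    truth_rows: list[tuple[str, str]] = []
    total_bases = 0

    def read_len(mean: int) -> int:
        # lognormal with ~40% CV, floored at 500 bp
        mu = math.log(mean) - 0.5 * 0.385**2
        return max(500, int(rng.lognormal(mu, 0.385)))

    def random_start(length: int) -> tuple[str, int]:
        while True:
            contig = contigs[int(rng.integers(len(contigs)))]
            start = int(rng.integers(0, max(1, lengths[contig] - length)))
            if contig != site.contig:
                return contig, start
            if start + length <= site.start - tol or start >= site.end + tol:
                return contig, start

    for i in range(scenario.n_reads):
        rid = f"read_{i:05d}"
        rl = read_len(scenario.mean_read_length)
        total_bases += rl
        transgene.append(
            ReadAlignmentRecord(rid, "eGFP", 0, max(1, min(rl, 720)), 60, "primary", rl)
        )
        is_specific = rng.random() < scenario.true_specificity
        if is_specific:
            offset = int(
                np.clip(rng.normal(0.0, scenario.offset_sd), -(tol - 1), tol - 1)
            )
            contig, start = site.contig, max(0, site.start + offset)
        else:
            contig, start = random_start(rl)
        filtered = rng.random() < scenario.frac_filtered
        if filtered:
            if rng.random() < 0.5:
                mapq, category = int(rng.integers(0, 20)), "primary"
            else:
                mapq, category = 60, "supplementary"
            truth = "unclassifiable"
        else:
            mapq, category = 60, "primary"
            truth = "site-specific" if is_specific else "random"
        genomic.append(
            ReadAlignmentRecord(rid, contig, start, start + rl, mapq, category, rl)
        )
        truth_rows.append((rid, truth))

    for i in range(scenario.n_untargeted_reads):
        rid = f"bg_{i:05d}"
        rl = read_len(scenario.mean_background_read_length)
        total_bases += rl
        contig, start = random_start(rl)
        genomic.append(
            ReadAlignmentRecord(rid, contig, start, start + rl, 60, "primary", rl)
        )
        truth_rows.append((rid, "untargeted"))

    pool = TargetedReadSet(
        transgene_alignments=transgene,
        genomic_alignments=genomic,
        total_bases=total_bases,
        genome_size=sum(lengths.values()),
        gene_copies=scenario.gene_copies,
        site=site,
    )
    truth = pd.DataFrame(truth_rows, columns=["read_id", "truth_label"])
    return pool, truth


# ---------------------------------------------------------------------------
# qPCR plate
# ---------------------------------------------------------------------------


def _logistic_curve(
    cp: float, n_cycles: int, rng: np.random.Generator, fluor_noise_sd: float
) -> np.ndarray:
    """Sigmoid fluorescence whose second-derivative maximum sits at ``cp``."""
    cycles = np.arange(1, n_cycles + 1, dtype=float)
    inflection = cp + SDM_OFFSET
    f = 0.05 + 1.0 / (1.0 + np.exp(-(cycles - inflection)))
    if fluor_noise_sd > 0:
        f = f * (1.0 + rng.normal(0.0, fluor_noise_sd, size=f.size))
    return f


def simulate_qpcr_plate(
    scenario: SimScenario,
) -> tuple[dict[str, list[AmplificationCurve]], pd.DataFrame]:
    """Simulate amplification curves encoding known copy-number ratios.

    Per sample the true target CP is ``base_target_cp - log_E(ratio)``;
    reference genes sit at fixed CPs and the calibrator sample encodes
    ratio 1, so the calibrator-normalized relative amount equals the true
    ratio.  Per-well CP jitter is N(0, cp_noise_sd).  When
    ``inter_run_shift`` is set a second run block is emitted with every CP
    (calibrator included) shifted by that many cycles.  Returns curves per
    run and a truth table (run, sample, gene, true_cp, true_ratio).
    """
    if scenario.efficiency <= 1.0:
        raise ValueError("efficiency must be > 1")
    rng = scenario.rng_qpcr()
    log_e = math.log(scenario.efficiency)

    runs = {"run1": 0.0}
    if scenario.inter_run_shift is not None:
        runs["run2"] = float(scenario.inter_run_shift)

    samples: list[tuple[str, float]] = [(scenario.calibrator_sample, 1.0)]
    samples += [
        (f"S{i + 1}", r) for i, r in enumerate(scenario.true_ratios)
    ]

    curves: dict[str, list[AmplificationCurve]] = {}
    truth_rows = []
    for run, shift in runs.items():
        run_curves: list[AmplificationCurve] = []
        well = 0
        for sample, ratio in samples:
            is_cal = sample == scenario.calibrator_sample
            gene_cps = {
                scenario.target_gene: scenario.base_target_cp
                - math.log(ratio) / log_e,
                **scenario.reference_cps,
            }
            for gene, true_cp in gene_cps.items():
                true_cp += shift
                role = (
                    ("calibrator-target" if gene == scenario.target_gene
                     else "calibrator-reference")
                    if is_cal
                    else ("target" if gene == scenario.target_gene else "reference")
                )
                truth_rows.append((run, sample, gene, true_cp, ratio))
                for _ in range(scenario.n_replicates):
                    well += 1
                    cp = true_cp + (
                        rng.normal(0.0, scenario.cp_noise_sd)
                        if scenario.cp_noise_sd > 0
                        else 0.0
                    )
                    run_curves.append(
                        AmplificationCurve(
                            f"{run}_W{well:03d}", sample, gene, role,
                            _logistic_curve(
                                cp, scenario.n_cycles, rng, scenario.fluor_noise_sd
                            ),
                        )
                    )
        curves[run] = run_curves
    truth = pd.DataFrame(
        truth_rows, columns=["run", "sample", "gene", "true_cp", "true_ratio"]
    )
    return curves, truth


def curves_to_frame(curves: list[AmplificationCurve]) -> pd.DataFrame:
    """Long-format frame (well, sample, gene, role, cycle, fluorescence)."""
    rows = []
    for c in curves:
        for cycle, f in enumerate(c.fluorescence, start=1):
            rows.append((c.well, c.sample, c.gene, c.role, cycle, f))
    return pd.DataFrame(
        rows, columns=["well", "sample", "gene", "role", "cycle", "fluorescence"]
    )


# ---------------------------------------------------------------------------
# Stability series
# ---------------------------------------------------------------------------


def simulate_stability(
    scenario: SimScenario,
) -> tuple[list[StabilitySeries], pd.DataFrame]:
    """Simulate long-term culture series with known retention.

    Fluorescence decays exponentially, ``F(t) = F0 * exp(-lam * t)`` with
    ``lam`` chosen per pool so that retention at the final day equals the
    scenario's target; copy numbers stay constant unless a
    ``gcn_end_factor`` emulates copy loss.  Growth rates ramp linearly
    between ``mu_start`` and ``mu_end`` over weekly assessment windows.
    Truth columns: pool, lam, true_retention.
    """
    rng = scenario.rng_stability()
    days = np.asarray(scenario.stability_days, dtype=float)
    final = float(days[-1])
    n_windows = max(1, int(math.ceil(final / 7.0)))
    edges = np.linspace(0.0, final, n_windows + 1)
    mids = 0.5 * (edges[:-1] + edges[1:])
    mus = scenario.mu_start + (scenario.mu_end - scenario.mu_start) * mids / final
    windows = tuple(
        MuWindow(float(edges[i]), float(edges[i + 1]), float(mus[i]))
        for i in range(n_windows)
    )

    series: list[StabilitySeries] = []
    truth_rows = []
    for pool, target_retention in scenario.pool_retention.items():
        if not 0.0 < target_retention:
            raise ValueError(f"pool {pool}: retention target must be positive")
        lam = -math.log(target_retention) / final
        fluor = scenario.base_fluorescence * np.exp(-lam * days)
        if scenario.stability_noise_sd > 0:
            fluor = fluor * (
                1.0 + rng.normal(0.0, scenario.stability_noise_sd, size=days.size)
            )
        gcn = np.full(days.size, scenario.base_gene_copies)
        factor = scenario.gcn_end_factor.get(pool)
        if factor is not None:
            gcn[-1] *= factor
        series.append(
            StabilitySeries(
                pool=pool,
                condition="without selection",
                days=days,
                fluorescence=fluor,
                gene_copies=gcn,
                mu_windows=windows,
            )
        )
        truth_rows.append((pool, lam, target_retention))
    truth = pd.DataFrame(truth_rows, columns=["pool", "lam", "true_retention"])
    return series, truth


def stability_to_frame(series: list[StabilitySeries]) -> pd.DataFrame:
    """Long-format frame matching :func:`safeharbor.stability.read_series_csv`."""
    rows = []
    for s in series:
        for i, day in enumerate(s.days):
            mu = np.nan
            for w in s.mu_windows:
                if w.start_day <= day < w.end_day or (
                    day == s.days[-1] and w.end_day >= day
                ):
                    mu = w.mu
                    break
            rows.append(
                (s.pool, s.condition, day, s.fluorescence[i], s.gene_copies[i], mu)
            )
    return pd.DataFrame(
        rows, columns=["pool", "condition", "day", "egfp_fluor", "gene_copies", "mu"]
    )
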