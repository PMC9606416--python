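# Methods

This note documents the models and procedures the package implements, the
defaults and why they were chosen, what the synthetic-data generators do
and do not emulate, and the numerical choices that matter.

## Coordinate conventions and interval algebra

All internal coordinates are 0-based half-open (BED-native); GTF/GFF input
(1-based inclusive) is converted on read. The TSS of a `+`-strand gene is
its 0-based start; of a `-`-strand gene, `end − 1`.

Three operations drive the site screen:

* **merge(S, max_gap)** joins intervals that overlap or whose gap is
  *strictly* smaller than `max_gap`. The strict reading means a 149 bp gap
  closes under the default `max_gap = 150` while a 150 bp gap does not,
  and `max_gap = 0` merges only genuinely overlapping intervals
  (book-ended ones stay apart — half-open neighbors share no base). Note
  this differs by one from bedtools `merge -d`, which joins gaps ≤ d;
  `max_gap` is exposed so either convention is reachable.
* **intersect(A, B)** is base-level: the output covers exactly the bases
  covered by both inputs.
* **anti_join(A, B)** is record-level: intervals of A are kept or dropped
  whole, dropped on any ≥ 1 bp overlap with B (bedtools `intersect -v`
  semantics). "Anti-join" names a record operation, not base subtraction.

`tss_distance` is strand-agnostic: 0 when a TSS lies inside the interval,
otherwise the gap to the nearest TSS (`start − tss` on the left,
`tss − end` on the right). The asymmetry of one base between the two
sides is a deliberate, documented convention matched by the tests'
exhaustive-scan oracle.

## The integration-site screen

Stage order (each stage logged with surviving counts):

1. per activating mark (default H3K4me3, H3K27ac), intersect the two
   timepoints' peak sets — a region counts only if marked at **both**
   growth phases (set `require_both_timepoints=False` for the union
   instead);
2. per mark, drop peaks that overlap any gene body or sit closer than
   `min_tss_distance` (default 5000 bp) to any TSS — note the TSS filter
   runs *before* the cross-mark intersection, so a mark's peak must be
   individually intergenic;
3. intersect across all activating marks;
4. anti-join against **all** repressive-mark peaks (default H3K9me3) from
   both timepoints, unfiltered;
5. merge with `merge_max_gap` (default 150 bp);
6. drop candidates shorter than `min_site_length` (default 600 bp).

Thresholds are inclusive where the screen keeps: TSS distance exactly
5000 bp and width exactly 600 bp pass.

Peaks on contigs without any annotated gene are kept by default (with a
logged count): highly fragmented rodent assemblies have many unannotated
scaffolds and silently dropping them would bias the screen toward
well-annotated contigs. `keep_unannotated_contigs=False` reverses this.
Sites on such contigs report an infinite nearest-TSS distance.

This package consumes per-timepoint peak BEDs and computes cross-timepoint
commonality by interval intersection. Differential peak callers can
produce "strongest common peak" tracks directly; users holding such output
should feed it in as a single timepoint (or bypass `common_peaks`), since
intersection of independently called peak sets is a simplification of
differential calling.

Harbor finding is strand-agnostic; predicted sites carry no strand.

## Targeted Cas9 read classification

A read is *transgene-bearing* if it has **any** alignment (primary,
secondary, or supplementary) to the transgene reference — the triage is
deliberately permissive because enrichment reads are chimeric around the
cut site. The strict filter (primary only, MAPQ ≥ 20) applies to the
*genomic* alignment used for classification; if several survive for one
read, the highest-MAPQ one is used. Reads whose genomic alignments are all
filtered out are reported as *unclassifiable* and excluded from the
specificity denominator, which therefore counts only reads assigned to
both the transgene and the genome.

Classification uses an overlap window of the intended site widened by
`tolerance` (default 1000 bp) on each side: observed knock-in junctions
sit up to several hundred bp from the nominal cut site, so a read
overlapping the widened interval is *site-specific*, anything else —
including any alignment on another contig — is *random*. The signed
offset (alignment start − site start) is reported per read.

Fold enrichment is `n / (2 · gene_copies · bases_sequenced/genome_size)`:
observed transgene-spanning reads over the number expected if the same
number of bases had been sequenced without targeting, given the relative
transgene copy number. The factor 2 follows the published form of the
expectation and is implemented literally.

Specificity is computed per **read**, not per unique integration event;
pools with clonal structure should interpret it as a read-weighted
fraction.

## qPCR: CP calling and relative quantification

**CP calling.** The crossing point is the maximum of the amplification
curve's second derivative. The implementation estimates per-cycle noise
robustly from the curve's second differences (median absolute deviation;
the sigmoid contributes to only a few of them), pre-smooths visibly noisy
curves with a Savitzky–Golay filter (`smooth_window`, default 5, quadratic),
fits a quintic smoothing spline whose residual budget matches the noise
estimate, and maximizes the spline's second derivative on a dense
(0.001-cycle) grid, ties breaking toward the earliest cycle. For a clean
curve the spline interpolates and the estimate is essentially exact: on a
noiseless logistic with inflection c₀ the analytic SDM lies at
`c₀ − ln(2 + √3)` ≈ c₀ − 1.317, and the estimator lands within 0.001
cycles of it. A residual grid-phase bias below ~0.06 cycles remains for
CPs at arbitrary fractional positions; it cancels exactly for integer
translations and is far below replicate noise on real plates. Flat or
purely drifting curves (no amplification upswing) return "no CP" rather
than a number. A plain discrete-second-difference estimator was rejected:
its bias on the same noiseless logistic is ~0.3–0.4 cycles.

**Relative quantification.** `E^(CP_ref − CP_target)` with efficiency
E = 2.0 by default (perfect doubling; per-gene efficiencies can be
passed). The dual-reference "all to mean" pairing is implemented as: each
target replicate CP is paired with the **mean** reference CP per reference
gene; every resulting ratio is divided by the calibrator sample's ratio
(computed identically); the relative amount and SD are the mean and SD
over the pooled {replicates × references} set. The vendor's exact pairing
algorithm is proprietary; this documented interpretation satisfies the
defining invariances (a constant CP shift applied to an entire run,
calibrator included, cancels exactly; identical CPs give ratio 1, SD 0).
Replicate outliers are never removed; a CP spread above 1 cycle is logged.

## Stability metrics

Retention is `R(t) = NF(t)/NF(0)` with `NF = F/GCN` (fluorescence per
relative gene copy), which separates epigenetic silencing (F falls, GCN
flat) from copy loss (GCN falls). R is invariant to the units of either
input. Generations accumulate as `Σ Δt·μ / ln 2` over piecewise-constant
growth-rate windows that must tile the culture span.

The verdict *stable* requires `R(end) ≥ 0.70` **and** `g ≥ 70`, both
bounds inclusive; by default only the final timepoint is tested
(`strict_monotone=True` demands every timepoint clear the threshold).
Note that at the growth rates typical of long-term CHO culture
(0.90–1.05 d⁻¹), a 49-day run yields ≈ 68.9–69 generations — colloquially
"70 generations", but the verdict uses the computed value literally, so a
49-day series needs a mean μ ≥ 0.99 d⁻¹ to clear the generation arm.
When measurement SDs accompany the series, first-order error propagation
(summed relative variances of F(t), F(0), GCN(t), GCN(0)) yields a
retention SD; this is a reporting convention, not a calibrated interval.

The complementary regulatory half of the stability definition —
"clinically meaningful differences" in product quality — is not
computable from these data and is out of scope.

The mPlum:eGFP ratio (both autofluorescence-corrected) indicates
integration type for donors whose mPlum cassette lies outside the
homology arms: homology-directed insertion carries eGFP only (ratios
around 0.05–0.2), random vector integration carries both (ratios near 1).
The package reports the ratio with interpretation guidance only — no hard
call, because the mapping from ratio to specificity depends on the pool's
clonal composition.

## Synthetic-data generators

One scenario seed fans out through `numpy.random.SeedSequence.spawn` to
four independent streams (harbors, reads, qPCR, stability), so adding or
re-running one generator never perturbs another and a fixed seed fixes
every output byte-for-byte.

* **Toy genome / planted harbors.** 3 contigs × 1 Mb, 50 genes per contig
  — large enough for 5 kb TSS-exclusion zones, small enough for per-base
  oracle tests. The genome is tiled in 20 kb blocks: even blocks carry two
  genes, odd blocks at most one intergenic feature placed ≥ 6 kb from the
  block edges, which guarantees TSS clearance by construction (a
  post-generation self-check re-verifies every invariant). Planted
  harbors are 2600–3900 bp wide — the width range of sites the screen
  produces on real data. Decoys each violate exactly one criterion:
  activating peaks straddling a gene start; intergenic regions overlapped
  1–200 bp by H3K9me3; intergenic fragments of 300–599 bp. Peaks are
  simulated directly (no signal-track or pileup model), and planted peaks
  coincide exactly with their harbor, so exact-coordinate recovery is the
  correct expectation; real peak boundaries are noisy, and the planted
  benchmark shows filter-logic correctness, not robustness to boundary
  noise.
* **Targeted reads.** Each of n reads (default 2000; lognormal lengths,
  ~12.6 kb targeted, ~5 kb background) is site-specific with the true
  specificity (defaults cover the observed 0.23–0.73 range); site-specific
  starts are offset N(0, 300 bp) truncated inside the ±1 kb tolerance
  window, random reads land uniformly outside it, and a configurable 5%
  get MAPQ < 20 or supplementary flags to exercise the filters. No
  sequence-level or error-model simulation — alignment coordinates are
  generated directly, so the benchmark shows classification-logic
  correctness, not aligner behavior on concatemers.
* **qPCR plates.** Per-well logistic curves with the inflection at
  `true CP + ln(2+√3)`, so the SDM of the curve sits exactly at the
  intended CP; true CPs encode copy ratios via `CP = CP₀ − log_E(ratio)`;
  replicate CP jitter N(0, 0.1 cycles) by default; a calibrator sample at
  ratio 1; an optional second run block with every CP shifted to test
  inter-run normalization. Real plates add baseline drift and plateau
  heterogeneity that this generator omits.
* **Stability series.** `F(t) = F₀·e^(−λt)` with λ set from a per-pool
  target retention at day 49 (defaults 0.97, 0.72, 0.40, 0.26 — the
  range observed across site-specific and random pools), constant copy
  number (optionally stepped to emulate copy loss), and growth rates
  ramping linearly 0.90 → 1.05 d⁻¹ over weekly windows.

## Problem sizes in tests and the acceptance script

The bundled benchmarks run at desk scale: 100 kb contigs for the per-base
algebra oracles (200 random cases), 5 peak-set scenarios of 20 harbors +
60 decoys, 20 replicates × 2000 reads per specificity level, 20 simulated
plates, and single stability series per pool — chosen so the whole suite
completes in seconds while keeping binomial/qPCR sampling error an order
of magnitude below the tolerances being asserted. Genome-scale inputs
(full CHO peak sets and deposited sequencing runs) flow through the same
code paths via the CLI but are not bundled.

## Known limitations

* Peak calling, differential ("common peak") calling, read alignment and
  basecalling are upstream; the package consumes their outputs.
* The screen ranks nothing: all sites passing the criteria are reported
  without signal-strength ordering.
* The specificity estimate treats reads as independent; UMI-less nanopore
  enrichment can over-count fragments from one integration event.
* qPCR quantification is relative only — no standard curves, melting
  analysis, or primer-efficiency estimation.
* Growth modeling is piecewise-constant μ; no lag/death-phase fitting.
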