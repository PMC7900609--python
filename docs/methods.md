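# Methods

This note records the models behind `replitx`, the defaults and why they
were chosen, and what the synthetic validation does and does not
demonstrate.

## Coordinate and data conventions

All coordinates are 0-based half-open (BED). A minus-strand gene has its
TSS at `end − 1`; a transcription-oriented window `[TSS−u, TSS+d)` maps to
the genomic interval `[tss+1−d, tss+1+u)` on the minus strand, so every
TSS-anchored quantity is exactly mirror-symmetric (verified by tests that
reverse the genome and all strands). Coverage is stored as per-bp density
on fixed bins; the last bin of a chromosome may be partial and all mass
accounting (window integrals, rebinning, RPM normalization to a total of
10⁶) weights it by its true width. Window queries weight partial edge bins
by overlapped length, which makes the binned computation equal a per-base
sum exactly; the test suite checks metagene and intron quantification
against naive per-base loops to 1e-6 relative.

Transcript records are kept throughout; gene-level outputs deduplicate by
`gene_id`, keeping the longest transcript.

## Analysis models

**Replication timing.** Each S-phase BrdU track is rebinned to 10 kb and
RPM-normalized; the timing score of a bin is the signal-weighted mean
S-phase index (1 = earliest), smoothed with a centred 5-bin moving
average. The weighted mean is parameter-free, strictly monotone in the
true replication time under any unimodal incorporation kernel, and
preserves the arg-max structure, which is all the downstream logic needs.
Bins with summed RPM below 0.5 stay undefined, and smoothing never
resurrects an undefined bin. Fork direction is the sign of the central
difference of the smoothed score, with a dead zone of ε = 0.01 index
units/bin; local minima are reported as initiation regions and maxima as
termination regions. All three knobs (bin size, smoothing, ε) are exposed
in `AnalysisParams`.

**Directionality.** Over the gene-overlapping bins with defined fork
direction, the majority fraction f decides the class at a threshold of
0.9. A strict "uniquely one direction" rule (f = 1) would be fragile to a
single noisy bin; 0.9 tolerates one dissenting bin in ten while still
separating genuine internal flips. Undefined bins are excluded from f.

**Replication time point.** Arg-max over S-phase tracks of the mean RPM
density over the gene body; ties break toward the earlier time point
(first maximum), all-zero genes are undefined.

**Nascent transcription and shutdown.** Intron-restricted quantification
(unweighted mean of per-intron mean densities; introns shorter than
100 bp are skipped to avoid splice-edge bins). The shutdown fold change
compares the gene's replication time point with the previous one; the
recovery fold change compares the following time point with the same
baseline. A transcript whose replication time point is the first label,
or whose prior-level is zero, is undefined. The shutdown flag threshold is
0.9: the detector asks whether a gene moved from no reduction (1.0)
toward the characteristic replication-coupled reduction (0.8), and the
midpoint is the natural decision boundary — a threshold of exactly 1.0
would flag half of all unaffected genes on noise alone, since an unbiased
fold-change estimate of a non-shut-down gene falls below 1.0 with
probability one half.

**Transcribed filter.** RPM ≥ 1 at every time point. The threshold is
configurable; ≥ (rather than >) is used so the boundary value passes.

**P³R² (pausing release ratio).** Per-bp densities, not raw sums: the two
windows have different lengths (350 vs 700 bp) and the density convention
makes uniform coverage give exactly 1. The body window truncates at the
TTS; genes ≤ 300 bp, or with zero coverage in either window, are
discarded.

**Antisense/sense ratio.** Symmetric TSS ± 1 kb window by default (an
upstream-only mode is a flag); zero sense signal is discarded.

**Metagene profiles.** Per-anchor sampling at fixed oriented offsets, then
an unweighted average; with an input track the per-anchor, per-position
ratio (sample RPM)/(input RPM + ε) is formed *before* averaging, matching
per-gene normalization rather than a ratio of averages. The pseudocount ε
defaults to 0.1 × the genome-median input RPM density, which leaves
normal-coverage positions essentially untouched while keeping zero-input
positions finite. Anchors whose window leaves the chromosome are dropped
and counted.

**Gap metrics.** The single-gene oriented ratio profile (±2.5 kb, 50-bp
steps) is divided by its flank baseline (mean over |x| ≥ 1.5 kb). The gap
centre is the minimum over the core |x| ≤ 1 kb of the profile smoothed
over 5 positions, and the depth is one minus that smoothed minimum: an
unsmoothed minimum over ~40 noisy positions is biased low by
extreme-value statistics, while the smoothed minimum is nearly unbiased
at realistic depth. The width, by contrast, is measured on the
*unsmoothed* profile (the contiguous run below θ = 0.8 around the
centre): smoothing spreads the gap edges, which shifts the θ crossing
outward by ~(θ − midpoint)/slope (≈ +50 bp at 50 % depth), whereas the
raw profile keeps the edges crisp. The core restriction stops flank noise
from becoming "the gap", and a flat profile returns (0, 0). The θ rule
cannot resolve gaps shallower than 1 − θ; such genes report width 0 by
construction.

**Peak calling.** Binned Poisson test at 200 bp against
λ = max(genome-wide input rate, input means over centred 1/5/10-kb
windows), scaled by the sample/input mass ratio — the local-λ logic of
MACS-style callers on binned input. Raw p < 1e-5 with no multiple-testing
correction (an optional Benjamini–Hochberg mode exists but is off by
default, matching common practice with this caller family); significant
bins merge across single-bin gaps and peaks need ≥ 2 significant bins.
Taking the maximum over background windows makes the null conservative:
on resampled-input null data the significant-bin rate stays below the
nominal 1e-5 (binomial test over 2 × 10⁵ bins in the test suite). Fragment
-model building of read-level callers does not apply to binned coverage
and is out of scope.

**G-MiDS.** G2/M peaks minus any peak overlapping (≥ 1 bp) the union of
all S-phase peak sets, kept or dropped whole. Hotspot transcripts carry a
G-MiDS-specific peak within the strand-aware window [TSS, TSS+2 kb); a
symmetric ±2 kb mode is available. Unique hotspot genes deduplicate
transcripts by gene.

## The synthetic data generator

The generator produces the statistical structure the analysis assumes,
with per-bin and per-transcript ground truth; its defaults are the
package's study conditions.

**Genome and genes.** 2 chromosomes × 10 Mb, 300 genes plus a 10 % chance
of a 3′-truncated second isoform, placed sequentially with ≥ 5 kb
clearance so that TSS windows and flank baselines sample only their own
gene. Gene lengths are drawn log-uniformly within the four standard
classes (<5 kb, 5–30, 30–100, >100 kb) with weights 0.35/0.35/0.20/0.10;
2–20 exons on a 100-bp lattice. Expression is log-normal (median e ≈ 2.7,
σ_log = 0.6) with 10 % silent genes; pausing is log-normal (median 2.5,
σ_log = 0.4) with correlation 0.5 to log gene length, reflecting that
longer genes are more promoter-proximally paused.

**Replication program.** Origins every ~1 Mb (±100 kb jitter) firing at
t₀ ∈ [0.5, 2.2] time point units; forks travel at 150 kb per unit, so the
true replication time of a bin is min over origins of t₀ + distance/v and
the fork direction flips exactly at origins and termini. With five
S-phase windows this spans the full early-to-late range while keeping the
genome-mean expected signal comparable across the five libraries — under
per-library depth normalization no single time point is amplified so much
that reduced (gapped) regions reach significance. Expected BrdU in a bin
at time point t is a Gaussian kernel exp(−(t−T)²/2σ_t²) with σ_t = 0.8,
plus a small uniform IP background (5 % of the kernel peak); each track is
scaled to a mean of 100 expected counts per 50-bp bin and observed through
Poisson noise, as is the uniform input.

**TSS gaps.** Each transcribed gene's window [TSS−1 kb, TSS+1 kb) is
multiplied by (1 − depth) at *every* S-phase time point — TSSs remain
under-replicated throughout S phase, as the fractionated replication data
show. Depth is 0.5 + 0.2 × (pausing z-score), clipped to [0.15, 0.85]
(more paused ⇒ deeper), giving a population mean of 0.5 and a width of
2 kb. Hotspot gaps never refill; 60 % of other transcribed genes have the
factor restored at the last S time point (how refilling distributes over
late S vs G2/M is not constrained by data, so it is a single free knob).

**Hotspots and G2/M synthesis.** Hotspots are the top 20 % of transcribed
genes by pausing — the hotspot phenotype belongs to the longest, most
transcribed, most paused genes, and their correspondingly deep persistent
gaps are what keeps their TSSs out of S-phase peak territory. The G2/M
track is uniform background (20 reads/bin) with a TSS-centred fill of
10 × background over 1.2 kb at hotspot genes: G2/M synthesis completes
replication exactly where the centred gap was, and the fill sits inside
the 2-kb gap with a ≥ 2-bin margin so the subtraction geometry is
well-posed at 200-bp caller bins.

**Chromatin RNA-seq.** Sense density over the gene body: 1 (introns) or
1 + 0.5 (exons, mature-mRNA contamination) per unit expression, plus a
pausing-proportional TSS peak over [−50, +300). Antisense covers
[TSS−1 kb, TSS) on the opposite strand with a density calibrated per gene
so that the *expected measured* antisense/sense ratio over TSS ± 1 kb
equals the drawn ratio (log-normal, mean 3.8 for hotspots vs 1.0
otherwise) — the parameter is defined as the observable, so group-mean
recovery tests the estimator rather than a window-overlap conversion. At
the gene's replication time point all of its signal (sense, TSS peak,
antisense) is multiplied by the shutdown factor (0.8 for 70 % of
transcribed genes, 1.0 otherwise) and restored at the next time point.

**GRO-seq.** Density p·k over [TSS−50, +300) and k over [+300, TTS) with
k ∝ expression, so each gene's true P³R² is exactly its drawn pausing.
Simulated at 10-bp bins: the pausing windows are only 350/700 bp, and at
50-bp bins the mixed boundary bins blend peak and body density enough to
bias the window ratio ~7 % low.

**Ground truth conventions.** The true replication time point is the
arg-max of the expected depth-scaled, gap-reduced gene-mean signal — i.e.
the expected outcome of the assignment rule, which coincides with the
kernel arg-max because the gap scales the kernel uniformly across time
points. True directionality classes are derived from the analytic fork
field with the same majority rule at the same 10-kb resolution, with a
coarse bin that straddles an origin or terminus marked *mixed* and
excluded — a sub-bin flip cannot be attributed to one direction by any
bin-resolution method, so including it would score an estimator against
information that is not present at the stated resolution.

## What the validation shows — and what it does not

The generator is deliberately structural, not read-level: Poisson counts
on binned densities, uniform mappability, no GC or fragment-length
effects, no blacklist artifacts, no replicate structure, piecewise-linear
timing from point origins, rectangular gaps, a single shutdown factor.
Passing recovery tests therefore demonstrates that the estimators are
correct and approximately unbiased *under the stated generative
assumptions* at realistic depths — not that real libraries meet those
assumptions. In particular the real-data peak counts and class
percentages depend on genome size, depth and annotation and are not
reproduced at this scale. Alignment, blacklist filtering and bigWig
handling are upstream/out of scope; the package consumes bedGraph tracks.

## Degenerate inputs and numerical conventions

Zero-mass tracks: RPM normalization refuses them; an all-zero BrdU series
yields an all-undefined timing profile with a warning; an all-zero time
point in relative enrichment yields an ε-dominated ≈ 0 profile rather
than a division error. Boundary values: length-class edges are
closed-left (a 5-kb gene is "<5 kb"); arg-max ties break toward the
earlier time point; peaks must be sorted and non-overlapping within a
set, and writing quantizes scores to 0.1 (the matching reader restores
them). bedGraph writing uses 17 significant digits and bin-aligned
intervals re-read exactly, so a write→read cycle at the native bin size
is the identity. All simulation randomness flows through
`numpy.random.SeedSequence(seed, stream-tag)`, making every product
byte-identical for a fixed config and seed.

## Problem sizes

The default study conditions (2 × 10 Mb, 300 genes, 100 expected counts
per 50-bp BrdU bin) were chosen so that the full simulate→analyse→evaluate
cycle completes in seconds on a single core while every experiment's
sample size (≥ 200 genes for estimator means, ≥ 10⁵ bins for caller
calibration, ≥ 50 genes per antisense group) retains enough statistical
power for the recovery bounds to be meaningful.
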