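# Methods

## The problem being modelled

Native ChIP-seq from small cell numbers suffers a characteristic failure
mode: the pool of unique immunoprecipitated fragments shrinks with input,
so the fixed PCR amplification (18 cycles in the workflow this package
models) re-sequences the same molecules over and over. The symptoms are a
rising fraction of duplicate reads, a rising fraction of unmappable
amplification artifacts, and — once duplicates are removed — fewer usable
reads and lost peaks. `lochip` simulates libraries with exactly this
structure and implements the evaluation statistics used to characterize
it: read-class accounting, Poisson-background peak calling, benchmark
sensitivity/specificity, subsampling saturation, genome-binned
correlations, and TSS metaprofiles.

## Simulator

### Genome and annotation

Synthetic genomes have equal-length chromosomes, optional repeat territory
laid down as non-overlapping 2 kb blocks (exactly `round(f·n_blocks)`
blocks, so coverage is within one block of the requested fraction), and
genes placed one per 10 kb slot with the TSS jittered inside the slot and
kept at least 1 kb clear of repeat blocks. Expression is log-normal
(σ = 1.2, a long-tailed distribution typical of expression microarray
intensities); genes are ranked into quartiles Q1 (lowest) to Q4 (highest).
The effective genome size used by the Poisson background is the non-repeat
length.

### Fragment pool and enrichment

The unique-fragment pool has `round(cells_per_ip × pool_per_cell)`
molecules. `pool_per_cell` defaults to 0.5 unique recoverable fragments
per cell — the scale is chosen so that the cell-number titration
(2×10⁴ … 2.5×10⁶ cells/IP) spans near-total duplication to <10%
duplication at a 2×10⁵-read depth on the 10 Mb test genome, the regime
the evaluated workflow operates in.

A fraction `enrichment_fold/(enrichment_fold+1)` of molecules carry
signal; the rest are uniform background. For H3K4me3, signal fragments
sit on six phased nucleosomes at strand-oriented offsets
{−600, −350, +100, +300, +500, +700} bp from the TSS with Gaussian
positional jitter (sd 20 bp) and a nucleosome-free zone at TSS ± 50 bp;
genes are chosen with probability proportional to expression. For
H3K27me3, signal fragments fall uniformly in broad domains spanning each
lowest-quartile gene body ± 5 kb; since the annotation carries only a TSS,
the gene body is taken as a nominal 10 kb downstream of the TSS (the slot
pitch), giving 20 kb domains. H3K27me3 fragments are rejection-sampled so
that no enriched fragment overlaps a top-quartile H3K4me3 nucleosome
footprint — mark exclusivity is exact, not statistical. Fragment lengths
are Normal(147, 20) truncated to [100, 250] bp (mono-nucleosome sizing).

### PCR and sequencing

Each molecule draws one amplification efficiency from
Normal(`pcr_efficiency_mean`, `pcr_efficiency_sd`) clipped to [0, 1] and
is amplified through `pcr_cycles` (default 18) branching steps:
`copies += Binomial(copies, efficiency)`. Per-molecule efficiency is the
two-parameter way to get amplification bias; setting mean 1.0 and sd 0
gives deterministic doubling (2^C copies each), the unbiased reference
case used by the occupancy-oracle tests.

Sequencing draws `n_reads` reads: a fraction `artifact_fraction` are
position-less unmappable artifacts, a further `error_unmapped_fraction`
of genuine draws are lost to sequencing error, and the remainder sample
molecules with probability proportional to copy number — without
replacement from the physical copies whenever the amplified pool is at
least as deep as the read count. The without-replacement draw is an exact
multivariate hypergeometric sample implemented by choosing `n` distinct
copy indices uniformly (rejection on duplicates) and mapping them through
the cumulative copy-number vector; this runs in O(n log U) for pools of
any depth (amplified pools reach ~10¹¹ copies). Reads take the fragment's
5′-end coordinate on the molecule's strand; reads whose fragment midpoint
lies in a repeat block are multi-mapping; single-end, 36 bp.

### What the simulator does not model

No base-level sequences, quality scores, or alignment; mapping class is
emitted directly. MNase cleavage-site preference is not modelled, so all
position-level duplicates among genuine reads arise from PCR resampling
or random coincidence — in real data some duplicates are biological.
Repeat blocks are rectangular and uniformly scattered rather than
family-structured. Expression is a scalar per gene with no noise model.
Consequently, passing tests show that the pipeline statistics respond
correctly to complexity, enrichment, and depth; they do not validate
behaviour against artifacts real aligners or real chromatin introduce.

## Duplicate accounting

The duplicate key is (chromosome, strand-aware 5′ position, strand) — the
de facto single-end standard. Duplicates are marked independently within
the uniquely-mapping and multi-mapping classes; one representative per
group (lexicographically first read id, for reproducibility) survives.
"Usable" reads are unique-class survivors only. A consequence worth
knowing: for sharply positioned signal, distinct (position, strand) pairs
are a finite resource (~1.5 M for maximal-density H3K4me3 signal on a
10 Mb genome), so usable reads saturate with depth. This is why the deep
evaluation libraries in the tests run at ~0.5 M usable reads; sequencing
further cannot raise that number much, and the evaluation statistics are
already saturated there (subsampling statistic s ≈ 0.99).

## Peak calling

A minimal MACS-style scan with the dynamic local background switched off,
matching the evaluated workflow: reads are shifted to the fragment
midpoint (`shift` = half the insert size, default 73 bp) and each
contributes one unit of pileup over a `window` (150 bp) centred there.
The background is a single genome-wide rate
λ = n_reads × window / effective_genome_size. A position is significant
when the Poisson upper tail P(X ≥ k; λ), computed via the regularized
incomplete gamma function (with a log-survival fallback when the tail
underflows), is below `pvalue_threshold` (default 1e−5). Significant runs
separated by ≤ `merge_gap` (100 bp) merge; the summit is the leftmost
pileup maximum; the score is −log10 of the best tail probability. The
defaults are declared choices in the MACS-1.4 style — the workflow's own
cutoffs are not published.

Control mode raises the local rate to
max(λ, depth-scaled control pileup smoothed over 10 kb) and reports both
the control-corrected peaks and the peaks lost relative to the plain
scan. With a matched input library the loss is small (<5% in the test),
mirroring the negligible effect reported for the workflow.

One behaviour to be aware of: peak *counts* are not monotone in depth
near saturation. Deeper data fuses adjacent significant runs across the
merge gap and raises the genome-wide threshold, so counts can dip as
reads are added. The non-decreasing-count property holds in the
discovery-limited regime and is tested there.

## Comparison metrics

Overlap is ≥ 1 bp on half-open intervals, after per-set merging.
Sensitivity = fraction of benchmark peaks touched by the sample;
specificity = fraction of sample peaks touching the benchmark; coverage =
covered-length fraction of each detected benchmark peak under the union
of sample peaks, with a full/partial split at exactly 1.0. Peak heights
are compared as reads-per-million-usable on matched peaks
(largest-overlap assignment, summing sample counts that map to one
benchmark peak) with Spearman's ρ; fewer than 3 matched pairs is
signalled as undefined. Replicate concordance reports both directional
overlap counts and three candidate percentages (denominators: smaller
count, larger count, union) because the conventional denominator is
ambiguous; none is privileged.

## Saturation and genome summaries

Subsampling is Bernoulli thinning (seed-stable, order-preserving); the
grid defaults to {0.1, …, 1.0} and the saturation statistic is
s = n_peaks(0.5)/n_peaks(1.0). Binned tracks count usable-read 5′ ends in
non-overlapping bins (10 kb narrow-mark / 50 kb broad-mark conventions)
normalized to reads per bin per million usable reads; Pearson
correlations are computed over all bins including zeros by default, with
flags for log1p transformation and dropping all-zero bins. TSS profiles
accumulate strand-oriented 5′-end offsets in [−2 kb, +2 kb) on a 10 bp
grid (fine enough to resolve nucleosomes), averaged per expression
quartile and depth-normalized. For quantitative quartile comparisons the
profile exposes a footprint mean over a nucleosome-scale window (default
±50 bp around a nucleosome centre): a single 10 bp bin holds only a
handful of reads for the low-expression quartiles and its ordering is
noise-dominated, while the footprint mean separates quartiles stably.

## Numerical and degenerate-input choices

Coordinates are 0-based half-open internally; SAM I/O converts at the
boundary, and a minus-strand read's stored coordinate is its actual 5′
base (fragment end − 1). The occupancy expectation U(1−(1−1/U)^m)/m is
computed with expm1/log1p and is stable for U ≥ 10⁹. Summit ties break
leftmost. Empty controls fall back to the plain scan with a warning;
empty read sets produce zero tracks with normalization skipped and
logged; empty peak sets make overlap metrics undefined (raised, not
NaN). All randomness flows from explicit integer seeds; per-condition
streams in the pipeline are spawned from the master seed so adding a
condition does not perturb the others.

## Problem sizes used by the shipped evaluations

The test suite and `scripts/acceptance.py` run on a 10 Mb single
chromosome at full gene density (1000 genes): occupancy oracle at
(U, m) ∈ {(10³, 10³), (10⁴, 5×10⁴), (10⁵, 10⁵)} × 24 seeds; duplicate
titration at 2×10⁴ … 2.5×10⁶ cells/IP, 2×10⁵ reads, 5 seeds each; deep
H3K4me3 evaluation library at 1.5 M sequenced reads (~0.55 M usable,
saturated); shallow library at 6×10³ reads (a depth where the Poisson significance
count is stable across the subsample halving — at still lower depths the
integer threshold itself drops with depth and the statistic becomes
erratic); correlation replicates at
1.2 M reads each. These sizes put every statistic deep in its intended
regime while keeping a full run in minutes on one core.
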