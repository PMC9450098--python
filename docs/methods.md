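# Methods

This note documents the models and procedures `peakconcord` implements, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical conventions that make results
reproducible bit-for-bit.

## Coordinate and format conventions

All genomic coordinates are 0-based half-open (BED native); 1-based sources
must be converted at the boundary. A summit is a width-1 interval. The peak
reference point for all distance computations is the summit when supplied,
otherwise `floor((start + end) / 2)`. Chromosome names are compared by
exact string match; mixing `chr1`/`1` naming is surfaced as an
empty-assignment warning rather than silently "fixed". Each gene carries an
explicit canonical TSS column instead of deriving it from strand and span,
which avoids the plus/minus strand-end ambiguity. Every interface is a
headered TSV, BED3/BED4 or FASTA; `truth.json` is the only non-tabular
artifact.

## Consensus peak atlas

Replicate summit calls are clustered per chromosome by single linkage at a
matching distance of 50 bp (on a sorted axis this reduces to breaking
between consecutive summits more than 50 bp apart). Clusters supported by
at least `min_replicates` (default 2 of 3) distinct replicates emit one
summit at the representative position: the lower median for odd member
counts, the floor of the central-pair mean for even counts — deterministic
and input-order free. The 50 bp matching distance reuses the merge
distance, there being no separate established value for cross-replicate
summit matching.

Condition-level sets are concatenated and merged with `max_gap = 50` bp
using the gap convention of the standard merge tool: two intervals
coalesce (transitively) when `next.start − prev.end ≤ max_gap`, so touching
intervals always merge. Atlas peaks get stable ids `peak_000001…` in
coordinate order. Merging is idempotent and permutation invariant, and is
tested against an O(n²) transitive-closure oracle and against
`bedtools merge -d 50` itself.

## Depth normalization and fold changes

Per-sample factor = (total in-peak count) / (mean total over samples);
normalized counts are raw / factor, so factors average to 1 and normalized
column totals are equal. Fold change for a condition pair uses replicate
means with a pseudocount of 1 normalized fragment added to both means —
the pseudocount affects the ratio only, never the count threshold, which
uses the raw normalized means. This floors empty peaks at fold change 1
without distorting the count axis. Direction is "up" when the experimental
mean exceeds the control mean.

## The threshold grid and estimated FDR

Thresholds are exponentially spaced, `step_i = lo · (hi/lo)^(i/(n−1))`,
50 steps per axis: fold change over [1.5, 10] and minimum normalized count
(in the condition with more counts) over [30, 237]. The count-axis lower
bound is configurable (a lower-coverage variant uses 10). A peak passes a
cell iff fold change ≥ the cell's fold threshold AND the larger condition
mean ≥ the cell's count threshold, so cell passing sets are nested: raising
either threshold can only shrink the set. Internally the per-cell counts
are a 2D histogram of each peak's (fold, count) cell followed by reversed
cumulative sums — O(n_peaks + n_cells) per comparison — and tests verify
cell-by-cell equality with the direct filter.

Each cell's estimated FDR is

    est_FDR = n_conditions × (mean false positives per control comparison)
              ÷ (total passing peaks over experimental comparisons)

Control comparisons are all unordered pairs of the vehicle-control groups
(3 pairs for 3 groups); any peak passing in a control-vs-control comparison
is a false positive by construction. Two genuinely open modeling choices
are exposed as flags with these defaults: `n_conditions`
defaults to the number of experimental condition pairs entering the
analysis, and control-pair false positives are averaged (`combine="mean"`,
`"sum"` available). Cells whose experimental comparisons pass no peak carry
an +infinity sentinel and can never qualify. Pooling takes the union of
passing sets over all cells with est_FDR strictly below the cutoff
(default 0.25%); because passing sets are up-sets in the threshold order,
the union is computed with a prefix-OR over qualifying cells.

### Known limitation: pooled-set FDP vs per-cell FDR

The estimator is honest per cell — on matched null simulations, qualifying
cells genuinely have expected control false-positive rates consistent with
their estimates. But the pooled set is the union of up-sets over the whole
est-FDR < 0.25% contour, and each distinct corner of that staircase
contributes its own expected ~1 null peak per comparison; cells whose
three control comparisons happen to show zero false positives also qualify
regardless of their true null rate. On a 20,000-peak simulation with 500
true 4-fold peaks (the `scripts/acceptance.py` experiment) the realized
false-discovery proportion of the pooled set is therefore about 1.5–3.5%
across seeds — roughly an order of magnitude above the per-cell 0.25%
target, though still a small absolute contamination (~10–20 of ~510 pooled
peaks). Alternative readings were checked and rejected: treating cells as
2D histogram bins rather than threshold up-sets inflates the FDP to 8–14%
(selection on sparse bins), and summing rather than averaging control
false positives reduces but does not close the gap. Users who need
union-level control should lower the cutoff or validate against the null
pooled count (near-empty: ≤ ~0.15% of the atlas across seeds in our null
simulations).

## Differential expression

The package deliberately does not re-implement a negative-binomial
shrinkage model; for real data the fidelity path is an external DE table
(gene_id, log2fc, qvalue) produced by a dedicated fitter. Calls use
|log₂FC| ≥ 0.5 and q ≤ 0.05 by default ("≥"/"≤" comparisons, per the
minimum/maximum wording of the thresholds). Two internal routes exist so
synthetic end-to-end runs need no external fitter: a Welch two-sample
t-test on log₂(value + 1) per gene with Benjamini–Hochberg adjustment, and
a threshold-only mode (|log₂FC| ≥ cutoff, default use case: datasets
without replicates, e.g. a log₂FC ≥ 2 rule). Expression fold changes use a
pseudocount of 1 (configurable; there is no single field convention for
the TPM pseudocount). Cross-dataset utilities: quantile
normalization (rank-wise column means; ties receive the mean of the
reference values over the tied span — the common convention) and a
low-expression filter dropping genes whose maximum condition mean falls
below 5 normalized units.

## Peak→gene assignment

Distances are TSS-centered and strand-agnostic (windows are symmetric on
either side of the TSS); strand matters only for the "downstream"
annotation category. Nearest: the gene minimizing |distance| on the peak's
chromosome, ties to the smaller TSS then lexicographic gene id. Window and
promoter: closed bounds |d| ≤ 50,000 and |d| ≤ 1,500. Distal: strict inner
bound, 20,000 < |d| ≤ 50,000 — distal peaks lie *outside* the 20 kb core
and inside the 50 kb window, since the promoter-vs-distal contrast is
meaningless if the distal class re-admits promoter-proximal peaks. TAD mode links a
peak to every gene whose TSS lies strictly inside the same domain as the
peak reference point; peaks in no TAD are unassigned. Annotation uses
priority promoter (±3 kb of any TSS) > gene body > downstream (≤3 kb past
the strand-aware gene end) > intergenic, anchored to the nearest
triggering gene. Locus complexity counts nearest-assigned peaks per gene;
the tertile cutoff is the nearest-rank 67th percentile over genes with ≥1
peak, and "high" requires strictly more peaks than the cutoff.

## Concordance statistics

For each gene, assigned peaks are compared with the expression direction:
same-direction differential peaks are concordant, opposite discordant, and
`proportion_concordant = concordant / assigned` (0 when no peaks are
assigned). Genes that are not DE use the sign of their log₂FC so the
statistic is defined genome-wide. DE genes with ≥1 concordant differential
peak are `{up,down}_concordant`, otherwise `{up,down}_nonconcordant`;
discordant peaks never disqualify a gene (direction enters only through
the proportion and the ≥1-concordant rule). The continuous proportion is
retained in all outputs so stricter group definitions remain a
configuration choice.

Per-gene accessibility collapse: median of the assigned peaks' log₂ fold
changes (mean of the central pair for even counts) or the signed value of
maximal magnitude (positive wins exact-magnitude ties). Pearson
correlations carry 95% percentile-bootstrap CIs (default 10,000 paired
resamples; degenerate zero-variance resamples are redrawn; the seed is
mandatory and recorded). Percentile rather than BCa intervals: the
simplest method consistent with plain bootstrap resampling, and coverage
is verified at 93–97% in simulation. Distribution comparisons use the
two-sample two-sided Kolmogorov–Smirnov test with the asymptotic p-value
(samples here are hundreds of peaks); set-overlap tests use Fisher's exact
test with the two-sided hypergeometric-enumeration definition, verified
exhaustively against direct enumeration for all tables with margins ≤ 10.
Top-k gene selection is deterministic with lexicographic tie-breaks.

## Motif scanning and enrichment

PWMs are 4 × L column-stochastic matrices floored at 10⁻³ per cell and
renormalized, so log-odds (log₂ of motif vs background probability) are
finite on ACGT windows. A peak's score is the best window score over both
strands (the reverse strand is scanned via the reverse-complemented
matrix, which is exactly equivalent to scanning the reverse-complemented
sequence); windows containing N, and sequences shorter than the motif,
score −∞. The default match threshold is 80% of the motif's maximum
attainable score — a simple, transparent rule exposed as a flag
(p-value–calibrated thresholds are out of scope). The scanner is tested
for strand symmetry and against Biopython's PSSM scanner.

The enrichment score for a motif is
`100 × (m_t − m_c) / m_c`, where `m_c` and `m_t` are the means over
control and (dose-pooled) treatment samples of the *summed* normalized
counts at motif-containing peaks; summed-then-averaged is the default,
per-peak-mean aggregation being the flagged alternative. Dose pooling is
the default to reduce estimate variance; per-dose scores are available.
The CI is a percentile bootstrap over peaks. This is the bias-uncorrected
fractional-change statistic: no GC- or accessibility-matched background
peak sampling is applied, so on real data scores will differ slightly from
deviation scores computed with sampled backgrounds.

## Synthetic-data generator

The generator emulates the perturbation study design: three exchangeable
ethanol-control groups (the FDR estimator needs control-control pairs),
one signal at three dose levels, three biological replicates per
condition, negative-binomial fragment counts with variance μ + αμ²
(α = 0.1 by default — the standard count-model assumption; α → 0 recovers
Poisson), baseline mean 100 normalized fragments, and 200 bp peaks (the
scale implied by 150 bp-extension summit calling) placed within ±50 kb of
each gene's TSS. Genes sit 200 kb apart on a virtual chromosome so the
nearest-TSS rule provably maps each peak back to its generating gene —
which is what makes assignment-level truth exact. Peaks-per-gene is
Poisson(4) by default (most genes well under 20 peaks, with a realistic
high-complexity tail).

A fraction `frac_de_genes` (default 0.2) of genes is differentially
expressed with log₂FC magnitude `expression_effect` (default 2) at the top
dose, scaled by dose rank r/3; directions are random. Of the DE genes,
`frac_concordant` carry truly differential peaks: each of their peaks is
differential with probability 0.5 (at least one forced), in the gene's
direction, with fold `accessibility_effect^(r/3)` at dose rank r —
monotone in dose, mirroring observed dose-dependent accessibility
responses. Nonconcordant DE genes have no differential peaks but their
peaks' baseline accessibility is multiplied by
`baseline_shift_nonconcordant` (default 2), reproducing the observation
that genes changing expression without local accessibility change tend to
sit in already-open chromatin. Expression is log-normal TPM around a
per-gene log-normal baseline (median 20 TPM, log-sd 1) with per-sample
log₂ noise sd 0.25. Optional motif placement plants a consensus site into
truly up-regulated peaks ("differential_up") or random peaks ("random")
within otherwise uniform-random 200 bp sequences, with membership recorded
in the truth object.

What the generator does not emulate: raw reads, fragment-length and Tn5
insertion bias, GC effects, correlated replicate noise, peak-width
variation, overlapping genes, and real TAD structure (TAD mode is
exercised with explicit synthetic domains). Passing tests therefore show
the statistical machinery is correct and calibrated under the assumed
count model — not that real ATAC data meet those assumptions.

## Problem sizes used in the shipped checks

The calibration experiment in `scripts/acceptance.py` uses 20,000 peaks
with 500 true 4-fold peaks. Test-suite sizes were chosen to keep the full
suite fast while leaving comfortable statistical margins:
concordant-fraction recovery at n_genes = 2,000 per setting; the
regime-separation sweep at n_genes = 400 across 10 seeds; baseline-shift
detection at n_genes = 600 across 20 seeds; bootstrap coverage over 500
datasets of n = 100 with 2,000 resamples; geometry oracles over 100 random
instances each. All simulations are seeded; every bootstrap records its
seed in its result object.
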