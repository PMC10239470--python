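# Methods

This note documents the models, rules and numerical choices behind each
stage, what the synthetic generator does and does not emulate, and the known
limitations.

## Coordinate conventions

All intervals are BED-style 0-based half-open `[start, end)`; touching
intervals never overlap; overlap means ≥ 1 shared bp. Peak membership in a
chromatin state or a contact-map bin uses the peak **midpoint** — states
partition the genome and bins tile it, so midpoint membership counts each
peak exactly once and never splits a peak across bins. The promoter window is
strand-oriented: 10 kb upstream to 2 kb downstream of the TSS. Nearest-TSS
distances are 0 when the TSS falls inside a peak and otherwise measured from
the nearer interval boundary; ties break toward the lexicographically
smaller gene id so outputs are platform-independent.

## Accessibility clustering and state enrichment

Signal over a region is the bp-weighted statistic (default median) of the
overlapping track bins; the weighted median reproduces the per-basepair
median exactly, including the even-count averaging rule. Clustering is
standard k-means (Euclidean, k-means++ init, 10 restarts, fixed seed) on the
regions × samples signal matrix; labels are then permuted so cluster 1 has
the highest mean signal in the ordering columns (the control sample by
default) and cluster 3 the lowest. Cluster 3 is therefore always "the
modestly accessible class", whatever the raw k-means labels were.

State enrichment for a peak set of size n against a segmentation: for each
state covering genome fraction g with k peak midpoints inside,
`FE = (k/n)/g`. Significance is the binomial tail under the coverage-fraction
null — upper tail when FE ≥ 1, lower otherwise — doubled and capped at 1 for
a two-sided report, then BH-adjusted across states. A state covering the
whole genome has FE = 1 identically.

## Developmental quartile atlas

The two cell types' peaks are unioned and merged (gap 0); a merged region's
replicate counts are the sums over its constituent peaks. log2FC of cell
type B over A uses size-factor-normalized means with pseudocount 1, which
bounds fold changes at zero counts. Regions are sorted ascending by
(log2FC, region id) and split into four parts whose sizes differ by at most
one — equal-count quartiles, consistent with printed quartile ranges rather
than fixed breakpoints. For the cluster-3 intersection, a peak counts in the
quartile of the region it overlaps by the most bp (ties toward the lower
quartile), so each peak counts once and proportions sum to ≤ 1.

## Differential accessibility

Normalization is median-of-ratios in the ratio scale (factor_j = median over
zero-free regions of count_ij / per-region geometric mean), rescaled to
geometric mean 1. The per-region test is Welch's t on
log2(normalized count + 1) with BH adjustment; a gain requires
log2FC > 0.5 **and** adjusted p < 0.05 (the loss rule is symmetric). The
adjusted-p cutoff is configurable.

Power characteristics, measured by simulation: under pure counting (Poisson)
noise at mean depth 100 and n = 3 + 3, planted 4-fold effects are recovered
with sensitivity ≈ 0.97 at observed FDR ≈ 0, and the null p < 0.05 fraction
is ≈ 0.04. Under additional biological overdispersion (negative-binomial
α = 0.05, the generator's replicate model) the per-region variance estimate
at n = 3 is too noisy for BH-corrected calls to retain that sensitivity
(≈ 0.2–0.5 depending on threshold) although precision stays near 1 — the
known cost of a simple per-region test versus dispersion-sharing engines,
accepted here because this package's contribution is the comparison design,
not the DE engine. The recovery tests assert sensitivity under counting
noise and precision under overdispersion accordingly.

## Super-enhancers

Peaks are stitched within 12.5 kb; each stitched region's rank signal is
max(0, Σchip − Σinput) as a per-bp track integral (clipping keeps regions
comparable when input exceeds chip). With ranks x and signals y scaled to
[0, 1], the cutoff is the largest index minimizing y − x — the tangent point
of a slope-1 line approaching the rank curve from below, i.e. where signal
begins to grow faster than rank. Regions strictly above the signal threshold
at that point are super-enhancers; on an exactly linear curve the tangent
degenerates to the top rank and nothing is called. The cutoff is invariant
to affine rescaling of the signal. Dense analytic curves give x* = 0.5 for
y = x² and x* = (1/4)^(1/3) ≈ 0.63 for y = x⁴. Affectedness of a
super-enhancer is the fraction of its overlapping ATAC peaks that belong to
cluster 3 (≥ 0.5 → affected; zero overlapping peaks → fraction 0, never
affected). ROSE's optional TSS exclusion is off by default.

## Hi-C loop strength and APA

Contact matrices are cis-only, per chromosome, symmetric, at fixed
resolution; triplet input is canonicalized to the upper triangle with
duplicates summed, then mirrored. A loop's pixel is the bin of each anchor
midpoint. The expected value at pixel (i, j) is the mean of the block
`{(a, b): i+p < a ≤ i+w, j−w ≤ b < j−p}` — below-left of the pixel, toward
the diagonal, excluding the (2p+1)² peak neighborhood — with defaults
p = 2, w = 5 at 10 kb. Strength is `log2((obs + 1)/(exp + 1))`; the
pseudocount defines strength at sparse pixels, and pixels whose window does
not fit (too near the diagonal or the matrix edge) are *undefined*, excluded
from fractions and reported as such. Because the local block lies nearer the
diagonal than the pixel, power-law decay biases the expected slightly high;
at the generator's decay exponent of 1 this shifts recovered strengths about
0.2–0.3 log2 units below log2(enrichment), which cancels in the two-condition
comparison since both conditions share the geometry.

Rewiring classification scores the **same** reference loop list in both
conditions and calls weakened when `strength_A − strength_B ≥ log2(1.5)`
(strengthened symmetric) — a 1.5-fold change of the observed/expected ratio.

APA averages the (2w+1)² observed/expected submatrix over loop pixels
(expected per entry from the matrix-wide distance-decay mean at that entry's
own offset; w = 10, p = 3 by default). P2LL is the center value over the
mean of the p × p lower-left corner block; 1 for structureless pixel lists,
> 1.5 for genuinely enriched loops.

## Enhancer–promoter assignment

The contact map is binned at 50 kb and bins containing at least one TSS are
indexed. "Interacting with a promoter bin" — undefined in purely verbal
descriptions of this method — is operationalized as: within 2 Mb, raw count
≥ 5, and observed over distance-decay expected ≥ 2; the promoter bin always
interacts with itself. All three thresholds are configurable. A peak (by
midpoint bin) inside any interacting bin is a candidate regulatory region of
that gene; with several candidate genes it goes to the promoter with the
highest interaction frequency, residual ties breaking by smaller bin
distance, then gene id — deterministic everywhere. Raising the O/E threshold
can only shrink the assigned set.

Per gene, the two conditions' assigned peaks are matched by ≥ 1 bp overlap:
matched pairs are *common*, unmatched peaks *unique* to their condition, and
the gene is differentially regulated iff more than two peaks are unique to
either condition (at least three condition-specific regulatory regions). A
distance-based variant of the same classifier is available by composing
`nearest_tss` with `classify_gene_regulation` when no contact map exists.

## The synthetic generator

Defaults define the study scale: 2 chromosomes × 20 Mb, 300 genes, 3,000
peaks (30 % promoter, 20 % gene-body, 50 % distal; half the distal peaks
form the affected low-signal class), class signal means 10/3/0.5 with
Gaussian sd 0.2, mutant multiplicative loss 0.5 on affected peaks, 3
replicates per condition with negative-binomial counts
(variance μ + αμ², α = 0.05, mean = 10 × signal). Gene promoters occupy
distinct 50 kb bins — a simplification that makes the planted peak→gene map
unambiguous at the assignment resolution. Contact maps decay as
(d+1)^(−1) with Poisson counts (≈ 1,000 expected at the first off-diagonals
of the 10 kb maps, emulating deeply sequenced merged replicates); 200 loops
at 200 kb–1 Mb span carry a 5-fold pixel excess, and 20 % of them are
divided by 3 in the mutant map. The planted enhancer→gene map boosts one
(peak-bin, promoter-bin) pixel per used distal bin; 30 % of genes are
rewired by turning whole (gene, bin) units off in the mutant and adopting
nearby reserve units as mutant-only, so condition-exclusive counts reach the
> 2 rule. The two-timepoint design plants 10 % gains and 10 % losses at
4-fold, 40 % of each shared between genotypes.

What the generator does **not** emulate: read-level artifacts (GC bias,
duplicates, mappability), irregular peak-width and signal distributions,
correlated replicate structure, domain/compartment organization in Hi-C,
balancing-weight artifacts, or trans contacts. Recovery on this generator
therefore demonstrates the correctness and calibration of the decision rules
under the assumed noise models, not end-to-end performance on sequencing
data.

## Numerical and reproducibility choices

Every stage's randomness derives from one seed expanded through fixed
per-purpose stream ids (`default_rng([seed, stream])`), and loop positions
are drawn on a condition-independent stream so both conditions share
coordinates exactly. Tables are written atomically (temp file + rename) with
a fixed float format, so identical config + seed reproduces outputs
byte-for-byte. Degenerate inputs are defined, not special-cased ad hoc:
all-equal rank signals raise (no tangent exists); super-enhancers without
ATAC peaks are unaffected; loops without a fitting window are undefined;
genes without assigned peaks are absent from the regulation table; size
factors require at least one zero-free region and otherwise direct the
caller to a pseudocount.

## Limitations

- The Welch-based differential engine trades power for simplicity at n = 3
  under strong overdispersion (quantified above).
- The tangent cutoff assumes a convex upper tail of the rank curve; rank
  curves with several inflection points can place the cutoff at a local
  rather than global transition.
- Enhancer–promoter assignment inherits the 50 kb bin resolution: peaks and
  promoters in one bin are indistinguishable, and a peak sharing a bin with
  any promoter is attributed to the resident gene.
- Loop strength at very sparse pixels is pseudocount-dominated; the +1
  default shrinks strengths toward 0 at low coverage.
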