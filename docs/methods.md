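# Methods

This note documents the models, parameter choices, numerical details
and limitations of `scse`. Coordinates are 0-based half-open
everywhere; GTF input is converted on read.

## Consensus enhancer calling

Each single cell's peak profile is treated as an independent dataset
whose quality is judged by its similarity to the other cells of the
same type. Similarity is the Tanimoto coefficient on raw count vectors
(not binarised profiles): binarisation discards quantitative
accessibility information, and the coefficient degrades gracefully to
the Jaccard index when the data happen to be binary. The full m×m
matrix is computed from the cells×cells Gram matrix of the sparse
counts; the peaks×peaks product is never formed. For very large m,
`tanimoto_matrix(max_cells=..., seed=...)` subsamples cells before the
O(m²) step.

The weight of cell t sums its off-diagonal similarities and is
normalised by the sum over **all ordered pairs** i ≠ k. The
normalisation choice matters: it makes weights sum to exactly one, so
consensus peak signals are weighted means on a fixed scale and
comparable across cell types. Two all-zero profiles get similarity 0
(with a warning); if every pair is dissimilar the weights fall back to
uniform.

"Signal in at least one-third of cells" is evaluated as
`support ≥ ceil(m/3)` on the count of cells with a nonzero entry —
the conservative reading of "at least one-third" on an integer count.
Raw counts (not depth-normalised values) enter the consensus signal,
matching the count-based stance of the rest of the pipeline; per-cell
normalisation can be layered on by transforming the matrix first.

The shuffle null relocates every peak uniformly at random within its
own chromosome, preserving width and allowing overlaps among relocated
peaks — the minimal reading of "shuffling across the entire DNA
sequence". Per replicate and peak the weighted consensus signal is
recomputed from the fragment file; the criterion-iii threshold is the
95th percentile of the pooled null over 20 replicates (the replicate
count is a package default chosen for a stable 95th percentile at desk
scale; the procedure pools all replicates rather than averaging
per-replicate percentiles). The null is pooled across peaks rather
than matched per peak width; per-width matching would be a
straightforward refinement but changes little when peak widths are
homogeneous. Without a fragment file criterion iii cannot be evaluated:
it is flagged as skipped (passed) with a warning rather than silently
failing every peak.

Promoter windows are strand-aware [TSS−2000, TSS+100): the 2 kb
upstream distance mirrors the gene-activity promoter window and the
100 bp downstream guard protects the TSS itself.

## Co-accessibility

The count matrix is TF-IDF transformed
(`ln(1 + (count/cell_total) · (m/n_cells_with_peak) · 10⁴)`), embedded
by truncated SVD (ARPACK, deterministic under the given seed; signs
fixed so each component's largest-magnitude coordinate is positive),
and component 1 is dropped from downstream use as depth-correlated.
UMAP is available for 2-D visualisation with a fixed seed; the pipeline
itself aggregates metacells on the retained LSI coordinates (the
documented `method="lsi"` fallback equals the first two retained
components exactly), which keeps end-to-end runs deterministic and
independent of numba thread scheduling.

Metacells are k-nearest-neighbour groups around seed cells visited in
seeded random order; a candidate is rejected when it shares more than
`max_overlap · k` members with an accepted metacell (defaults k = 50,
max_overlap = 0.8, the published defaults of the co-accessibility tool
this stage follows). Inside `run_all` k is additionally capped at
n_cells/5 so that small sub-populations still yield the ≥ 5 metacells
the covariance estimation needs.

Counts are depth-normalised per metacell and unit-variance scaled per
peak (constant peaks are excluded); the genome is tiled into windows of
width 2·d_max stepped by d_max (d_max = 500 kb human/mouse default,
100 kb fly — the fly value is a package choice scaled to its genome,
config-overridable), and within each window a graphical lasso is
solved with off-diagonal penalty `ρ_ij = scale · d_ij / d_max`, and
`ρ_ij = ∞` beyond d_max (pair forced to zero). The solver is a block
coordinate-descent graphical lasso written in this package because an
element-wise penalty matrix is required; a scalar-penalty library
implementation serves as the cross-check oracle in the tests
(agreement to 2e−3 at uniform penalty). Non-convergent windows are
skipped with a warning. The default `penalty_scale = 1.0` was
calibrated so that background-only simulated windows (independent
peaks, 100 metacells) retain roughly ≤ 10% nonzero off-diagonal
entries. A pair falling into two windows keeps the score from the
window whose centre is nearest the pair midpoint — deterministic and
simple; averaging would be a defensible alternative.

Scores are partial correlations, `−Θ_ij/√(Θ_ii Θ_jj)`, clipped to
[−1, 1]. One caveat observed in testing: at small metacell counts a
*stronger* penalty can push an individual background partial
correlation across the 0.1 line non-monotonically (zeroing a
neighbouring edge removes a conditioning variable). Sparsity
monotonicity therefore holds in the well-sampled regime but is not a
pointwise guarantee.

An enhancer–promoter link requires exactly one pair side overlapping a
promoter window and score ≥ 0.1; the gene is taken from the promoter
side, one link per overlapped gene.

## Super-enhancer calling

Candidates (narrowPeak input, or the matrix peak set) are stitched
left-to-right per chromosome while `next.start − current.end ≤ d`
(d = 12.5 kb human/mouse, 2 kb fly). Stitching is idempotent and
member-conserving. A region's signal is the summed `count` field of
fragments (from the cell type's barcodes) overlapping it by ≥ 1 bp —
the discrete form of integrating the coverage track; a fragment
spanning two regions contributes to both, and duplicate collapsing is
available upstream by feeding deduplicated fragment files. No
control-track subtraction is applied (no control exists for scATAC
fragments). TSS exclusion before stitching is available as an option
(default off, 2.5 kb windows).

The rank curve sorts signals ascending and min–max scales both axes to
[0, 1]. The published "slope equals 1" inflection is operationalised
exactly as the lower slope-1 tangent of the scaled curve:
`cutoff_index = argmin(scaled_y − scaled_x)`, ties broken toward the
largest index (most stringent). A consecutive-point slope with
denominator R_i − R_{i+1} is sign-ambiguous for ascending ranks; the
tangent formulation is the standard geometry and is verified in the
tests against an exhaustive anchor-checking oracle. A flat curve
degenerates to a cutoff at the top and zero super-enhancers.
Classification is strict (`signal > cutoff_signal`), so the tangent
region itself is never a super-enhancer; calls are retained only when
they overlap a typical enhancer of the same cell type by ≥ 1 bp.

## Gene markers

Gene activity sums peak counts over the strand-aware window
gene body ∪ 2 kb upstream; a peak in two genes' windows counts toward
both. Normalisation is per-cell log-normalisation with scale 10⁴
(the convention of the marker-finding tooling this stage mirrors; the
source procedure states only that the matrix is normalised). Marker
detection is one-vs-rest per cell type: prefilters
`pct_in ≥ 0.3` and `log2((mean_in+1)/(mean_out+1)) ≥ 0.585` on
de-logged normalised means (pseudocount 1 keeps the ≈1.5× threshold
interpretable and guards zero denominators; whether the published fold
change used raw or normalised means is unstated — de-logged normalised
means were chosen), then a two-sided Wilcoxon rank-sum test (normal
approximation with tie correction) with Bonferroni adjustment over the
genes actually tested within that type. Markers satisfy adjusted
p < 1e−5. At least three annotated cell types are required; the
pipeline skips the stage with a warning below that.

## Overlap statistics

N is the number of maximal merged regions in the bp-union of both
interval sets; K and n are the raw set sizes and k the overlap count at
≥ 1 bp (a reciprocal-fraction mode is available). Both the
hypergeometric point mass `C(K,k)·C(N−K,n−k)/C(N,n)` and the upper tail
P(X ≥ k) are returned; the tail is reported as the significance, since
a point mass is not a valid enrichment p-value — the source procedure
prints the point-mass formula but reports tail-like values, and this
package surfaces both rather than hiding the discrepancy. Computation
is scipy's log-space hypergeometric, verified exhaustively against
exact integer enumeration for N ≤ 30. Overlap percentages use half-up
rounding to two decimals. Jaccard similarity is base-pair-level on
merged sets (split-invariant by construction). Signal comparison
between overlapping and non-overlapping sets reports
log2(mean ratio) and a two-sided Welch t-test (equal-variance option
available). Inputs must share a genome assembly; no coordinate
conversion is performed.

## Synthetic data

The generator emulates the statistical structure the pipeline assumes:
sparse nonnegative integer counts with per-cell depth variation
(Gamma-mixed Poisson, i.e. negative-binomial-like overdispersion),
cell-type-specific accessible peaks, planted SE clusters (8 peaks at
1 kb spacing, below the stitch distance), promoter-proximal peaks tied
to planted marker genes, and a fragment file whose in-peak fragments
exactly account for the matrix counts (background fragments are placed
only in guaranteed peak-free zones, so the file total equals the matrix
total plus the background count — asserted in tests).

Default study conditions: 2 cell types × 150 cells, 30 planted
type-specific enhancers per type, signal multiplier 8 over accessible
background, closed-peak leak-through probability 0.01, ~800 in-peak
fragments per cell plus 5% background. Each planted enhancer is paired
with a marker gene ~20 kb away whose promoter peak co-varies with it
through a shared per-cell Gamma latent factor — this provides the
promoter co-accessibility that criterion iv requires and makes the
planted pairs the strongest scores in their windows. Planted loci are
spaced ≥ 1.2 Mb apart on two chromosomes so each co-accessibility
window sees one structure; background pairs (two shared peaks 200 kb
apart, far from genes) exercise the glasso noise floor. Realized SE
signal is sanity-checked at generation time against
multiplier × background within three standard errors computed over
per-cell means (cells are the independent units; the latent factor
correlates a cluster's peaks within a cell).

What the simulation does **not** emulate: Tn5 sequence bias, read-level
data, doublets, batch effects, genome-scale peak density, overlapping
regulatory domains, or distance-decaying contact structure. Passing
recovery tests therefore demonstrates the pipeline's correctness and
calibration under its own assumptions, not performance on real tissue
atlases.

## Pipeline, determinism and problem sizes

`run_all` executes preprocess → per-type co-accessibility → consensus
enhancers → super-enhancers (when fragments are present) → markers →
optional overlap report, writing TSV/BED tables and a `manifest.json`
with version, seed, all parameters and per-stage counts. One global
seed fans out to per-stage seeds via `SeedSequence(seed, crc32(tag))`,
so stages are reproducible independently; gzipped outputs are written
with zeroed mtime so identical runs are byte-identical. QC thresholds
default to the published values (cells < 200 peaks, peaks < 10 cells or
on mitochondrial/scaffold-like chromosomes, cell types < 100 cells,
strict inequalities); desk-scale synthetic runs override the per-cell
peak minimum since the simulated peak universe is a few hundred peaks.

Tests and the acceptance script run simulations of 300–450 cells and
150–250 peaks with 3–10 seeds per property; these sizes were chosen so
the whole suite completes in a couple of minutes while keeping every
recovery margin wide (observed recall/precision are 1.0 at the default
conditions, against thresholds of 0.8–0.9).

## Known limitations

- Criterion iii uses a pooled null over all peaks; a per-width matched
  null is noted as an option but not implemented.
- The O(m²) Tanimoto matrix is exact by default; subsampling beyond
  `max_cells` trades exactness for memory at very large m.
- Window-based glasso scores depend mildly on window placement for
  pairs near window edges (nearest-centre stitching resolves ties
  deterministically).
- The hypergeometric universe counts merged union regions, which makes
  N depend on the fragmentation of both sets; this matches the stated
  definition but means N is not invariant to splitting reference
  intervals.
- liftOver-style assembly conversion, BAM parsing, peak calling and
  doublet detection are out of scope; inputs must already share a
  coordinate system.
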