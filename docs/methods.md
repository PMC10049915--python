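# Methods

`chromoswitch` analyses how a genome's three-dimensional chromatin
organization differs between two conditions — a control (CK) and a treatment
(PD, phosphorus-deficient in the motivating system) — from binned Hi-C
contact matrices, and relates the structural changes to gene expression and
active histone marks (H3K4me3, H3K27ac). This note describes the models and
procedures, the synthetic data that the tests run on, and the numerical
choices that were genuinely open.

## Contact-matrix model and balancing

A contact matrix over uniform bins is stored as its upper triangle; symmetry
is implied. Balancing follows iterative correction under the equal-visibility
assumption: each bin i carries a multiplicative weight b_i and the balanced
matrix W_ij = M_ij · b_i · b_j is iterated (weights divided by normalized
balanced marginals) until the maximum relative deviation of unmasked row sums
falls below `tol` (default 1e-5, `max_iter` 200). Bins with zero coverage, or
nonzero coverage below median − 3·MAD of the nonzero marginals, are masked
before iteration and excluded from every downstream statistic. After
convergence the weights are rescaled so unmasked rows sum to 1. A
non-converged run returns the last iterate with `converged=False` and a
warning rather than failing.

The MAD mask is worth a word: on simulated genomes it removes bins near
chromosome ends (whose short-range contact mass is truncated) and bins at
sharp compartment transitions. That is the intended behaviour — those bins
have genuinely unequal visibility — but it means planted features adjacent
to chromosome ends are not recoverable, and the simulator keeps its loop
anchors at least 150 kb from the ends for that reason.

## Expected profile and observed/expected scores

The cis expected value at bin separation s is the mean balanced value over
unmasked pairs at that separation (zeros included), optionally lowess-smoothed
in log–log space with fraction `span` (default 0.3; `span=0` disables
smoothing; empty strata are interpolated from neighbours in log–log space).
The serialized O/E score is log2(W_ij / E(|i−j|)); pixels with zero observed
are omitted from the sparse map rather than being written as −inf.

Two numerical caveats drove design decisions here:

- **Correlation input.** The compartment correlation map is computed from the
  *linear* O/E ratio with zero-observed pixels included as 0, not from the
  present-only log2 map. At realistic desk-scale depth most of the
  checkerboard signal is carried by which pixels are empty; correlating only
  the present pixels reduces label recovery to chance, while the linear ratio
  recovers planted labels almost perfectly.
- **Expected for loop backgrounds.** The loop caller's λ estimates use the
  unsmoothed per-distance means. On genomes with domain structure the decay
  curve has a kink at the domain scale that lowess flattens, which
  underestimates local λ by up to 2× and floods the caller with spurious
  near-diagonal calls. Smoothing remains the default for the O/E and
  compartment path, where only relative per-bin profiles matter.

## A/B compartments and switch regions

Per chromosome, the Pearson correlation map of O/E bin profiles
(pairwise-complete over unmasked bins, unit diagonal) is eigendecomposed and
PC1 is its leading eigenvector. The sign of an eigenvector is arbitrary, so
PC1 is oriented per chromosome to correlate non-negatively with gene density
(ties resolved by making the vector sum non-negative); the gene-rich class is
then A by construction, matching the biological convention that A is the
active, gene-dense class. The label rule is strict: A iff PC1 > 0, otherwise
B; bins with undefined PC1 (masked, or a degenerate all-equal correlation
matrix) are left unlabelled and excluded from denominators.

Switch regions are maximal runs of adjacent bins whose label flips in the
same direction between conditions (CK=A, PD=B → A2B; CK=B, PD=A → B2A),
never crossing a chromosome boundary; bins masked in either condition break
runs. Region counts are reported per direction. Swapping the two input
tracks maps every A2B region to an identical B2A region — this mirror
property is asserted in the tests.

## Insulation scores and TAD boundaries

The insulation score of bin b is the mean balanced contact in the diamond
window between the w bins to its left and w to its right (central row and
column excluded; masked pixels ignored), log2-normalized by the chromosome
mean of the diamond means, so the chromosome mean of 2^score is 1 and global
matrix rescaling cancels exactly. Scores are defined only where the full
window fits.

Boundaries are local minima of the score after a NaN-aware centred moving
average (half-width 2 bins); strength is the mean, over both sides, of the
highest smoothed score within `delta_window` (default 100 kb) minus the
minimum, and boundaries below `min_strength` (default 0.1 in log2 units) are
dropped. Of two surviving minima closer than `delta_window`, only the deeper
is kept. The default window is 200 kb: the diamond must fit inside a domain
to contrast it against its neighbour, and plant TADs are sub-megabase — with
300 kb domains a 500 kb window blurs adjacent boundaries (recall drops from
~0.92 to ~0.79 on the standard simulation). TAD intervals are the spans
between consecutive boundaries and chromosome ends, so they tile each
chromosome exactly.

## Loop calling and differential loops

The caller is a single-resolution donut filter. For each cis pixel with
separation between `min_dist_bins` (default 2) and 2 Mb, four local
neighbourhoods are formed from offset masks (outer half-width 5, inner
exclusion 2): the donut annulus, the lower-left quadrant, and horizontal and
vertical stripes. The local expected is the neighbourhood's balanced sum over
its decay-expected sum, times the pixel's decay expected, divided by
b_i · b_j to return to raw-count scale; significance is the exact Poisson
upper tail of the raw count (no λ-chunking — at desk scale the exact tail is
cheap), with BH-FDR applied within log2-spaced distance strata separately per
neighbourhood. A call requires q ≤ `fdr` (default 0.1) against all four
backgrounds, enrichment ≥ 1.5 over the donut and lower-left, and a raw count
of at least 4 — without the raw-count floor, sparse far-diagonal strata
produce near-zero λ estimates that make single-count pixels "significant".
Adjacent called pixels merge into one loop at their count-weighted centroid.

On genomes with compartment or domain structure the caller also reports foci
at domain corners and at the corners of condition-specific compartment
blocks. These are genuine local contact enrichments, not statistical errors;
the false-discovery benchmarks therefore run on decay-only backgrounds, and
the recovery benchmarks plant point loops on such backgrounds.

For differential analysis the CK and PD call sets are merged (anchors within
1 bin in both coordinates are the same loop), each merged loop is scored per
condition by its centre-pixel linear O/E (a 3×3 footprint is available via
`footprint_half`, but a point loop of factor 8 is diluted to ~1.6× by the
3×3 mean, which would misclassify planted differential loops under the
|log2FC| ≥ 1 rule), and classified enriched / depleted / stable at
|log2(OE_PD/OE_CK)| ≥ 1. A loop observed in exactly one condition at the
centre pixel is classified by the sign of that one-sided evidence; a loop
with no usable O/E in either condition is `unscored`. The call-set partition
(common / CK-specific / PD-specific) is reported alongside, since specificity
by call set and by fold change are different notions. Anchors overlapping a
gene (≥ 1 bp, half-open) are proximal, otherwise distal, giving loop styles
P-P / D-P / D-D; anchor-mark fractions count unique anchors once.

## Integration statistics

Genes are assigned to bins by midpoint. Gene density (per-bin gene counts)
and expression (per-gene mean FPKM) are compared between A and B bins with a
two-sided Wilcoxon rank-sum test; histone marks are compared as per-bin peak
coverage in bp (peak unions, so coverage is conserved). The DE flag applied
throughout is |log2FC| ≥ 1 and adjusted p < 0.05, evaluated on statistics
consumed from the input table — the package does not re-fit a DE model.
Condition-specific peaks are defined by overlap alone: a peak is specific iff
it intersects no peak of the other condition. GO enrichment is the exact
hypergeometric upper tail per term over a flat gene→term map (no DAG
propagation), BH-adjusted, significant at adjusted p < 0.05. The Wilcoxon
test is exact (full enumeration) for pooled samples up to 20 without ties and
the normal approximation with continuity and tie corrections otherwise; all
pooled values identical returns p = 1 by convention.

All interval operations (gene/anchor/peak/region) go through one shared
engine with 0-based half-open semantics, cross-checked in the tests against
a naive quadratic oracle.

## The synthetic-data generator

The simulator emulates the *structure* of a two-condition chromatin
reorganization study, with every planted feature recorded for recovery
scoring. Expected cis counts at separation s ≥ 1 bins are

    μ(i,j) = depth · s^(−α) · c(i,j) · t(i,j) · l(i,j),

with Poisson noise; trans contacts are structureless Poisson background.
Compartments are alternating 500 kb A/B blocks; same-label pairs are
multiplied by the compartment factor m and cross-label pairs divided by it
(m = 2 by default). Condition PD flips the label inside 10 planted 100 kb
switch regions centred inside blocks. TADs are 300 kb blocks whose internal
contacts are multiplied by 3. Loops multiply single anchor pixels by 8;
anchors sit on the bin grid, 50–100 kb apart and ≥ 150 kb from chromosome
ends — at the default depth (20–30 expected counts per bin pair at s = 1 bin)
the Poisson donut test only has power where the decay background is at least
a few counts, which is also why real loop catalogues are depth-limited in
distance. The standard genome is two 5 Mb chromosomes; analyses run at 20 kb
(compartments), 10 kb (insulation) and 5 kb (loops), each resolution
simulated from the same planted structure.

Genes occupy the central half of a bin with probability 0.8 in A bins and
0.4 in B bins (the 2:1 density ratio the compartment orientation relies on).
Per-gene log2 expression is Normal(5, 1) shifted by +1 in A bins under each
condition's own labels, with three replicates at σ = 0.15; FPKM = 2^log2.
The DE table is planted by construction: genes in B2A switch regions are
up-regulated and A2B down-regulated (|log2FC| = 1 + half-normal, adjusted
p < 0.01), plus 40 random DE genes elsewhere; all other genes receive
sub-threshold statistics. Peaks are placed per bin at rate 0.15 in B and
3× that in A (per condition's labels, so switch regions change marks with
the flip); loop anchors carry a correlated pair of mark assignments such
that 63% of anchors carry at least one mark and 30% of those carry both.
All randomness derives from one master seed through hashed, named
sub-streams, so each track is independently reproducible.

What the generator does **not** emulate: read-level artefacts
(ligation/duplicate structure, restriction-fragment geometry, mappability),
overdispersion beyond Poisson, replicate structure, distance-dependent loop
strength, compartment strength gradients, or any mechanistic trans
structure. Passing recovery tests therefore demonstrates that the estimators
invert this generative model at realistic depth — not that they are robust
to every artefact of real libraries.

## Problem sizes and determinism

The test and acceptance workloads use the standard 2 × 5 Mb genome (500 bins
at 20 kb, 2 000 at 5 kb), chosen so a full two-condition pipeline run takes
tens of seconds and the whole suite a few minutes. Recovery rates at these
sizes are the package's own benchmark conditions; larger genomes only
tighten the statistics. Pipeline runs are deterministic given config and
seed — reports contain no timestamps, outputs are written atomically
(temp-file + rename), and a rerun is byte-identical.

## Known limitations

- Poisson noise understates the variance of real Hi-C counts; FDR calibration
  on real libraries will be somewhat optimistic.
- The compartment caller assigns whole bins; sub-bin switch boundaries are
  rounded, and one- to two-bin dilution at switch-region edges is visible at
  small region sizes.
- Loop calls on structured genomes include domain-corner foci (see above).
- The per-chromosome cis-fraction attributes each trans contact to both of
  its chromosomes; other conventions exist and change per-chromosome values
  (not the genome-wide fraction).
- GO enrichment ignores the term DAG and tests terms independently.
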