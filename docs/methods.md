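# Methods

This note documents the models and procedures implemented in
`chromascreen`, the parameters that matter, what the synthetic data do and
do not emulate, and the numerical choices made where the design was open.

## Coordinate and data conventions

All genomic coordinates are 0-based half-open; GFF-like input (1-based
inclusive) is converted at the I/O boundary. Contact matrices are
intra-chromosomal, symmetric, and binned at a fixed resolution (100 kb in
all defaults); bin `i` spans `[i*res, min((i+1)*res, chrom_length))`.
COO-format contact text may list each unordered pair once (it is
mirrored); duplicate pairs are summed, matching how binned pair lists are
accumulated. Only cis matrices are handled: all the structures analyzed
here (compartments, TADs, loops) are cis features.

## Distance normalization

Contact frequency decays roughly as a power law in genomic distance, so
all comparisons are distance-stratified.

*Expected profile.* `e(d)` is the mean count over the d-th diagonal.
Pairs at a distance with no data give NaN.

*O/E.* `OE_ij = C_ij / e(|i-j|)`. By construction every diagonal of O/E
has mean 1 (the conservation property the tests assert), and O/E is
invariant to global count scaling.

*Lowess z-scores.* Per-distance means and standard deviations are
lowess-smoothed (frac 0.3, no robustness iterations) in **log10 intensity**
against **log10(1+d)**. A power-law decay is exactly linear in that space,
so the local-linear smoother reproduces it without edge bias; fitting the
raw means against log-distance instead leaves a multi-sigma short-range
bias because the decay curve is exponential in log-d. With `it=0` the
smoother is linear in log-counts, which makes z exactly invariant to
rescaling all counts — sequencing depth cancels. Smoothed standard
deviations are floored at `sigma_floor` (1e-8) to keep z finite on
degenerate strata. Bins with zero marginal coverage are masked (all-NaN
rows/columns) and propagate through differences. The differential matrix
is simply `z_treat - z_control`.

Calibration: on pure-decay Poisson fixtures the per-stratum z means are
within 0.15 and the standard deviations within 0.2 of 1. Because a
stratum of n pairs estimates its mean only to ~1/sqrt(n), the calibration
test pools z values across three seeds per stratum (400-bin matrices,
d ≤ 200), which is the smallest design that can resolve those tolerances
at all; a single-seed maximum over 200 strata would exceed them under a
perfect normalizer.

*Reproducibility.* Replicate concordance is a distance-stratified weighted
Pearson correlation: r is computed separately on each diagonal
d = 1..20 (degenerate strata skipped) and combined with weights equal to
the number of finite pairs. Stratifying prevents the universal decay from
inflating the score; structureless matrices score ~0, identical matrices
score 1. This is a deliberately simple concordance score with the same
contract (a value in [-1, 1], higher for replicates than for permuted or
cross-condition pairs) as random-walk-based methods.

## Compartments

PC1 is the leading right singular vector of the column-centered Pearson
correlation matrix of unmasked O/E columns (NaN-aware correlations; bins
with no variance are treated as masked). The eigenvector sign is
arbitrary, so it is oriented by the standard biological covariate: gene
density. If the correlation between PC1 and per-bin gene-midpoint counts
is negative the vector is flipped; on an exact tie (e.g. no annotation)
the orientation with frac_A ≤ frac_B is chosen, encoding the prior that B
typically dominates. Labels are A for PC1 > 0, B for PC1 < 0, NA for 0 or
masked.

Transitions between two samples are per-bin joint labels (A2A, A2B, B2A,
B2B; NA if either side is NA). Because published counts of "stable" and
"switching" compartments are ambiguous between bins and contiguous
segments, both units are always reported.

## TADs

The insulation score of bin i is
`log2(w_i / mean(w))` with `w_i` the mean count over the
`window x window` square upstream-by-downstream of i (window default
5 bins = 500 kb at 100-kb resolution, the canonical insulation scale; the
window is configurable). Scores are NaN within one window of the
chromosome ends. Boundaries are strict local minima; their strength is
the mean of the maximum score on each side within the window minus the
score at the minimum, and calls below `min_strength` (default 0.1 log2
units) are dropped. Cross-sample boundary comparison uses greedy
nearest-first matching within ±1 bin, each boundary matched at most once.
Boundary pileups average O/E submatrices (not raw counts) so the
within-TAD versus cross-TAD corner contrast is not confounded by distance
decay.

## Loops

For every pair with separation in [2, 100] bins, the local expected is
`e(d)` rescaled by the mean O/E over a donut annulus
(`inner 2 < Chebyshev radius ≤ outer 5`, same-row/column cross excluded
because stripes travel along rows/columns). The observed count is tested
against `Poisson(lambda_local)` (upper tail), q-values are
Benjamini–Hochberg over all tested pairs, and calls require p ≤ 0.01,
q ≤ 0.01 and observed/expected ≥ 2. The enrichment floor suppresses
significant-but-tiny effects on deep matrices. Pairs whose annulus falls
entirely outside the matrix are skipped. Counts are treated as
integer-valued (rounded) for the Poisson tail. Calls made at several
resolutions are merged in bp midpoint coordinates: calls whose anchors
both lie within the coarsest involved resolution are clustered (single
linkage) and represented by the smallest-q member.

On pure-decay null matrices the caller makes no calls in ≥ 9/10 seeds; on
matrices with realistic TAD/compartment structure it does report corner
and plaid enrichments beyond the planted loops — without lambda-chunked
local corrections that overcalling is inherent to the donut filter and is
the reason locus-level loop counts are treated as annotations rather than
decisions in the screen.

## Differential expression

Welch t-tests on log2(CPM+1), per stage comparison, with
`log2fc = log2((mean CPM_a + 0.5) / (mean CPM_b + 0.5))` and BH adjustment
within each comparison. A gene is up if log2fc ≥ 1 and padj ≤ 0.05 (down
symmetrically). Up/down sets for the screen are unions over the stage
comparisons. The t-test keeps the package free of a count-model
dependency; precomputed DEG tables can be substituted upstream of the Venn
without changing anything downstream.

## Coexpression network

All network operations run on log2(count+1). The unsigned adjacency is
`|cor|^beta`; beta is the smallest power whose signed scale-free fit index
reaches 0.8, else the argmax over powers 1..20. The fit index discretizes
connectivity into 10 equal-width bins and regresses log10 frequency on
log10 mean connectivity; R² is signed by the negated slope so only
decreasing relationships (the scale-free signature) score positively, and
a perfectly flat frequency profile scores 0.

TOM follows the standard unsigned formula
`TOM_ij = (Σ_{u≠i,j} a_iu a_uj + a_ij) / (min(k_i,k_j) + 1 − a_ij)`,
implemented with matrix products and verified against a triple-loop oracle
to 1e-10. Modules come from average-linkage clustering of `1 − TOM` with a
**static cut at absolute dissimilarity 0.99**: unrelated genes sit at
dissimilarity ≈ 1 and splinter into unassigned singletons, while genuine
modules attach internally far below the cut. (A cut at a *quantile of the
merge heights* was tried first and fails structurally: unrelated-gene
merges crowd the top of the dendrogram, so any high quantile lands above
the module attachment points and returns one giant module.) Clusters of
≥ 15 genes become modules, numbered by decreasing size; everything else is
label 0.

Eigengenes are the first principal component of the standardized member
expression, unit variance, sign-oriented to correlate positively with the
module's mean profile. Modules whose eigengenes correlate above 0.75 are
merged iteratively (highest pair first, eigengenes recomputed after every
merge; module count strictly decreases, so the loop terminates). Module–
trait relationships are Pearson r with two-sided Student t p-values,
reported raw (no multiplicity correction, mirroring default practice for
module–trait tables). kME is the gene-to-eigengene correlation; hub genes
are assigned members with |kME| > 0.8.

## The screen

Switching segments (A2B, B2A by default) are expanded by ±3 Mb, clipped to
the chromosome, and genes with half-open interval overlap are collected
with their distance to the segment. The four-way Venn over {known, up,
down, windowed} is computed exactly (15 signature regions, disjoint,
covering the union). The default candidate signature is
`windowed ∩ (up ∪ down) ∩ known` — both motivating hits were
pathway-annotated genes — with a flag to relax to `windowed ∩ DEG`.
Candidates and all other Venn members are annotated with hub status, kME,
and the treat−control insulation difference at the gene midpoint and
loop-count difference in gene ± 100 kb; rows sort by evidence count, ties
broken lexicographically.

## Synthetic data

`make_contact_matrix` draws Poisson counts with intensity
`depth * (d+1)^-alpha * (1 + a*s_i*s_j) * tau^[same TAD] * rho^[near loop]`
— a power-law decay (alpha 1), plaid compartments (profile s in ±1,
strength a, default 0.3–0.4), block TADs (contrast tau 2), and 3x3 loop
boosts (rho 5). Poisson is the simplest noise model with the right
mean-variance coupling; overdispersion is a known omission. Passing a
matrix with no TAD boundaries means no domain structure (factor 1
everywhere), not one whole-chromosome domain.

`make_expression` builds log2-scale signals: baseline U(4,9) + module
loading x module factor + weak global background factor (per-gene loading
U(0.1, 0.3)) + planted differential offsets + N(0, 0.3) noise, exponated
to counts with a mild lognormal library factor. Module loadings fall
linearly from 0.95 (hubs) to 0.6 across members: the loading gradient plus
the background factor give the network the continuous, heavy-tailed
connectivity spectrum that real coexpression data show — with one-point
loadings and fully independent background genes the connectivity
distribution is two-point and the scale-free fit is both unreachable and
unstable. Defaults: 3 modules of 50/40/30 genes among 300, 5 hubs each,
36 samples (2 conditions x 3 stages x 6 replicates), and a redness trait
(0 throughout for green; 0.1/0.6/1.0 across stages for red) that drives
module 1 anticorrelated.

`make_study_fixture` assembles the full study: two chromosomes x two
conditions x two Hi-C replicates (default 300 bins each at 100 kb), gene
annotation biased 4:1 toward A bins, and expression for 600 genes. Chr2
carries a planted region that is B in the red condition and A in the green
one; the candidate gene sits inside it, is down-regulated in red at every
stage (log2fc −2), is on the known list, and is a hub of the
trait-anticorrelated module. Known-list decoys are deliberately
non-differential and outside the planted modules (module factors already
carry group structure, so a clean negative control must avoid them); DEG
decoys are outside the known list. The small scale (120 bins, 240 genes,
4 replicates) exists for fast tests; 4 is the smallest replicate count at
which the Welch/BH screen retains power at these noise levels.

What the generators do **not** emulate: overdispersed counts, batch or
replicate effects, unmappable/low-coverage bins, nested TADs,
resolution-dependent loop sizes, sequence content, and trans contacts.
Passing tests therefore demonstrate correctness of the machinery and
recoverability under the planted model, not performance on real libraries.

## Pipeline, determinism and problem sizes

`run_screening_pipeline` executes normalize → compartments → transitions →
tads → loops → degs → windows → venn → coexpression → rank, writing every
intermediate through the I/O layer and a manifest with the resolved
config, package version, chosen soft power and per-stage counts. There is
no randomness anywhere in the analysis path — all stochasticity lives in
the generators — so identical config + seed reproduces every artifact
byte-for-byte. Replicate matrices are pooled by summation before analysis.
The coexpression stage defaults to the full gene set rather than the DEG
subset: at synthetic-study scale the DEG subset is too small to carry the
planted module structure (configurable via `coexpression_genes: deg`).

Test and acceptance problem sizes are chosen so the whole suite runs in
well under a minute of compute on one CPU: 200–400-bin matrices,
≤ 600 genes, 10-seed recovery loops, five full pipeline runs in the
acceptance script. The TAD-recovery checks run at depth 400 (a deep
library, 8x the generator default): boundary prominence testing at the
default depth admits spurious weak minima, and the recovery contract is
about the caller, not about shallow-coverage robustness.

## Known limitations

- The loop caller has no lambda-chunked multiple-testing correction and
  overcalls corner/plaid enrichment on structured matrices; loop counts at
  a locus are annotations, not selection criteria.
- The static TOM cut at 0.99 assumes unrelated genes are near-orthogonal
  after soft-thresholding; extremely correlated backgrounds would require
  a dynamic cut.
- Module–trait p-values are raw; with many modules and traits they should
  be corrected downstream.
- Hi-C normalization offers no ICE/KR balancing; copy-number and
  mappability artifacts are out of scope.
- The DEG model is a two-group Welch test per stage, not a time-course or
  count model.
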