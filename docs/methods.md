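# Methods

Statistical models, parameter defaults, and numerical choices. All
defaults live in `omicord.pipeline.RunConfig` and are configurable from
YAML or the CLI.

## Study design

A time course with points 0, 0.25, 1, 4, 8, 13, 18, 24 hr; the 0 hr
sample is the control, and all quantities are log10 abundance ratios
versus it. The default design (`omicord.design.DEFAULT_DESIGN`) drops
the 0.25 hr point for RNA (emulating a failed-array scenario) and uses 3
technical replicates per platform. Profiles are defined over the treated
times; the control point, whose ratio is identically 0, carries no
information and is excluded.

## Differential calling

**RNA.** Intensities are quantile-normalized (rank-mean with tie
interpolation over columns; any missing cell is an error naming the
offending row/column). For every entity × treated time, a two-sample
t-test compares the log10 intensities of that time's replicates against
the 0 hr replicates. Benjamini–Hochberg correction is applied over the
flattened entity × time grid of p-values. An entity is significant when
some time point has both q ≤ `fdr` (default 0.05) and |log10 ratio| ≥
log10(`fold`) (default 1.5). The per-time `sig_<t>` columns use the same
conjunction and feed the time-domain enrichment.

**MS proteomics.** Peptide treated:control ratios are aggregated per
protein × time: log10 ratios are screened by an iterative two-sided
Grubbs test at `grubbs_alpha` = 0.05 (critical value
G = ((n−1)/√n)·√(t²/(n−2+t²)) with t = t₍1−α/2n₎,ₙ₋₂; skipped for n < 3),
and the surviving log10 ratios are averaged — i.e. a geometric mean on
the linear scale, which keeps calling symmetric between a ratio r and
1/r. Significance requires ≥ `min_peptides` = 2 peptides and ≥ 1.5-fold
at some time.

*Known limitation:* Grubbs has intrinsically low power at small n
because the statistic is bounded by (n−1)/√n; at n = 4 that bound (1.5)
barely exceeds the α = 0.05 critical value (1.481), so even huge
outliers escape. Measured removal rates for 5-SD outliers: ≈ 42 % (n=4),
69 % (n=5), 83 % (n=6), 90 % (n=7), 94 % (n=8).

**Western.** Per entity × time, the ratio is the median of the 3 × 3
pairwise treated/control replicate ratios (robust to one aberrant
replicate on either side); < 3 replicates per side is an error.
Significant when ≥ 1.5-fold at some time.

## Integration

RNA and protein differential tables are merged by symbol (an optional
probe→symbol map resolves many-to-one cases by keeping the probe with
the largest mean |log10 ratio|) over the intersection of their time
grids. `filter_complete` keeps pairs with no missing ratio at any shared
time. K-means (default, `n_init=10`, seeded) or average-linkage
hierarchical clustering groups the concatenated scaled RNA+protein
profiles into `k_clusters` = 6 groups.

## Concordance

Profiles entering all concordance statistics are scaled to mean 0, SD 1
(sample SD, n−1); constant profiles are flagged degenerate and excluded
with a warning.

**CCA.** Canonical correlations between the pairs × times RNA matrix and
protein matrix are computed by orthonormalizing each centered matrix via
SVD and taking the singular values of Uxᵀ Uy — numerically stabler than
solving the covariance eigenproblem, and verified against the
brute-force Sxx⁻¹ Sxy Syy⁻¹ Syx oracle to 1e-8. Scaled profile matrices
are rank-deficient by one (rows sum to 0), so the pipeline uses
`on_rank_deficient="reduce"`, which drops the null dimensions by pivoted
rank reduction (the behaviour of R's `cancor`); the strict mode raises
an error naming the collinear columns. The permutation test shuffles the
protein row pairing `n_perm` = 1000 times (a row permutation of the
orthonormal basis, so bases are computed once) and reports the add-one
p-value (1 + #{perm ≥ obs}) / (1 + n_perm) per rank, which is never 0.

**Spline F-statistics.** The basis is a cubic B-spline with `spline_df`
= 3 basis functions on the observed hours: with df = 3 there are no
interior knots and the first basis column is dropped, the intercept
being fit separately (the construction of R's `bs(t, df=3)`); interior
knots are placed at quantiles only when df exceeds the degree. For a
pair, the unconstrained model fits separate intercepts and separate
spline coefficients to the stacked scaled profiles (RSS_u), the
constrained model shares the spline coefficients (RSS_c), and the
intercepts-only model gives RSS_0. Then
F1 = ((RSS_c − RSS_u)/3)/(RSS_u/(2n−8)) tests shape equality and
F2 = ((RSS_0 − RSS_c)/3)/(RSS_c/(2n−5)) tests the shared shape against
flatness. The composite score is `a·F2 + b·F1` with defaults a = 1,
b = −1 (a > 0, b < 0 enforced); the negative-concordance variant refits
with the RNA profile negated. Higher composite_pos ⇒ stronger positive
concordance.

**Category statistics.** Coherence: one 4-parameter logistic curve of
scaled expression vs time is fit jointly to all member profiles of a
category (≥ 3 members) and compared to the constant model by F-test;
marks XX (p < 0.01), X (p < 0.05), NA on non-convergence. Concordance
enrichment: two-sided Wilcoxon rank-sum test of member vs non-member
composite scores over all scored pairs (exact distribution when the
total ≤ 25), direction = sign of the median difference.

## Network

A direct-interaction network keeps only database edges whose *both*
endpoints are in the root set (the differential entities). Graphs are
undirected; the same pair may carry several interaction types
(transcriptional, protein-interaction, phosphorylation, other), which
collapse to one simple edge holding the type set. `n_edges` counts typed
edges; `mean_degree_largest` is 2·(simple edges inside the largest
connected component)/its node count; hubs are the top-k degrees with
lexicographic tie-breaking; edge-type fractions are over typed edges.
`compare_integration` evaluates several root sets and their unions on
one database — union largest-cluster size is provably ≥ each
constituent's.

## Enrichment

Hypergeometric upper tail P(X ≥ k) = `hypergeom.sf(k−1, N, K, n)` with
N = platform background, K = category ∩ background, n = significant set,
k = overlap; optional BH correction across categories. Time domains are
early [0, 4], intermediate [8, 13], late [18, 24] hr (inclusive); an
entity joins a domain when significant at any time inside it, and the
domain enrichment uses the union background over platforms.

## Synthetic generator

Each entity's RNA and protein time profiles derive from true shapes in
the same 3-df cubic spline family the concordance model fits (knots from
the full time grid), anchored to 0 at t = 0. Pair classes (default 20 %
each): *concordant* — identical shapes; *lagged* — protein shape
evaluated at max(t − `lag`, 0), default lag 4 hr; *anticorrelated* —
negated protein shape; *independent* — separate random shapes; *null* —
flat. Exact class counts come from largest-remainder apportionment of
the fractions, randomly permuted. Shape coefficients are iid
N(0, `effect_sd` = 0.3); measurement noise is additive Gaussian on the
log10-ratio scale with `noise_sd` = 0.1 per replicate/peptide. Proteins
carry 1 + Poisson(3) peptides; with probability `outlier_rate` = 0.05 a
peptide observation gets a gross offset of ±(5–10)×noise_sd. Optional
per-entity, per-time protein `dropout` (pipeline default 0.1) exercises
the completeness filter. Western panels cover a subset of entities with
triplicate treated/control intensities. The interaction generator grows
a preferential-attachment graph (endpoint probability ∝ 1 + accumulated
degree, 5 designated hubs with starting weight 20), rejecting self-loops
and repeated pairs; each accepted pair draws one type from the mixture
*after* acceptance, so realized type fractions are an unbiased
multinomial sample.

Limitations: no raw spectra or probe-level data; technical replicates
are iid (no batch structure); noise magnitudes are not calibrated to any
instrument; and because independent pairs draw shapes from the same
3-dimensional smooth family, two independent shapes align by chance
fairly often (mean |r| ≈ 0.6 noiselessly), which bounds how cleanly any
statistic can separate "independent" from "concordant" labels.

## Numerical choices

- All randomness flows from a single integer seed; the pipeline derives
  per-stage seeds by fixed offsets and records them in the manifest,
  together with SHA-256 checksums of every output file.
- Linear algebra avoids explicit normal equations: CCA uses SVD bases,
  spline fits use `lstsq`.
- F-statistics with zero residual denominators are mapped through a
  tolerance so exact fits give inf/0 deterministically; a both-infinite
  composite is defined as 0.
- Text outputs are TSV/GMT/SIF/JSON with `\n` line endings for
  byte-stable checksums across platforms.
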