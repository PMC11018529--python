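# Methods

## Expression preprocessing

Raw counts are converted to TPM per sample: rate_g = count_g / length_g,
TPM_g = rate_g / Σ rates × 10⁶, so every sample column sums to 10⁶. Gene
length is an input column (bp); whether lengths are union-exon effective
lengths is upstream of this package. The expressed-gene filter retains
genes with TPM ≥ 1 in at least two samples and is applied on the
replicate-level matrix *before* replicate averaging — filtering and
averaging do not commute, and the pipeline order is fixed this way.
Replicate summaries are arithmetic means per tissue; pattern-level
analyses use log2(TPM + 1). Outlier replicate removal is exposed as an
optional step: iteratively drop the replicate with the worst Pearson
correlation (< 0.8 by default) to the centroid of its tissue-mates,
keeping at least two. This is a declared stand-in for the usual
by-eye hierarchical-clustering screen, which has no published numeric
rule.

## Homoeolog bias model

A triad (one gene per subgenome A/B/C) in one tissue is summarised by its
relative expression vector TPM_i / ΣTPM, defined only when ΣTPM > 0.5
(strict). The vector lies on the 2-simplex and is assigned the category of
the nearest ideal point (Euclidean distance):

| category      | ideal point       |
|---------------|-------------------|
| Balanced      | (1/3, 1/3, 1/3)   |
| X dominant    | 1 at X, 0 elsewhere |
| X suppressed  | 0 at X, 1/2 elsewhere |

Seven points (balanced + 6 biased) are the default; a six-point mode
(`include_balanced=False`) exists because some formulations count only the
biased categories. Distance ties within 1e-12 are resolved by a fixed
order (Balanced, then dominants, then suppresseds, alphabetical within
tier) and flagged. The scheme is label-permutation equivariant and covers
the whole simplex.

Scalar summaries use a pseudocount of 0.01: pair log-ratios
log2((TPM_x + 0.01)/(TPM_y + 0.01)) and the per-subgenome log deviation
log2(((TPM_i + 0.01)/(ΣTPM + 0.01))/0.33). The 0.33 expectation constant
is deliberately not 1/3 — it is the conventional printed value, and the
residual log2((1/3)/0.33) ≈ 0.0145 offset is a property of the statistic,
not a bug. Both constants are configurable.

Up-regulation counts are a replicate-level criterion: per subgenome pair
and homoeolog group, a two-sided Welch t-test on log2(TPM+1) replicate
values, Benjamini–Hochberg adjustment across all groups within a tissue
and pair, and a call when adjusted p < 0.05 and the |log2 fold change| of
(pseudocounted) replicate TPM means is ≥ 1. The Welch-on-log2 engine is a
deliberate, self-contained substitute for count-model GLM packages; the
test function is pluggable (`test=` argument) so a count-based engine can
be dropped in.

## Expression shift

Per-homoeolog profiles (replicate-averaged log2(TPM+1) over a fixed tissue
list) are clustered by average-linkage agglomerative clustering cut to
exactly k = 10 groups. The dissimilarity is 1 − Pearson correlation
(pattern similarity); Euclidean distance is a config alternative. Constant
profiles get distance 0 to identical profiles and 1 otherwise. Profiles
are sorted by gene id before linkage, making the result invariant to input
order. A homoeolog group is *shifted* when its members span more than one
cluster; the shifted fraction is monotone non-decreasing in k because
hierarchical cuts are nested. `subsample_comparison` re-clusters seeded
random subsets of groups (without replacement) so tetraploid pair
collections can be compared to hexaploid triad counts at matched n.

## Co-expression network

Biweight midcorrelation: u_i = (x_i − median)/(9·MAD), weights
(1 − u²)²·1[|u| < 1], correlation of the weighted, median-centred vectors.
The maxPOutliers = 0.05 cap rescales u side-specifically so that at most
5% of observations per tail receive zero weight. Zero-MAD vectors raise an
error (or fall back to Pearson via a flag; the matrix routine falls back
by default so a constant gene cannot poison a whole run).

Soft power: for each candidate exponent, signed-hybrid adjacency
a_ij = corr^power·1[corr > 0] (diagonal 0), connectivity k_i = Σ_j a_ij,
and a scale-free fit index = R² of log10(frequency) on log10(mean k) over
10 equal-width connectivity bins, signed negative when the slope is
positive. The chosen power is the first to reach the 0.9 target; when none
qualifies (common on strongly modular synthetic data, which is not
scale-free) the maximum-fit power is returned with a warning.

Unsigned TOM: TOM_ij = (Σ_u a_iu a_uj + a_ij)/(min(k_i,k_j) + 1 − a_ij),
diagonal 1. Modules come from average-linkage clustering of 1 − TOM with a
*static* cut (default height 0.99) — a deterministic, testable replacement
for dynamic tree cut; clusters below 30 genes are unassigned (label 0).
Module eigengenes are the first principal component of the standardized
module submatrix (unit variance, sign oriented so mean member correlation
is nonnegative); modules whose eigengenes correlate above 1 − 0.15 are
merged iteratively (best pair first) until stable — a fixed point, so
re-merging changes nothing. Hubs are genes with KME (correlation with
their own module's eigengene) strictly above 0.9. Neighbour composition
ranks each gene's partners by edge weight (TOM by default; ties broken by
ascending gene id), takes the top 100 and counts same- vs other-subgenome
neighbours. Everything is single-block with O(n²) memory; desk-scale
inputs (≲ 5,000 genes) are the intended regime.

## Fractionation

Retention tracks are ordered reference gene lists with boolean presence
per subgenome. Windows are 100 genes wide (0-based, half-open), slide at a
default stride of 10 within — never across — reference chromosomes, and
drop trailing partials. The stride is a free parameter (the convention
fixes only the window size); it changes the number of windows but not the
medians materially, and tests pin it. Distribution comparisons use the
two-sided Wilcoxon rank-sum test; identical constant samples are reported
with p = 1 and a degeneracy note. The ratio census classifies groups by
their decreasing copy-count signature.

## Synthetic data: what it emulates, what it does not

`simulate_expression` emulates the sampling design of a multi-tissue
polyploid RNA-seq study: 1,157 triad groups (the shared-triad count the
design targets), five tissues (leaf blade, leaf sheath, shoot, root,
rhizome), three biological replicates, and an 8-fold planted dominance
effect — these defaults are the stated study conditions. Remaining
defaults are free parameters chosen once as realistic bulk RNA-seq values,
not calibrated to any real dataset: group base expression log-normal with
median 20 TPM and σ = 1 (a typical expressed-gene spread), NB dispersion
φ = 0.05 (variance μ + φμ², Poisson at φ = 0; typical replicate-level
overdispersion), library-size CV 0.1, gene lengths uniform on
500–5,000 bp so that length normalisation genuinely matters downstream.
The planted category mixture defaults to 76.9% balanced / 6% dominant /
17.1% suppressed, a balanced-dominated mixture typical of triad
classifications in allopolyploids. Planted categories are constant across
tissues; recovery is scored per triad-tissue call against the truth table.

Each simulator owns an RNG stream seeded by (fixed offset, master seed),
so interleaving calls never perturbs draws, and identical configuration +
seed gives bit-identical outputs.

What a green recovery test does *not* establish: the generator has no
tissue-specific regulation, no correlated homoeolog noise, no isoform
structure, no mapping bias and no count-level correlation between genes,
so classifier accuracy here is an upper bound relative to real data.
"Zero-noise" configurations (φ = 0, library CV 0, base spread 0) still
carry Poisson sampling noise — the one irreducible noise source of a
count model — which is negligible at the default expression level but is
why exact-recovery tests use homogeneous base expression rather than the
log-normal spread.

`simulate_modules` generates each module from one latent N(0,1) sample
profile: gene = baseline + loading × latent + N(0, noise_sd), loadings
uniform (default 0.5–1.5). Genes at or above the per-module 0.9 loading
quantile are planted hubs; hub labels follow the hub weight vector,
non-hub labels are uniform. Values are log2-scale; at noise 0,
within-module correlations are exactly 1. `simulate_retention` draws
presence flags as independent Bernoulli(1 − loss probability) per
subgenome along the reference order.

## Numerical choices

* TSVs: tab-separated, UTF-8, `#` comments ignored, 6 significant digits;
  values are double precision in memory.
* Simplex vectors validated to sum to 1 within 1e-6; classification tie
  tolerance 1e-12; TPM column-sum contract 1e-6 relative.
* Correlation/TOM matrices are clipped to their theoretical ranges and
  symmetrised before linkage to absorb floating-point drift.
* Exactly-k clustering uses the cut-tree of the average-linkage merge
  sequence; determinism comes from sorting inputs by gene id, which is
  stronger than a per-tie merge rule.
* Module relabelling is by size (descending), then smallest member index.

## Known limitations

* The DE criterion is Welch-on-log2, not a count GLM; with 3 replicates
  its power at small fold changes is limited (by design, the criterion's
  fold-change gate dominates).
* Static tree cut can split a module that dynamic methods would keep
  whole; the eigengene merge step recovers most such splits.
* The scale-free fit target of 0.9 is rarely reached on small synthetic
  module data (which is not scale-free); the fallback power is then used.
* Windows shorter than the window size (short chromosomes, trailing ends)
  produce no output rather than partial fractions.
* All-pairs matrices limit the network module to desk scale; there is no
  block-wise mode.
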