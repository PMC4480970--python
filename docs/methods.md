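# Methods

Statistical models, default parameters, and known limitations of each
stage. Coordinates, thresholds, and defaults quoted here are the ones the
test suite pins.

## Normalization and FPKM

Size factors are median-of-ratios: the per-gene reference is the geometric
mean of counts across samples, restricted to genes with no zero count in
any sample; sample *j*'s factor is the median over those genes of
counts_gj / reference_g. FPKM is computed on normalized counts:

    FPKM_gj = (c_gj / s_j) / (len_g / 10^3) / (S_j / 10^6)

with S_j the column total of normalized counts. FPKM is invariant under
uniform rescaling of a sample's counts on no-zero matrices (the size
factor absorbs the scale; a single-gene matrix is the degenerate
exception).

## Expression classification

Per replicate, genes with zero counts are NE. The log2-FPKM values of the
remaining genes are fitted with a two-component unequal-variance Gaussian
mixture by EM, written by hand so the per-iteration log-likelihood
monotonicity guarantee can be asserted (tolerating only float rounding and
the sigma floor of 1e-3). Initialization is a median split plus five
seeded random restarts; the best log-likelihood wins; components are
reported ordered by mean. Fewer than 50 finite values or zero spread is an
error.

Class boundaries use tail false discovery rates at a target level
(default 0.05): t_HE is the smallest x where

    FDR_HE(x) = pi_LE SF_LE(x) / [pi_LE SF_LE(x) + pi_HE SF_HE(x)]

drops to the target (SF = normal survival function), t_LE the analogous
largest x on the CDF side, both located by bisection to 1e-6. When the
mode overlap is heavy the two boundaries can cross; they are then
collapsed to their midpoint (no INT band). When a component weight is at
or below the target FDR, the tail FDR never reaches the target anywhere;
the boundary falls back to the crossing of the two scaled component
densities and is flagged degenerate. A local-posterior boundary rule is
available as an alternative (`boundary_rule="posterior"`). Classification:
count 0 → NE; log2 FPKM ≤ t_LE → LE; ≥ t_HE → HE; else INT.

## Differential expression

Counts are modeled as NB(mu, alpha) with variance mu + alpha mu^2, mean
mu_gj = s_j q_g 2^(beta_g [j in B]) for a contrast A vs B; beta is the
log2 fold change of B over A.

**Dispersion.** Per-gene method-of-moments estimates
(s^2 − mean)/mean^2 are pooled within conditions and left untruncated so
the trend regression below is not biased upward by flooring. The trend
alpha(mu) = a + b/mu is fitted over well-expressed genes
(mean ≥ 5) — not by per-gene regression, where the estimate's noise is
correlated with the regressor and attenuates the fit, but by pooling
second moments within log-spaced mean bins and putting a weighted line
through the bin aggregates. Per-gene estimates are shrunk toward the
trend with weight df/(df + prior_df), prior_df = 30 (a method design
constant validated on global-null simulations), floored at 1e-8 after
shrinkage. All-zero genes are untestable (NaN).

**Wald test.** The moderated log2 fold change is the posterior mode under
a zero-centered normal prior with sd 2.0 (configurable), found by
L-BFGS-B in (log q, beta) with an analytic gradient. The standard error
comes from the observed information of the penalized log-likelihood
(central differences on the gradient, h = 1e-4); the Wald statistic
beta/se is referred to a standard normal, two-sided. The prior keeps
log2fc finite even when one side is all zeros. |moderated log2fc| never
exceeds the unpenalized estimate's magnitude.

**BH adjustment** is the step-up rule with NaN pass-through: undefined
p-values do not count toward m and stay NaN.

This stage is intentionally a simplified stand-in for a full DE engine:
no GLM covariates, no outlier handling, no independent filtering. Its
calibration is validated directly (null fraction of raw p < 0.05 within
0.05 ± 2·SE at 5,000 genes, 2 vs 2) rather than inherited from a
reference implementation. Note that with two replicates per side the
sampling sd of a per-gene log2 fold change at alpha ≈ 0.1 is roughly
0.45, so individual estimates scatter widely around the truth even when
recovery (padj < 0.05) is near 100%; accuracy statements are therefore
about medians, not per-gene bounds.

## Regulation calling

Differential in a contrast: padj < 0.05 AND INT/HE in at least one
replicate of at least one of the two conditions (genes NE/LE throughout
both conditions are ignored). Regulated: differential in both the lineage
contrast and the transduction contrast; direction is the sign of the
factor-contrast fold change. Per mutant (compared against the full-length
factor condition): dysregulated iff significant AND the change points
back toward the control baseline — down for factor-upregulated genes, up
for factor-downregulated genes; significant changes that exaggerate the
factor's effect are retained. Dysregulated ⊆ regulated is a hard
assertion. Summaries report per-mutant counts split by direction and
pairwise intersection sizes.

## Set statistics

The exact two-sided binomial test uses the minimum-likelihood convention
(sum of all point masses not exceeding the observed mass, with relative
slack 1e-7 for float ties); a doubling variant (twice the smaller tail)
is available and always agrees within a factor of two. Fisher's exact
test enumerates the hypergeometric distribution with fixed margins under
the same convention. All masses are computed through log-gamma, so
p-values down to the 1e-70 scale are exact to relative rounding. Sample
distances are Euclidean on log2(normalized count + 1) — a deliberate
variance-stabilizing stand-in, not a regularized-log reimplementation —
restricted to the regulated genes; PCA is centered SVD over samples;
hierarchical clustering is complete linkage.

## Conservation scan

Per alignment column, pairwise identity is the fraction of sequence pairs
with identical residues among pairs where neither is a gap; similarity is
the mean pairwise BLOSUM62 score rescaled to [0, 1] by the matrix's
global min/max. Both profiles, and the per-codon Bayes factors, are
smoothed with a centered moving average (window truncated at the ends,
renormalized over non-missing entries; defaults 4/20/4) and reported at
1-based ungapped reference coordinates. Subdomain candidates are maximal
proline-free runs of the reference; each is annotated with its profile
means and flagged selected when mean BF > 40 and conserved when mean
identity passes the configured threshold (no principled default exists;
0.8 is used in fixtures). Note that identity is not monotone under
duplicating a sequence: duplicating a column's minority residue lowers
that column's pair identity (e.g. A,B,B,B at 3/6 falls to 4/10).

## Synthetic data generator

A seeded SeedSequence spawns three substreams (structure, library,
counts), so the planted structure is stable across library/count
re-draws. The baseline is a mixture: an exact frac_zero fraction of
never-expressed genes, the rest split pi_LE / 1−pi_LE between
N(−2, 1) and N(6, 1) on the log2-FPKM scale (defaults). Regulated genes
are drawn from the high-expression component — by design, since the
downstream class filter discards genes that never leave NE/LE, planting
effects in the low mode would test the filter, not the caller. Effects
are uniform log2 fold changes in [2, 4], signed by an exact frac_up
split. Effect conditions carry the shift; mutant conditions revert their
dysregulated subset toward control (fully by default; partially with
reversion < 1). Dysregulation specs: an integer count (drawn disjointly
across mutants, in config order), a fraction (independent draw), or an
explicit gene list. Counts are NB around
FPKM · length/10^3 · libsize/10^6 with dispersion trend
alpha(mu) = 0.05 + 5/mu by default.

Generator limitations worth knowing:

- **Low-mode refit bias.** Pushing the mixture through NB counts and
  refitting on log2 FPKM recovers the high mode within ±0.06 but biases
  the low mode downward by ~0.1–0.25 at the default depth: LE genes sit
  at mean counts ≈ 3–8, where the concavity of the log (Jensen's
  inequality) shifts and widens the mode. This is a property of counting
  noise, not of the EM; EM on directly drawn mixture values recovers
  means within ±0.1.
- Library sizes and dispersion magnitudes are fixture choices, not
  estimates of any real dataset.
- No read-level simulation, no activation time courses, no explicit
  codon-evolution model in the MSA generator (sequences keep the
  reference residue with the local identity probability, else substitute
  uniformly).

## Determinism

Every stochastic step takes an explicit seed; the pipeline re-run with
the same inputs and seed produces byte-identical summary files. The
acceptance script derives all its substream seeds (each < 2^31) from a
single `--seed` via SeedSequence spawning.
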