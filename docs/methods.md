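# Methods

`chcevol` implements a complete analysis chain linking chemical-profile
divergence to mating behaviour and to the tempo and mode of trait
macroevolution on a phylogeny.  This note records the statistical models,
their assumptions, the defaults and why they were chosen, and the numerical
conventions that affect results.

## Compositional CHC processing

Per-specimen hydrocarbon amounts (ng) are obtained from chromatographic
peak areas by internal-standard scaling, `amount = area × IS_mass /
IS_area` (default IS mass 200 ng).  Amounts are closed to proportions
(dividing by the specimen's total) to remove body-size variation, then
mapped to additive log-ratio ("log-contrast") coordinates: each non-divisor
proportion is divided by the divisor component's proportion and logged.
The default divisor is 13Me27 and the default component set is the five
methyl-branched heptacosanes with 9Me27/11Me27 pooled; a field set pooling
11Me27 with 13Me27 is provided for samples where those peaks cannot be
separated.

Conventions:

* **Log base.** Natural log.  The base rescales all coordinates by one
  constant, so permutation F-ratios, Mantel correlations, and discriminant
  variance fractions are unaffected; it is exposed as a parameter anyway.
* **Zero proportions.** The default policy is an error naming the specimen
  and component, because a zero amount usually indicates an integration
  problem rather than true absence.  An optional multiplicative pseudocount
  (default 1e-6 of the row total, rows re-closed) is available.
* **Divisor choice.** Any component may serve as divisor; log-contrast
  analyses are equivariant under this choice and downstream conclusions
  should not depend on it.

## Nested permutation MANOVA

Group structure is nested: populations within species (or, intraspecifically,
populations within host plants).  Squared Euclidean distances on
log-contrast coordinates are partitioned into outer, inner-within-outer,
and residual sums of squares; for Euclidean distance this distance-based
partition equals the classical nested ANOVA trace partition, which is what
is computed (and asserted in tests).  The outer pseudo-F tests against the
nested mean square (df = a−1 over b−a); the inner pseudo-F against the
residual.

Permutation schemes respect exchangeability:

* outer effect — whole populations (labeled blocks, unbalanced sizes kept)
  are reassigned to species;
* inner effect — individuals are shuffled among populations *within their
  species*.  The source analysis's description ("individuals randomized
  among populations") does not state whether randomization crossed species;
  the restricted scheme is the one under which individuals are exchangeable
  when the nested null holds, so it is the default and only scheme.
* designs without a nested term (inner labels equal to outer) randomize
  individuals among outer groups directly.

p-values use `(exceedances + 1) / (n_perm + 1)` so that p is never 0; with
the default 1000 permutations the resolution is ~0.001.  An `exact=True`
mode enumerates all distinct permutations for small designs and then
reports the exact proportion (identity included); it is used in tests
against brute-force enumeration oracles.  If the residual (or nested) mean
square is zero the F-ratio is undefined and the result is flagged
degenerate rather than invented.

Parametric MANOVA uses Wilks' Λ = det(W)/det(W+B) with Rao's F
approximation (the standard choice); the discriminant functions are the
eigenvectors of W⁻¹B ordered by eigenvalue, with the between-group
variance fraction λⱼ/Σλ.  Eigenvalues are shared between the two:
Λ = Π 1/(1+λⱼ), asserted in tests against statsmodels and scikit-learn.

## Mating propensity

Propensity for a female-species × male-species cell is successes/trials;
zero-trial cells are missing, not zero.  Species-pair summaries average the
two reciprocal cells without pooling counts (an unweighted mean; pooling
would let the better-sampled direction dominate and re-introduce the male
"eagerness" asymmetry the averaging is meant to remove).

The interspecific model is a logit-link binomial GLM on per-cell
proportions weighted by trial counts, with male-species treatment dummies
first (alphabetical reference level), then genetic and CHC divergence
covariates.  Conspecific (diagonal) cells are excluded by default.
Overdispersion is handled quasi-likelihood style: point estimates equal the
ordinary binomial fit; the dispersion φ = Pearson X²/df_resid rescales
standard errors by √φ, and t = coefficient/SE is referenced to a t
distribution on df_resid.  Rank-deficient columns (for instance an
identically zero covariate) are detected and reported as dropped rather
than silently absorbed.  Saturated designs leave φ undefined (reported as
NaN).  Pairwise divergences are not independent data points; the GLM's
p-values are therefore indicative, and the Mantel tests are the primary
inference route.

## Distance matrices and Mantel tests

CHC divergence between species is the Euclidean distance between
per-component species medians (each component an axis; each species the
median of its cloud of specimens).  Per-component matrices take
|median_A − median_B| for one component of the *non-log-transformed*
proportions.  Genetic divergence is preferably supplied precomputed; an
uncorrected p-distance from an alignment (gap/ambiguity sites skipped
pairwise) is provided as a convenience only.

The Mantel statistic is the Pearson correlation of lower-triangle entries;
the null permutes rows and columns of the first matrix simultaneously.
The partial Mantel statistic is the first-order partial correlation of
triangles, with the same permutation applied to the first matrix only
(Smouse–Long–Sokal).  Mating propensity enters as a similarity (higher =
more mating), so its correlation with divergence matrices is expected to
be negative; for that reason the default tail is two-sided and the tail is
always recorded — an upper-tail default would be blind to the expected
direction.  Default 999 permutations with the +1 rule (p resolution 0.001).

## Nine models of trait change on a phylogeny

Three phylogenetic classes × three tempos, all sharing the Brownian-motion
likelihood: tip values are multivariate normal with mean μ (root state) and
covariance σ²C, where C_ij is the shared root-to-MRCA path length on a
*transformed* tree.

Transformations: pure-phylogenetic keeps the topology (distance: original
lengths; equal: every edge 1); nonphylogenetic is a star (distance: tip
lengths = original root-to-tip paths; equal: unit lengths); punctuated sets
the retained daughter's edge to 0 at every bifurcation and gives the
changing daughter the tempo-defined length, ancestral values propagating
through zero-length edges.

Fitting: for distance/equal tempos μ is profiled by GLS and σ̂² is the
residual quadratic divided by the number of informative tips, with the
likelihood evaluated at the optimum.  Tips whose root path is all-zero
(always one lineage under punctuated models) are exact observations of μ:
they pin μ, contribute nothing to the log-likelihood, and make it −∞ if
two such tips disagree.  This deterministic conditioning is preferred to
jitter; an ε-jitter fallback exists for ill-conditioned covariances.  The
likelihood is evaluated both by Felsenstein pruning and directly from the
covariance matrix; the two agree to 1e-8 in tests and the pruning pass is
the default.

Parameter counting follows the framework's AIC bookkeeping: the profiled
root state is uncounted; single-rate models have P = 1; free-tempo models
count their optimized branch lengths (2n−2, n, n−1).  AIC = −2lnL + 2P;
AICc is not offered for free models, where P approaches the sample size.

**Free tempo.** σ² is fixed at 1 and branch lengths are free, bounded below
by ε (default 1e-6) because the likelihood diverges as a branch length
shrinks onto a fitted tip.  The star/free profile is closed-form given μ
(each tip length max(ε, residual²)); the pure/free fit is multi-start
bounded L-BFGS-B on log-lengths seeded from the distance- and equal-tempo
optima (which guarantees the nesting inequality lnL_free ≥ lnL_distance,
lnL_equal) plus random restarts; the punctuated/free fit is exact per
assignment (the model is just-identified: change magnitudes are a
triangular function of tip values).  Any fit with a parameter at the ε
floor is flagged `boundary`: its reported likelihood is floor-dependent and
its MLE does not exist.

**Punctuated daughter assignment.** `fit_model` can profile the likelihood
over all 2^(n−1) assignments of which daughter changes (exhaustive up to 15
internal nodes, greedy bit-flip hill-climbing with restarts beyond, checked
against the exhaustive answer in tests).  The model-comparison layer
`aic_model_table` deliberately does *not* use this profile: maximizing over
2^(n−1) discrete configurations while declaring P = 1 biases AIC toward
punctuated models strongly enough that a gradual (pure/distance) truth is
essentially never recovered at n = 9 — and gradual models demonstrably can
win in this framework on real data of that size.  The comparison layer
therefore fixes a canonical, data-independent assignment (the first-listed
daughter changes at every node) so every single-rate model is an honest
one-parameter fit; `punct_mode="max"` restores the profiled variant.  Under
simulation the fixed-assignment comparison recovers pure/distance most
often under Brownian truth and the punctuated class most often under
punctuated truth, which is the behaviour a tempo-mode inference needs.

**Boundary fits in the AIC table.** Boundary-flagged free fits are excluded
from the ΔAIC ranking (cells NaN, flag reported).  The star/free model is
always such a case — its profile diverges for any data — and the original
program's output shows enormous sentinel values in exactly that row; the
table here reports the flag instead of a sentinel.

## Synthetic data generator

The generator reproduces the *design* of the study the pipeline targets:
nine species, two sampling locations each except one species with a single
location (17 locations), 3–6 females per location (≈76 specimens), five
components, and the packaged unbalanced 9×9 trial-count matrix (1422
trials).  The packaged fixture tree is a random ultrametric Yule topology
scaled to unit depth — explicitly *not* an inferred phylogeny.

Structure is generated in log-contrast space, which guarantees valid
compositions after the inverse logistic transform: species mean vectors
(iid normal, or evolved by Brownian motion along the tree — the default, so
CHC distance correlates with phylogenetic distance as in real data),
population offsets, and individual noise, with default scales
(0.9, 0.28, 0.39 per coordinate) chosen to put roughly 78% of coordinate
variance between species and 7.5% between populations within species, the
partition observed in the data the pipeline emulates.  Amounts multiply
compositions by a lognormal body-size factor (sd 0.35 around 500 ng), so
scale-invariance of the downstream chain is exercised by construction.  A
Dirichlet composition mode is available as an alternative.

Mating outcomes are binomial per cell with
logit(p_ij) = α_male(j) + β_chc·d^CHC_ij + β_gen·d^gen_ij.  Defaults
α ~ N(1.2, 1), β_chc = β_gen = −1.0 were fixed once so that simulated
propensities span ~0–0.95 with mean ≈ 0.2, matching the range real
no-choice trials produce; genetic distances are patristic distances on the
unit-depth tree.

What the generator does *not* emulate: measurement error in peak
integration, host-plant or rearing effects on profiles, non-normal
individual variation, correlated evolution among components beyond the
shared tree, or any real topology.  Passing tests therefore demonstrate
that the estimators recover the structure *this* generative family
produces, not that any biological conclusion holds.

## Problem sizes and reproducibility

Every randomized routine takes a seed; the pipeline manifest records seeds,
configuration, input digests, and permutation counts, and identical
configurations yield byte-identical output tables.  The test suite and the
acceptance script use: 100 random trees for the dual-likelihood oracle;
50 datasets for the nesting inequalities; 200 replicates per truth for
model recovery plus 500 replicates at 64 tips for rate consistency; 1000
null simulations at 199 permutations for type-I calibration (199 keeps the
achievable level exactly 0.05 while keeping the suite fast); 200 replicates
for GLM dispersion/coefficient recovery; and 100 full synthetic studies for
the end-to-end association check.

## Known limitations

* Mantel-type tests have known inflated type-I error when one matrix has
  strong autocorrelation structure; calibration here is demonstrated under
  exchangeable nulls only.
* The nine-model framework assumes no extinction (or random extinction)
  and a correct, fully sampled topology; missing species bias the
  speciational-change inference.
* The punctuated likelihood conditions on a singular covariance direction;
  comparing its likelihood to full-rank models is a convention of the
  framework, not a measure-theoretic identity.
* Free-tempo models are reported for completeness but are effectively
  diagnostic: with one observation per tip they are at or beyond the
  identifiability limit.
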