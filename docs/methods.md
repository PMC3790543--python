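# Methods

## The model

The unit of analysis is a local species pool: a rooted phylogeny with
branch lengths over *n* species, plus per-species values of a specific
effect function (SEF, per-unit contribution to an ecosystem property)
and a specific response function (SRF, tolerance of one specified
driver; high = tolerant). The statistical backbone is the Brownian
variance–covariance matrix **V**, whose (i, j) entry is the branch
length shared by the root-to-tip paths of species i and j. Pagel's λ
rescales its off-diagonals, nesting phylogenetic independence (λ = 0)
and full Brownian structure (λ = 1) in one parameter.

Trees may be non-ultrametric and may contain polytomies. Covariance
construction and phylogenetic-diversity sums handle polytomies natively;
only the D statistic needs a bifurcating tree, and the pipeline resolves
polytomies deterministically with zero-length edges when asked
(`polytomy_policy="resolve"`, the pipeline default; the low-level
function refuses polytomies so the choice is explicit). λ's standard
interpretation assumes an ultrametric tree, so a warning is logged when
tip depths differ by more than 1% relative. λ is clamped to [0, 1]; on
non-ultrametric trees the PSD-feasible maximum can exceed 1, but the
conventional scale stops at 1 and the labeling bands assume it.

## Signal estimation

**Continuous (Pagel's λ).** λ̂ maximizes the MVN profile likelihood with
μ and σ² concentrated out by GLS at each λ (ML, not REML; case-study
style reports rarely state which, and ML composes cleanly with the
likelihood-ratio tests). The profile can be multimodal on small trees,
so the maximizer combines a 51-point coarse scan, bounded refinement on
four subintervals and around the best coarse point, and both endpoints;
near-ties (within 1e-7 log-likelihood) break toward the lower λ.
Boundary tests against λ = 0 and λ = 1 use the plain χ²₁ reference,
which is anti-conservative at a boundary — reported as-is and noted
here. On ultrametric trees the diagonal of **V** is constant, so
**V**(λ) shares **V**'s eigenvectors and one symmetric
eigendecomposition makes each profile evaluation O(n); non-ultrametric
trees use a Cholesky factorization per λ. Star phylogenies make the
likelihood flat in λ: the fit returns λ̂ = 0 with an `unidentifiable`
flag rather than an arbitrary interior value.

**Binary (Fritz–Purvis D).** The observed statistic is the sum over
internal nodes of |left − right| daughter values, with nodal values the
unweighted mean of the two daughters (branch lengths deliberately play
no role at this step; they enter only through the Brownian null). D
scales this sum between the mean of a tip-shuffle null and the mean of a
Brownian-threshold null, each with `n_perm` replicates (default 1000,
minimum 100). The Brownian null rank-thresholds each simulated
continuous draw at the observed prevalence, so both nulls condition on
the observed state counts. Monte-Carlo p-values include the observed
dataset ((1 + count)/(n_perm + 1)) and are never exactly 0. If the two
null means coincide (denominator < 1e-9) the statistic is undefined and
the fit raises rather than returning a garbage ratio. 1 − D is reported
alongside D so both signal statistics run in the same direction; for
labeling, 1 − D is clipped to [0, 1] (the raw value is kept in the
report).

## PGLS and the dual correlation

PGLS whitens by a factorization of **V**(λ) and solves the GLS normal
equations by least squares on the whitened data; λ is either fixed or
estimated by the same profile machinery. Standard errors use the
unbiased σ̂² (n − p); r² is defined on the whitened scale as
1 − RSS/TSS with TSS taken about the GLS-estimated grand mean
(intercept-only model) — there is no unique r² for GLS, so the
definition is stated; values are unadjusted. With λ = 0 or on a star
tree, PGLS reduces to OLS exactly (tested to 1e-8). Missing rows are
dropped listwise with a logged count.

The SEF–SRF association is assessed twice: PGLS with estimated λ
(phylogenetic arm) and OLS (nonphylogenetic arm), with the sign taken
from the OLS slope and a flag when the two arms disagree in sign. The
quadratic check regresses on centered x and its square and reports the
squared term's p-value; for a binary SRF the squared column is collinear
with the linear one, so the check is undefined and reported as NaN.

Effect-trait modeling of the SEF uses single-step backward elimination:
fit the full PGLS model once, drop every predictor with p > α (default
0.05), refit once. This mirrors the practice of discarding traits that
explain no significant additional variance without inventing a stepwise
search.

## Labels, quadrants, risk

Default signal bands — λ: none < 0.15 ≤ weak < 0.30 ≤ moderate < 0.60 ≤
strong; 1 − D: none < 0.20 ≤ moderate < 0.60 ≤ strong (no weak band) —
are the minimal bands consistent with the published case-study labels,
and are configurable. Quadrant dichotomization counts moderate as
high-signal. Correlation strength uses max(phylo r², nonphylo r²) with
cutpoints 0.01 (negligible/weak) and 0.30 (weak/strong); the lower
cutpoint is a calibrated choice, not an authors' value.

The risk rule uses both strength and sign. Negative associations:
strong → high (with a maximum-concern flag in quadrant D, where both
functions are phylogenetically patterned and no independently evolved
lineage backs the function up), weak → low, negligible → very low.
Non-negative associations → very low for the specified driver,
with an explanatory note when the association is non-trivial: a strong
positive correlation means the function is concentrated in the tolerant
species. The published case-study table distinguishes risk calls that
identical r² magnitudes cannot separate; its caption states that risk
reflects both the strength and the sign of the correlation, which is the
rule implemented here. The ordinal scale includes `maximum`, but the
default rule reports `high` plus the flag, mirroring how the strongest
published case is labeled.

## Driver filter and retained diversity

`apply_filter` removes the least tolerant fraction q of species (default
q = 0.5, the equal-split presentation): the cut value is the
⌊n·q⌋-th smallest SRF, species strictly above it survive, and species
tied at the cut all survive (tie count recorded). The order-statistic
cut — rather than an interpolated quantile — makes the no-tie survivor
count exactly ⌈n(1 − q)⌉ for every q and makes q = 0 the identity.
Retained phylogenetic diversity is the Faith-style branch-length sum of
the minimal root-connected subtree of the survivors, divided by the same
sum for the full pool.

## The synthetic generator

`simulate_tree` draws pure-birth (Yule) trees: exponential waiting times
at rate 1 per lineage, a uniformly chosen lineage splits, one final
exponential interval after the n-th tip, then all depths rescale to 1.
Unit depth makes λ and σ² comparable across tree sizes and gives
unit-variance tips, so the mixing weight ρ in
srf = ρ·u + √(1 − ρ²)·w (u, w independent MVN(0, **V**(λ)) draws) is the
target cross-species Pearson correlation. Quadrant archetypes use
λ = 0.05 (low) and 0.95 (high) — extreme but not boundary values, so
estimator noise in both directions is visible. When λ_sef ≠ λ_srf and
ρ ≠ 0 the mixture slightly perturbs the SRF's marginal signal; the
archetypes either share λ or use ρ = 0, so the approximation does not
affect them. Binary traits rank-threshold a Brownian draw at the target
prevalence. All generators are deterministic under a fixed seed, and the
orchestrator derives per-stage seeds from one root seed.

What the generator does not emulate: measurement error, intraspecific
variation, non-Brownian trait evolution (OU, early-burst), extinction in
the tree process, abundance structure, and SEF/SRF built from shared
underlying traits rather than drawn directly. Passing recovery tests
therefore show that the estimators and the classification logic are
correct and calibrated under the generating model — not that real
field systems satisfy that model.

## Problem sizes and numerical choices

Calibration checks use 128-tip trees with 200 replicates for λ recovery
(mean λ̂ within ±0.08 of truth, the ML downward bias at interior λ being
a few hundredths at this size), 64-tip trees with 500 datasets and 500
permutations for D calibration, 100 replicates per quadrant for
archetype recovery, and 500 replicates for filter behaviour — sizes at
which Monte-Carlo error is comfortably inside the tolerances while the
whole suite stays quick on a single core. Degenerate inputs fail loudly:
constant traits, absent binary states, fewer than 4 tips, rank-deficient
designs, all-zero-length trees. PSD factorizations add a relative 1e-12
jitter before Cholesky; eigenvalues are clipped at 0 in the ultrametric
fast path.

## Known limitations

- λ p-values use χ²₁ at boundaries (anti-conservative); no CIs on λ̂.
- r² is unadjusted; phylogenetic r² depends on the stated whitened-space
  definition.
- The D-to-label mapping treats 1 − D on the λ scale, which is a
  convention, not an equivalence of statistics.
- One driver, one filter event: no sequential or interacting drivers, no
  recolonization, no abundance weighting.
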