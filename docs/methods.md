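# Methods

This note documents the statistical model, the numerical scheme, the
defaults, and the choices made where the design was genuinely open.

## Metric scoring

A feature table holds entries in {present, absent, missing} for taxa ×
binary features.  A metric is a set of *function-groups*: singleton
groups for fusion-style metrics, multi-feature groups for
informativity-style metrics where bound and free exponents of the same
grammatical function must count once (OR rule).  Per taxon, a group
scores 1 if any member is present, 0 if every coded member is absent,
and is skipped when every member is missing; the raw score is the mean
over non-skipped groups, so it always lies in [0, 1] and a taxon with
all groups present scores exactly 1.  Taxa with no coded groups are
dropped and logged.

Coverage filtering precedes scoring: a taxon is removed when its
missing fraction across **all** features in the table (not only metric
features) exceeds the threshold (default 0.25).  The boundary is
strict — exactly 25% missing is retained.  Filtering and scoring
commute because they consult disjoint aspects of the table.

Standardization uses the sample (n−1) standard deviation; at the
sample sizes this pipeline targets (hundreds to ~1300 taxa) the
difference from the population denominator is immaterial, and the
(n−1) convention keeps the toy examples exactly checkable
(raw {0, 0.5, 1} → z {−1, 0, 1}).

Multistate cell values outside the {1, 0, ?, blank} map are coerced
present-if-nonzero with a logged count; a per-feature value map can
override this.  Two bundled toy definition files document the
configuration layout; real analyses supply definitions derived from
the published feature lists.

## Random-effect structures

*Phylogenetic.* Under Brownian trait evolution on a rooted tree with
branch lengths, cov(i, j) equals the depth of the most recent common
ancestor of tips i and j, and var(i) is the root-to-tip distance.  The
matrix is assembled in one postorder sweep (O(n²)).  Polytomies and
zero-length branches are accepted as-is, since empirical supertrees
contain both.

*Spatial.* Great-circle (haversine) distances on a 6371-km sphere are
expressed in degree-equivalents (111.195 km per degree), and the
Matérn correlation ρ(d) = (2^{1−κ}/Γ(κ))(d/ϕ)^κ K_κ(d/ϕ) is applied
with κ = 1 throughout.  The two canonical ranges are ϕ = 1.25
("local": correlation < 0.01 beyond ~9°-equivalents ≈ 1000 km) and
ϕ = 17 ("regional": appreciable correlation over several thousand
km).  Interpreting ϕ in degree-equivalents is a choice; it is the one
that reproduces the stated locality behavior of the two parameter
sets.  Planar lat/lon Euclidean distance is available behind a flag
for sensitivity checks only.

*Areas.* Block structure C[i,j] = 1 if two taxa share an area label,
else 0 — an exchangeable within-area effect, equivalent to an iid
area-level intercept.  Distances between areas are deliberately
ignored; this structure exists as the distance-free competitor in the
random-effects ladder.

*Standardization.* Every structure is scaled by the mean of its
diagonal so its average marginal variance is 1, making the effect SDs
of different structures directly comparable (this is the purpose of
standardizing at all; "divide by the variance" admits several readings
and mean-diagonal scaling is the one that serves it).  Inversion to a
precision matrix uses Cholesky with a diagonal jitter escalating ×10
from 1e-8 to 1e-4 (relative to the mean diagonal); the jitter actually
used becomes part of the stored matrix, so precision × covariance = I
holds to 1e-7 by construction, and failure beyond the cap raises an
error carrying the condition number.

## The mixed model and its inference

The observation model is

    y = α + Xβ + Σ_k u_k + ε,  u_k ~ N(0, σ_k² C_k),  ε ~ N(0, σ_e² I)

with standardized C_k.  Every SD has a penalized-complexity prior,
operationalized as σ ~ Exponential(rate) with rate = −ln(α)/u, i.e.
P(σ > u) = α; the default is u = 1, α = 0.1, and the sensitivity grid
varies α over {0.01, 0.1, 0.5, 0.99}.  Fixed effects have flat priors.

Inference is deterministic, in the nested-approximation family:

1. With θ = log σ (dimension K+1, typically 2–4), β is marginalized
   analytically under its flat prior, giving
   log p(y|θ) = −½[(n−p)log 2π + log|V| + log|XᵀV⁻¹X| + rᵀV⁻¹r]
   with V(θ) = Σ σ_k²C_k + σ_e²I and r the GLS residual.
2. The posterior mode of θ is found by Nelder–Mead; a finite-difference
   Hessian at the mode defines grid axes, and the posterior is
   evaluated on a tensor grid spanning ±3.5 posterior SDs (41 points
   in 1-D, 15² in 2-D, 9³ in 3-D, 7⁴ in 4-D).
3. Posterior summaries are Monte-Carlo mixtures over grid nodes:
   nodes are sampled by normalized weight (restricted to the
   highest-weight subset covering 99.9% of mass), and at each node
   β | θ, y and the latent total u | β, θ, y are drawn from their
   exact Gaussian conditionals.  For models with at most one
   structured component, a cached eigendecomposition makes each
   node evaluation O(n · p); with two or more components a Cholesky
   factorization per node is used, with the conditional covariance
   of the latent total simplifying to σ_e²(I − σ_e²V⁻¹).

The seed passed to `fit` controls only the node/conditional draws; the
grid itself is deterministic, so refitting with the same seed is
bit-identical.  Diagnostics reported with every fit: whether the mode
search converged, and the posterior mass on the outermost grid shell
("boundary mass").  Boundary mass below ~5% indicates the grid
captured the posterior; larger values usually mean a weakly identified
SD whose posterior piles up at zero on the log scale, which is benign
for the remaining parameters but is logged loudly.  These play the
role that potential-scale-reduction statistics play for samplers: the
approximation is deterministic, so there is no chain to mix.

WAIC is computed from the pointwise **conditional** log-likelihood
log N(y_i; η_i, σ_e²) at each posterior draw of the linear predictor
η = Xβ + Σu_k, with the variance-based penalty:
WAIC = −2 Σ_i [log mean_s exp(ll_si) − var_s(ll_si)].  Variance
fractions are posterior medians of σ_k² divided by their sum
(posterior means behind a flag); the denominator includes the residual
variance, which is why structured fractions need not sum to 100%.

An effect is "substantial" when its (2.5%, 97.5%) interval excludes
zero.

## RW2 nonlinear effects

A continuous covariate can enter as a second-order random-walk over
25 equal-width bins (configurable, minimum 5).  The intrinsic RW2
penalty DᵀD (D the second-difference operator) has a two-dimensional
null space — constant and linear trends.  A proper prior covariance is
built by (i) dropping the constant direction entirely (sum-to-zero)
and (ii) assigning the linear direction a large finite variance equal
to the largest principal variance of the penalized part.  The smoother
therefore properly nests linear truths (its credible band contains the
line) while a constant truth shrinks its SD posterior toward zero.
The bin-level posterior curve is recovered from the exact Gaussian
conditional of the bin vector, mixed over high-weight grid nodes, and
centered per draw.

## Ladders

The random-effects ladder fits intercept-only models with: phylo;
spatial-local; spatial-regional; areas; phylo+local; phylo+regional;
phylo+areas, and ranks them by WAIC.  The fixed-effects ladder fits,
on top of the chosen random structure (or with none, for contrast):
L1; vehicularity; L1+vehicularity; the lone product term
L1_log10 × vehicularity (the interaction uses the log-transformed but
*unstandardized* speaker scale, and no main effects); neighbors;
official; education.  A failed fit is recorded and the ladder
continues; all models appear in the output regardless.  Both
fixed-effect ladders verify they received the identical covariate
table via a content hash.

Covariate preparation: speaker counts are floored at 1 before log10
(affects only extinct/dormant entries, logged), then standardized
along with neighbor counts; EGIDS levels 0–3 map to vehicular = 1;
rows with missing modeled covariates are dropped per model with a
logged count (complete-case analysis).  Taxon alignment across tree,
scores, coordinates and covariates is an intersection join with a
written exclusion manifest.

Pagel's λ multiplies the off-diagonal phylogenetic covariance by
λ ∈ [0, λ_max]; the intercept-only GLS profile likelihood (β and σ²
profiled in closed form) is maximized by bounded scalar optimization
(tolerance 1e-6), with λ_max = 1.2 unless positive-definiteness fails
earlier (for ultrametric trees the bound is computed in closed form
from the eigenvalues).  The LRT against λ = 0 uses χ²₁; the 50:50
boundary mixture is available behind a flag, default off.  λ is
estimated on a single tree; averaging over a posterior tree sample is
out of scope.  A star tree makes λ unidentifiable: the estimate is
returned as 0 with a flag.

## Synthetic data

The generators mirror the model's assumptions: pure-birth (Yule)
trees (ultrametric, seeded); coordinates as a mixture of eight 2-D
Gaussian clusters (SD 2°) scattered over a ±40° latitude band —
clusters rather than uniform scatter, so the local Matérn field has
detectable structure at n = 300; covariates with log10 speaker counts
~ N(4, 1.5) floored at 0, vehicularity Bernoulli with a logistic link
on the speaker scale, Poisson(6) neighbor counts, and status flags
conditioned on vehicularity; traits y = α + Xβ + σ_p L_p z₁ +
σ_s L_s z₂ + σ_e ε with the factors taken from the standardized
covariances; and features Bernoulli(raw score) with
missing-completely-at-random gaps.  Reference conditions: n = 300,
σ_phylo = 1, σ_spatial = 0.3 (local Matérn), σ_e = 0.3, 100 features,
10% missingness.

What the generator does **not** emulate: dependence among features
given the latent score (real features are not conditionally
independent), non-random missingness (real descriptive gaps correlate
with region and documentation effort), phylogenetic signal in the
covariates unless explicitly constructed, and the shape of an
empirical supertree.  Passing tests therefore demonstrate the
estimators work when the model's assumptions hold — calibration,
recovery, ranking — not that any empirical dataset satisfies those
assumptions.

## Problem sizes and defaults in the test suite

Simulation-based checks run at the reference n = 300 (50 replicates
for coverage, ladder-recovery and confounding experiments; 20 seeds at
n = 500 for λ recovery) with 300 posterior draws per fit — enough that
quantile noise is far below the effect sizes being asserted.  The
acceptance script uses the same reference conditions and derives every
stream from its `--seed`.

## Known limitations

- Dense linear algebra throughout: fine to a few thousand taxa,
  no sparse tree-structured precision exploitation.
- Gaussian responses only; no measurement-error model for scores
  (feature-sampling noise inflates the residual component and
  attenuates λ on scored — rather than latent — traits).
- The grid approximation is exact only as the grid refines; with more
  than ~4 variance components the tensor grid coarsens (5 points per
  dimension) and summaries of weakly identified SDs become rough.
- WAIC uses the conditional likelihood; leave-one-out style criteria
  on the marginal likelihood are not implemented.
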