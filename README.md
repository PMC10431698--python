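# spatiophylo

Spatiophylogenetic mixed models for typological trait scores.

Languages (like species) are not independent data points: related
languages inherit grammar from common ancestors, and neighboring
languages borrow from each other.  Any claim that a sociodemographic
variable — speaker population, contact with second-language speakers,
number of neighbors, official status — shapes grammatical structure
must therefore be tested against models that control for both shared
ancestry and spatial diffusion.  This package provides that toolchain
for quantitative typologists and cultural-evolution researchers:

1. **Metric scoring** — turn a languages × binary-features table
   (wide CSV or CLDF-style long table) into *fusion* (reliance on
   phonologically bound marking) and *informativity* (obligatory
   explicit distinctions) scores: each grammatical function-group
   contributes 1 if any member feature is present, 0 if all coded
   members are absent, and is skipped when uncoded; the raw score is
   the mean over coded groups, then standardized.  Languages with more
   than 25% missing values across all features are removed first.
2. **Random-effect structures** — Brownian-motion covariance from a
   rooted Newick phylogeny (`C[i,j]` = shared root-to-ancestor branch
   length), Matérn spatial covariance
   ρ(d) = (2^{1−κ}/Γ(κ))(d/ϕ)^κ K_κ(d/ϕ) over great-circle distances
   at a "local" (ϕ = 1.25, κ = 1) and a "regional" (ϕ = 17, κ = 1)
   range, and exchangeable area blocks.  All structures are
   standardized to unit mean variance so their SDs are comparable.
3. **The mixed model** — y = α + Xβ + Σₖ uₖ + ε with
   uₖ ~ N(0, σₖ²Cₖ), penalized-complexity priors P(σ > 1) = 0.1 on
   every SD, fitted by a deterministic Laplace-anchored grid posterior
   (fixed effects marginalized analytically, latent effects drawn from
   their exact Gaussian conditional).  Results objects carry posterior
   quantiles, WAIC, variance fractions and diagnostics.
4. **Model ladders** — seven intercept-plus-random-effects models
   ranked by WAIC, then seven fixed-effect models fitted on top of the
   winner (and, for contrast, without random effects).
5. **Phylogenetic signal** — Pagel's λ by profile maximum likelihood
   with a χ²₁ likelihood-ratio test.
6. **Synthetic data** — seeded generators for trees, clustered
   coordinates, covariates, structured traits and feature tables, so
   the entire pipeline is testable offline.

## Worked example

```python
import spatiophylo as spp

# a synthetic study: 300-tip pure-birth tree, clustered coordinates,
# trait = Brownian effect (sd 1) + local Matern effect (sd 0.3) + noise (sd 0.3)
ds = spp.simulate_dataset(n_taxa=300, seed=42)
scores = ds.scores

lam = spp.estimate_lambda(scores.set_index("taxon")["z_score"], ds.tree)
print(lam.summary())

res = spp.SpatioPhyloLMM(
    scores.set_index("taxon")["z_score"],
    structures=[ds.structures["phylo"], ds.structures["spatial_local"]],
).fit(seed=0, draws=400)
print(res.summary())
```

prints

```
Pagel's lambda = 0.8296 (search bound 1.00)
logL(lambda_hat) = -244.2796, logL(0) = -425.1807
LRT chi2(1) = 361.8022, p = 1.14e-80

Spatiophylogenetic linear mixed model (n = 300, draws = 400)
random effects: phylo, spatial_local
term                       2.5%      50%    97.5%  substantial
Intercept                -1.180   -0.359    0.340
phylo                     0.734    0.855    0.979  *
spatial_local             0.245    0.307    0.369  *
resid                     0.134    0.198    0.252  *
WAIC = 73.01 (p_eff = 153.6)
variance fractions: phylo 84.5%, spatial_local 10.9%, residual 4.5%
diagnostics: mode_converged=True, boundary_mass=0.023
```

The λ estimate says the standardized score carries strong phylogenetic
signal (λ near 1 means closely related tips have similar values; the
LRT compares against λ = 0).  The model summary reports posterior
quantiles for the intercept and the three SDs; an effect is flagged
substantial (`*`) when its 95% interval excludes zero.  Here the
phylogenetic component dominates the variance (84.5%), the local
spatial component is clearly present (10.9%) — both consistent with
the generating SDs — and the WAIC value is what the ladder functions
use to rank competing models.

The same analysis runs from the shell:

```sh
spatiophylo simulate --n-taxa 300 --seed 42 --out-dir fx
spatiophylo score fx/features.csv --metric-config my_metric.json --out scores.csv
spatiophylo lambda scores.csv fx/tree.nwk
spatiophylo ladder scores.csv fx/tree.nwk fx/coords.csv \
    --covariates fx/covariates.csv --out-dir results
```

Real data enter the same way: a Grambank-style feature table, a rooted
Newick supertree, per-language coordinates and area labels, and a
covariate table with speaker counts, EGIDS levels (mapped to a binary
vehicularity flag: levels 0–3 are vehicular), neighbor counts and
status flags.  Download recipes: the Grambank CLDF release, the global
language supertree, and Glottolog coordinates are distributed by their
maintainers; place the value table, tree and tables in the formats
above — the package performs no network access.

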