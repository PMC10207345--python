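# Methods

## Model

Outcomes are country×year panel values of the gender gap in life
expectancy (female minus male, in years) or a gender-specific life
expectancy. The likelihood is Gaussian,
`y_it ~ Normal(μ_it, σ_e²)` with precision `τ_e = 1/σ_e²`, and the linear
predictor decomposes into an intercept, a time-constant spatial effect, a
shared temporal trend, a cell-level space–time interaction, and log-scale
covariate effects:

```
μ_it = α + s_i + θ_t + δ_it + Σ_k β_k ln x_k,it          (M1s)
```

M0s drops the covariates; M2s replaces the two exposure coefficients
(pwPM2.5, urbanization) with one coefficient per region while the four
confounders (poverty, education, calories, smoking) stay global.
Covariates must be strictly positive; they are log-transformed and
centered over the used observations, so the intercept absorbs their
means and reported coefficients are directly comparable to the simulation
truth. The outcome is modeled on the identity scale by default, with an
optional log transform.

### Spatial effect (BYM2)

`s = (√φ·u* + √(1−φ)·v)/√τ_s`. The structured part `u*` is an intrinsic
CAR effect on an undirected country adjacency graph: precision `Q = D −
A` (graph Laplacian), rank `n − #components`, used with a per-component
sum-to-zero constraint. For the mixing parameter `φ` to be
interpretable, `u*` is scaled per connected component by the constant
`κ = exp(mean log diag(Q_c⁺))` — the geometric mean of the marginal
variances of the constrained ICAR effect, computed from the
eigendecomposition of the component's Laplacian block (eigenvalues below
`1e−10 × max` treated as null space). After scaling, `τ_s` is the
marginal precision of `s` and `φ` the structured variance share.
Degree-zero nodes (island countries) have no structured part: their
effect is purely unstructured with full variance `1/τ_s`, and their
component's scaling constant is 1 by convention. Adjacency is caller
supplied as an edge list; the package never computes polygon contiguity
because no single neighborhood rule is canonical for world maps.

### Temporal trend and interaction

`θ` is a random walk (order 1 by default, order 2 optional) with
increment precision `τ_θ` and a sum-to-zero constraint, giving a smooth
nonparametric global trend. `δ_it` is the exchangeable (Type I)
interaction — i.i.d. `Normal(0, 1/τ_δ)` centered overall — letting each
country's trajectory deviate from the shared trend. Structured
interaction types (II–IV) are out of scope.

### Priors

`α, β ~ Normal(0, 1000²)` (a flat intercept prior is available for the
degenerate conjugate check); `τ_e, τ_θ, τ_δ, τ_s ~ Gamma(shape 1, rate
5e−5)`; `φ ~ Uniform(0,1)`. All configurable via `Priors`.

## Sampler

Given the five hyperparameters the latent field is jointly Gaussian, so
one sweep draws it exactly rather than coordinate-wise:

1. **Collapsed joint Gaussian draw.** Because `δ` is exchangeable, `δ +
   ε` is Gaussian noise with precision `τ* = τ_eτ_δ/(τ_e+τ_δ)`; the block
   `(α, β, s, u, θ)` is drawn from its joint full conditional with `δ`
   integrated out, by dense Cholesky of the (small: `1+p+2n+T`) posterior
   precision. The cross-product matrices of the design are precomputed
   once, so each sweep costs one Cholesky plus O(N) work.
2. **Constraints.** Sum-to-zero constraints (per-component on `u`,
   overall on `θ`) are enforced by conditioning-by-kriging on the sampled
   vector. A ridge `λ·AᵀA` is added to the precision beforehand; it
   vanishes on the constraint set, so the conditioned draw is exact while
   the unconstrained solve stays nonsingular.
3. **Interaction.** `δ` is then drawn cell-wise from its conditional
   (posterior precision `τ_e+τ_δ` at observed cells, prior at missing
   cells) and centered by a weighted projection.
4. **Precisions.** `τ_θ` has a conjugate gamma update from the trend
   increments (degrees of freedom `T −` order). When the interaction is
   absent, `τ_e` is conjugate gamma from the residuals.
5. **Noise pair `(τ_e, τ_δ)`.** With the interaction present the
   likelihood identifies only the variance sum `v = 1/τ_e + 1/τ_δ`; the
   split is prior-driven, and conditional gamma updates crawl along the
   resulting ridge (split-chain R-hat near 2.6 in early runs). The pair
   is therefore updated in `(v, ρ)` coordinates: `v` is exactly conjugate
   inverse-gamma given the split fraction `ρ`, and `ρ | v` is a cheap 1-D
   density (derived from the gamma priors by change of variables) sampled
   by grid-proposal independence Metropolis (acceptance ≈ 0.99). This
   makes the update essentially i.i.d.; R-hat drops to ≈ 1.02.
6. **BYM2 pair `(τ_s, φ)`.** The scaled parameterization admits no gamma
   conjugate update for `τ_s` (a `√τ_s` cross term appears in the joint
   `(s,u)` prior), so both are updated by random-walk Metropolis on
   `(log τ_s, logit φ)` with step sizes adapted during warm-up toward a
   30–45% acceptance rate and frozen afterwards.

Missing outcomes are excluded from the likelihood and their interaction
cells drawn from the prior; rows with missing covariates are excluded
from the likelihood under the covariate models, never zero-filled.
Chains run sequentially from independent streams spawned from one seed;
identical seed and configuration reproduce draws bit-for-bit.
Split-chain potential scale reduction is computed for scalar quantities
when ≥ 2 chains are run and warned about above 1.05 (warn-only).
Defaults are 2 chains × 5,000 iterations with 2,000 warm-up; the
experiments below use shorter chains because the exact joint latent draw
makes the effective sample size per iteration high.

### Identification notes

* `δ` vs. `ε`: an exchangeable interaction at the observation level is
  likelihood-confounded with Gaussian noise. Only `1/τ_e + 1/τ_δ` is
  data-identified; under the diffuse gamma priors the split posterior is
  bimodal near its extremes. Linear-predictor estimates, coefficient
  inference, and everything computed through `τ*` are unaffected; the
  individual `τ_e` and `τ_δ` posteriors should be read as prior-dependent.
* `u` enters the likelihood only through `s`; the `(s, u)`
  parameterization keeps the likelihood design hyperparameter-free so the
  cross-product matrices never need rebuilding.

## Model comparison

`DIC = D̄ + p_D` with the Spiegelhalter plug-in (deviance at the posterior
mean of the linear predictor and noise precision) and `WAIC = −2 Σ_i
[log mean_s exp(ℓ_is) − var_s(ℓ_is)]` with the variance-form effective
parameter count and a stable log-sum-exp. Both use the **δ-marginal
focus**: pointwise log-likelihoods are recorded as `y_it ~ N(μ_it, 1/τ_e
+ 1/τ_δ)` with `μ` excluding `δ`. Conditioning on an
observation-level random effect that is confounded with the error makes
the pointwise terms track the prior-driven variance split (p_waic
exceeded the observation count in early runs, and DIC and WAIC
disagreed); on the marginal focus both criteria depend only on
likelihood-identified quantities and agree. Smaller is better; ranking
is by WAIC with stable tie-breaks, and comparisons across different
observation sets are refused.

## Exposure aggregation

Per zone, `pwPM2.5 = Σ pm_i·pop_i / Σ pop_i` over the zone's grid cells,
accumulated row-major in double precision. Cells outside any zone are
ignored; cells with population but missing concentration are excluded
from numerator and denominator alike, with the population coverage
fraction reported per zone. A zone with zero population over covered
cells yields a missing value plus a warning, never a silent 0.
Reprojection/resampling of real rasters is out of scope; grids are read
as whitespace-delimited text matrices.

## Trend taxonomy

Trajectories (≥ 7 non-missing years) are smoothed with a centered moving
average (window 5, truncated at the edges, missing-tolerant). A country
is labeled **peak** when the smoothed argmax lies ≥ 3 years inside both
ends and both the smoothed rise (max − first) and fall (max − last) reach
ε = 0.25 years; the reported peak value is the raw series value at the
smoothed argmax year. Otherwise the label is the sign of the Theil–Sen
slope (reported per decade). Window, edge margin, and ε are parameters:
no published operational rule exists for this classification, so these
defaults are this package's explicit, tunable operationalization.
Region averages are unweighted means over countries with data in a given
year, with contributing counts reported.

## Synthetic data

The generator composes the generative model exactly: BYM2 effects drawn
per component from the scaled Laplacian eigenbasis (sum-to-zero by
construction), random-walk trends, centered exchangeable interactions,
and i.i.d. log-normal covariates (configurable location/scale per
covariate; optional shared-factor correlation; defaults give realistic
magnitudes, e.g. pwPM2.5 around 20 µg/m³). Default conditions emulate
the real study: 134 countries × 1960–2018 in six regions, coefficients
`(0.034, 0.251, −0.012, −0.061, 0.419, 0.076)` and hyperparameters
`τ_e = 156, τ_s = 5.11, φ = 0.473, τ_θ = 20,400, τ_δ = 180` matching the
reported global gender-gap fit. What it does **not** emulate: real-world
geography (a lattice or random geometric graph stands in for the country
map), temporal persistence or cross-correlation of real covariates,
informative missingness (only MCAR is available), or measurement error in
the exposure grids. Passing recovery tests therefore demonstrates
correctness of the machinery under the model's own assumptions, not
robustness to their violation.

## Validation experiments and problem sizes

`stgap.experiments` (driven by `scripts/acceptance.py` and the test
suite) runs:

* conjugate oracle — degenerate intercept-only model (n = 50, flat prior,
  known `τ_e`, 20,000 draws) against `Normal(ȳ, 1/(nτ_e))`;
* coefficient recovery — one 60-country lattice × 30-year panel, all six
  posterior means within 3 posterior SDs of truth;
* interval calibration — 50 replicate panels at 30 countries × 20 years
  (a size chosen so the full study runs in about a minute while leaving
  hundreds of effective draws per fit), per-coefficient 95% coverage;
* regional sign recovery — M2s with pwPM2.5 truth (+0.2, −0.3) in two
  regions, 20 replicates at 30 × 15;
* WAIC preference — 20 replicate panels at 20 × 12 comparing M1s vs. M0s
  on covariate-bearing truth and the BYM2 vs. no-spatial variant on
  strong-spatial truth (`τ_s = 1, φ = 0.9`, no covariate effects);
* trend taxonomy — monotone and tent series over 30 years, noise-free and
  with Gaussian noise (sd 0.1, amplitude 4, 200 replicates);
* exact checks — the 3-node complete graph's scaling constant (2/9) and
  the exposure aggregation against a per-cell loop oracle.

## Numerical choices

Equal-tailed 95% intervals with linear-interpolation quantiles; a
quantity is "significant" when its interval excludes zero. Constraint
projections hold sums to below 1e−10. Pseudo-inverses use
eigendecomposition with relative null-space tolerance 1e−10. Summary
CSVs round-trip at 12 significant digits; pipeline outputs embed version,
seed, and a configuration hash and rerun bit-identically.

## Known limitations

Spatial confounding between `s` and spatially structured covariates is
not corrected. The interaction is Type I only. Absolute DIC/WAIC values
are focus-dependent and not comparable to values computed by other
software conditioning on a different latent set. The τ_e/τ_δ split is
prior-driven (see identification notes). Real-data ingestion is limited
to the documented CSV/edge-list/text-grid formats; no source-specific
download or cleaning is provided.
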