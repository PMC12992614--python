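# phylodisp

Phylogenetic mixed models, projection-predictive trait selection and
cross-clade prediction of avian dispersal distances.

## The problem

How far birds disperse — the movement from a natal or breeding site to the
next breeding site — shapes population connectivity, gene flow and range
dynamics, yet empirical dispersal estimates exist for only a fraction of
species. A long-standing idea is that *dispersal syndromes* (covariation
between dispersal ability and morphological, life-history and behavioral
traits) let us predict dispersal for species without data. `phylodisp`
implements the full statistical machinery needed to test that idea:

1. **Dispersal responses** from kernel parameters: the median and the 95th
   percentile ("long-distance" dispersal) of Weibull or half-Cauchy dispersal
   kernels, modeled on the natural-log scale.
2. **Trait design matrix**: log transforms for body mass and hand-wing index,
   z-standardization, the slow–fast life-history axis (PC1 of egg mass,
   clutch size, age at first breeding, broods per season, life span),
   variance-inflation screening and complete-case filtering.
3. **Phylogenetic mixed model (PGLMM)**. For log distance *y*,

       y = Xβ + u + e,  u ~ N(0, σ²ₚ C),  e ~ N(0, σ²ₑ I)

   where C is the phylogenetic variance–covariance matrix (shared
   root-to-ancestor branch lengths, correlation-scaled). Estimation is by
   profile maximum likelihood over the mixing ratio ρ = σ²ₚ/(σ²ₚ+σ²ₑ);
   phylogenetic signal is reported as Pagel's λ in its variance-ratio form
   (λ = ρ), and variance explained as marginal/conditional R²
   (fixed effects alone vs fixed plus phylogenetic effects).
4. **Variable selection and model combination**: forward projection-predictive
   selection (submodels ranked by Gaussian KL divergence from the full
   reference model, the phylogenetic term delayed to the last step), size
   choice by K-fold expected log predictive density with a one-standard-error
   parsimony rule, exact leave-one-out model comparison, and Bayesian
   stacking of models within two standard errors of the best.
5. **Cross-prediction experiments**: within-order k-fold and between-order
   leave-order-out cross-validation with phylogeny-only and
   permuted-response baselines, scored by predictive R² and species-weighted
   mean R².
6. **Synthetic data with known truth**: clade-labeled pure-birth phylogenies,
   traits with mixed Brownian/independent structure and controllable
   collinearity, and responses with chosen β, λ and clade-level syndrome
   heterogeneity — so every stage of the pipeline is testable end to end.

Trees are handled with `dendropy`; consensus trees are built by
neighbor-joining on the mean patristic distance matrix with branch lengths
re-fitted by nonnegative least squares.

## Worked example

Simulate a 200-species study under the reference condition
(β = 0.5 body mass, −0.4 life history, −0.2 breeding latitude; λ = 0.6)
and fit the full model:

```bash
phylodisp simulate --seed 7 --out demo
phylodisp fit --tree demo/tree.nwk --traits demo/traits.tsv \
              --kernels demo/kernels.tsv --out demo/fit
```

which prints

```
lambda=0.605 R2m=0.372 R2c=0.752
```

and writes `demo/fit/fit.json` with the coefficient table:

| predictor          | estimate | 95% CI           |
|--------------------|---------:|------------------|
| body_mass          |   +0.677 | [+0.536, +0.818] |
| life_history       |   −0.281 | [−0.463, −0.098] |
| breeding_latitude  |   −0.254 | [−0.362, −0.147] |
| hwi                |   +0.068 | [−0.137, +0.272] |

The three generative effects are recovered with the right signs and
magnitudes, the noise trait (hand-wing index) spans zero, and the estimated
signal λ = 0.605 sits at the generating value 0.6. `phylodisp run-all`
chains the whole pipeline (fit → selection → stacking → cross-validation)
and `phylodisp crossval` runs the within/between-order experiments on any
tree + trait + kernel input; every output directory carries a manifest
(config echo, master seed, input checksums) and reruns are byte-identical.

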