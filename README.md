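# memscape

Spatial optimisation of plant-community predictors over connectivity
graphs: Moran's eigenvector maps, permutation tests of the scale of
effect, environment-filtered ordinations, diversity estimation, and the
comparison of diversity against spatially optimised predictors in
discriminating habitat categories.

## The problem

Community samples from a mosaic agricultural landscape (sites in crops,
field edges, oak forest and successional wasteland) are spatially
dependent: nearby sites share environment and exchange propagules. A
diversity index computed per site ignores this structure, so differences
among habitats may reflect spatial configuration rather than habitat
processes. `memscape` implements the spatial-optimisation workflow for
site-by-species count data over a small number of sites (n ≈ 23):

1. **Connectivity hypotheses.** Four planar graphs over the site
   coordinates express decreasing connectivity density: Delaunay
   triangulation, the Gabriel graph, and two lune-based β-skeletons
   ("relative neighbour" graphs, β = 2 and β = 3). Each graph becomes a
   binary spatial weighting matrix (SWM) **W**.
2. **Moran's eigenvector maps.** Eigenvectors *u*₁ … *u*₍ₙ₋₁₎ of the
   doubly centred SWM, **Ω** = **C W C**, ordered by eigenvalue. Leading
   MEMs describe broad-scale spatial patterns, trailing MEMs fine-scale
   alternation; under binary weights, *I*(*u*ᵢ) = (*n*/W)·λᵢ, where *I* is
   Moran's autocorrelation statistic.
3. **Smoothed scalograms.** A focal variable (an ordination axis of the
   chi-square-transformed site-by-species matrix **Y**, of the
   environment-constrained fit **F**, or of the environment-filtered
   residual **R**) is projected on the MEM basis; per-MEM *R*² values are
   summed within two smoothing windows (broad = MEMs 1–11, fine =
   MEMs 12–22 at *n* = 23) and tested by permuting sites. Because the
   basis spans the centred space, broad + fine *R*² = 1 exactly.
4. **Moran's I Monte-Carlo tests** of each ordination axis's best MEM,
   with the null expectation −1/(*n*−1) recovered by permutation.
5. **Diversity.** Tsallis entropy *S*_q = (1 − Σ *p*ₛ^q)/(q − 1)
   (default q = 0.5, rare-species sensitive) and the asymptotic Shannon
   diversity *D*_AE = exp(Ĥ), where Ĥ corrects the plug-in entropy for
   unseen species via singleton/doubleton frequencies; plus hypergeometric
   rarefaction.
6. **Discrimination.** MANOVA with Wilks λ = det(E)/det(E+H) and Rao's F
   approximation, and pooled-covariance LDA (uniform or frequency priors,
   optional stratified half split), comparing the predictor sets
   {*S*_q, *D*_AE} and {selected MEM scores} for the habitat categories.

A synthetic landscape generator with known ground truth (which MEM carries
the injected fine-scale signal, which habitat drives diversity) makes the
whole pipeline testable end to end.

## Worked example

```bash
python analysis/01_simulate_landscapes.py
python analysis/05_habitat_discrimination.py
```

prints, for a landscape where habitat drives diversity but not the
spatial eigenstructure:

```
diversity: Wilks lambda=0.0089 F(6, 36.00)=57.65 p=5.44e-17  -> significant
mem      : Wilks lambda=0.5978 F(6, 36.00)=1.76 p=0.1353  -> not significant

MEMs fed to the LDA: [17, 1]
LDA diversity_uniform: 23/23 correct
...
LDA mem_uniform: 13/23 correct
```

The two diversity estimates separate the four habitats almost perfectly
(λ near 0 means strong separation), while the spatially optimised MEM
scores — which carry the landscape's connectivity structure, not its
habitat identity — do not. `analysis/04_diversity_estimates.py` shows the
habitat ordering by mean *S*_q (`Crop < Edge < Oak < Wasteland`) and the
redundancy of the two estimators (r² ≈ 0.88 across sites), and
`analysis/03_spatial_scalograms.py` prints the scalogram and Moran tables
for all four connectivity hypotheses.

The CLI exposes the same stages over CSV inputs:

```bash
memscape simulate --n-sites 23 --seed 1 --out data/
memscape pipeline --sites data/sites.csv --abundance data/abundance.csv \
    --env data/env.csv --n-perm 999 --seed 1 --out results/
```

## Layout

- `src/memscape/` — the library (data model and IO, synthetic generator,
  connectivity, spatial eigenanalysis, ordination, diversity,
  discrimination, environmental screening, pipeline, CLI)
- `analysis/` — numbered narrative drivers writing under `results/`
- `tests/` — pytest suite, including geometric brute-force oracles and a
  dual implementation of the asymptotic Shannon estimator
- `docs/methods.md` — models, assumptions, parameter choices, limitations
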