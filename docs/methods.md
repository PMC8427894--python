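# Methods

## Scope and model

`memscape` analyses a site-by-species count matrix observed at a small set
of planar sampling sites with categorical habitat labels, together with a
site-by-environment matrix. Its question is twofold: at which spatial
scale (broad vs fine) are community composition and environment
structured, under competing a-priori hypotheses of landscape connectivity;
and do per-site diversity estimates discriminate habitat categories better
or worse than spatially optimised predictors derived from the connectivity
structure itself.

Coordinates are treated as strictly planar. No CRS handling, resistance
surfaces or least-cost paths are implemented; connectivity is expressed
only through linear (lattice) graphs over the sites.

## Connectivity graphs and weights

Four graph families: Delaunay triangulation; Gabriel graph (edge kept iff
the closed disc on the segment as diameter contains no third site); and
lune-based β-skeletons with β = 2 and β = 3 ("relative neighbour 1/2").
β = 1 reproduces the Gabriel graph exactly.

**Boundary rule.** A third site exactly on the disc/lune boundary counts
as a blocker (closed-region rule), with coordinates compared at 1e-9 of
the extent diagonal. This keeps behaviour deterministic on gridded or
co-circular layouts (the unit square keeps no Gabriel diagonal) and makes
the β = 1 / Gabriel identity exact. A consequence worth knowing: the
longest edge of any triangle is always lune-blocked, and an exactly
equilateral triangle retains no β = 2 edges at all; degenerate inputs are
never jittered silently.

**Weights.** Default binary (w_ij = 1 iff edge): the canonical choice for
graph-based MEMs, and the one that makes the Moran's I / eigenvalue
identity exact. A row-standardised style (binary rows divided by row sums,
then symmetrised as (M + Mᵀ)/2) is available.

β > 2 skeletons need not contain the minimum spanning tree and can be
disconnected on random layouts; a disconnected graph is a hard error that
names the components, because the MEM basis downstream requires
connectivity.

## Moran's eigenvector maps

MEMs are eigenvectors of **Ω** = **C W C** with **C** = **I** − **11**ᵀ/n.
Rather than eigendecomposing Ω directly and discarding near-null
eigenvalues, the problem is restricted to an orthonormal (Helmert) basis
of the centred subspace, which deflates the constant direction exactly.
A connected n-site graph therefore always yields n − 1 centred,
orthonormal eigenvectors — including any structurally null eigenvalues
that sparse (near-tree) graphs produce — so the basis always spans the
centred space and the scalogram's unit-sum property holds identically.

Determinism: eigenvector signs are fixed by making the largest-magnitude
entry positive; ties in eigenvalues (within 1e-9 relative) are ordered
lexicographically by eigenvector entries.

## Moran's I and its permutation test

I = (n/W)·Σ w_ij (x_i − x̄)(x_j − x̄) / Σ (x_i − x̄)², W = Σ w_ij. The test
permutes x across sites; the reported expectation and variance are the
Monte-Carlo moments of the null draws (they wobble from run to run, as a
permutation framing implies), with the analytic expectation −1/(n − 1)
carried alongside. p = (1 + #{null as-or-more extreme})/(n_perm + 1); the
two-sided alternative measures extremeness from the Monte-Carlo null mean.
Default n_perm = 999, so the attainable p floor is 0.001.

## Ordinations and scalograms

The count table is chi-square transformed,
ŷ_ij = √y₊₊ · y_ij/(y_i₊√y₊ⱼ), which up-weights rare species and is
invariant to uniform count rescaling. Three variable sets feed the
scalogram: **Y**, principal axes of the transformed table; **F**,
principal axes of its fitted values on the standardised environment
(constrained/RDA axes); **R**, principal axes of the residual. Variance
proportions for F and R are taken against the *total* variance of the
centred table, so they decompose it exactly (Pythagoras). Environment
columns are standardised; aliased columns are dropped by pivoted QR; an
environment with as many columns as sites is rejected. Default k = 2 axes
per set.

The scalogram of a focal variable is R²_i = corr²(x, u_i); with the
complete centred basis, Σ R²_i = 1. The smoothing windows partition the
MEM indices into two equal halves by default (broad = 1–11, fine = 12–22
at n = 23). Window sums are tested by site permutation (default), with the
within-window sum as statistic; a max-statistic p over windows is also
reported for family-wise control, and an alternative scheme that permutes
MEM identities within the basis is available behind a flag.

## Diversity estimation

Tsallis entropy S_q = (1 − Σ p^q)/(q − 1); S₁ is Shannon entropy by
continuity. The default q = 0.5 up-weights rare species, consistent with
the estimator's purpose for incomplete vegetation samples; it is exposed
as `--q`. The asymptotic Shannon diversity uses the singleton/doubleton
tail correction with A = 2f₂/((n−1)f₁ + 2f₂) (the f₂ = 0 and f₁ = 0 cases
handled per the published estimator) and is reported on the Hill-number
scale, D_AE = exp(Ĥ), the conventional "effective species" reading of
asymptotic Shannon diversity. Rarefaction is the exact hypergeometric
expectation computed in log space. Counts are aggregated per site (summed
over collections) before estimation; per-collection estimation plus
habitat-by-season summaries run when collection metadata is present.

## Discrimination

Predictor columns are Box-Cox transformed (per-column λ maximised on the
grid −2…2 step 0.1, non-positive columns shifted first), then centred and
scaled. One-way MANOVA with Wilks λ = det(E)/det(E+H) uses Rao's F
approximation, which yields fractional denominator degrees of freedom for
three or more predictors — e.g. F(6, 36) for two predictors and F(9, 41.52)
for three, with four classes and 23 sites. LDA is the classical
pooled-covariance Gaussian discriminant (scikit-learn's implementation
behind the module surface) with uniform or class-frequency priors; the
half split is stratified by habitat when every class has ≥ 2 sites, and a
class missing from a training half is a loud error, never a silent
resample. The MEM predictor set defaults to, per ordination role (Y, F,
R), the axis-1 MEM with maximum R² under the first configured graph, with
a manual override.

## Environmental screening

Gridded layers are plain-matrix CSV on one shared grid (origin at the
minimum-x/minimum-y corner; a point maps to floor((coord − origin)/cell);
maximum-edge points belong to the last cell; extraction is grid-exact,
no interpolation). Slope/aspect come from Horn's 8-neighbour stencil;
aspect is the downslope compass direction with flat cells flagged
undefined. Screening fits one binomial GLM (logit) per candidate layer of
site presence against uniformly sampled background points and retains
variables with slope p < α; a joint 19-predictor model with ~23 presences
would be ill-posed, hence per-variable screening. No multiple-testing
correction by default; a Holm step-down adjustment is available via
``correction="holm"``. Complete separation is flagged and the variable
retained with a warning.

## Synthetic landscape generator

The generator emulates the study design: 23 sites uniform in a 10×10
extent with minimum separation 1% of the diagonal, four habitat labels
(Crop, Edge, Oak, Wasteland) assigned by a blocked draw guaranteeing two
sites per habitat when sites permit (group tests need ≥ 2 members per
class), ~300 species, negative-binomial counts with mean 50 and
overdispersion 0.3 (Poisson at 0), and five environmental columns — one
exactly the broad spatial gradient (the standardised first principal
direction of the coordinates), the rest squared-exponential GP surfaces
(range 4.0) plus a categorical cover block. Layouts whose β = 3 skeleton
is disconnected are redrawn, since the analysis presumes a usable MEM
basis under every hypothesis.

Per species s and site i,
log μ ∝ broad·bl_s·g_i + fine·fl_s·u_i + o(h_i, s) + c(h_i)·z_s, with the
fine signal injected through an actual trailing MEM (index ⌈0.75(n−1)⌉)
of the Gabriel-graph basis over the same sites, so the truth is exactly
expressible in the detector's basis. Expected abundances are normalised
per site (softmax over species), which fixes each site's relative
composition to exp(η) and the marginal count mean to `mean_abundance`;
per-species normalisation was rejected because it leaks one habitat's
unevenness into the others' relative abundances. The optional
`habitat_evenness` map concentrates abundance on a shared species ranking
z_s with habitat-specific strength, producing a controlled diversity
ordering (used with Crop 2.5, Edge 1.5, Oak 0.75, Wasteland 0.0).

What the generator does *not* emulate: temporal/seasonal dynamics,
taxonomic structure, spatially autocorrelated habitat patches (labels are
spatially random), or observation effort differences between sites.
Passing tests therefore demonstrate correctness of the machinery and
detectability of the injected structure, not field realism.

## Fixture parameters and problem sizes

Effect sizes have no empirical anchors, so fixture values were chosen for
clear test behaviour: fine-scale power runs use fine = 1.5 (power ≈ 1 at
n_perm = 199 over 40 landscapes); calibration runs use 200 landscapes
with all effects zero; the discrimination contrast uses 10 replicate
landscapes with the evenness gradient above, broad = 0.6 and habitat
offset SD 0.15. The contrast is reported as a distributional statement —
diversity MANOVA significant in every replicate, MEM MANOVA
non-significant in the majority — because max-R² MEM selection feeds the
(random) habitat pattern back through the community's residual axes, so
single replicates can produce a nominally significant MEM MANOVA by
selection alone.

## Numerical choices

- Null eigenvalue tolerance 1e-10 (relative); orthonormality asserted at
  1e-8; scalogram unit sums at 1e-8.
- Permutation p-values use the (1 + extreme)/(n_perm + 1) estimator:
  valid (never zero), floor 1/(n_perm + 1).
- Result tables are TSV at 17 significant digits, so write/read
  round-trips float64 exactly.
- All randomness flows from one seed: the pipeline derives a named
  generator per stage from a CRC of the stage name, so stages are
  insensitive to each other's draw counts and runs are byte-reproducible.

## Known limitations

- Replication of the original field tables requires the externally
  deposited data (fetching is manual); the loaders accept its generic
  CSV layout but no numerical claims about the field data are made here.
- The smoothing statistic is the within-window R² sum; the max-statistic
  variant is reported alongside but is not the default decision rule.
- Forward selection of individual MEMs and eigenvalue-sign-restricted
  subsets are out of scope (the analysis uses the full basis in two
  windows).
- GeoTIFF input is not supported; gridded layers must be supplied as
  plain-matrix CSV on a pre-aligned grid.
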