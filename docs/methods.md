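# Methods

This note documents the models and procedures implemented in `betascape`,
the choices made where the design was genuinely open, and what the synthetic
data do and do not establish about real data.

## Diversity partitioning

Diversity is Rao's quadratic entropy Q(p) = Σ_ij d_ij p_i p_j over relative
abundances p and pairwise species dissimilarities d_ij ∈ [0, 1], transformed
to equivalent numbers D = 1/(1 − Q) (Jost's correction) so that alpha, beta
and gamma are on an effective-species scale and obey γ_eqv ≥ α_eqv.

Two conventions are open in this framework and are explicit, flag-switchable
choices here:

- **Gamma pooling** (`gamma_weighting`): the pooled unit vector p̄ is the
  *equal-weight* mean of the communities' relative-abundance vectors
  (default). This makes γ insensitive to unequal total counts across point
  counts, which largely reflect detection rather than community size. An
  abundance-weighted pooling (summing raw counts) is available.
- **Alpha averaging** (`alpha_averaging`): the Jost transform is applied to
  the *mean raw Q* across communities, α_eqv = 1/(1 − mean Q) (default),
  matching the additive Rao partitioning convention in which alpha is
  averaged on the entropy scale before conversion. Averaging community-wise
  equivalent numbers instead is available.

β_prop = 100 · (γ_eqv − α_eqv)/γ_eqv is reported on a 0–100 scale: it is a
proportion of regional diversity, and the percentage scale keeps intercepts
and effect sizes in readable units.

With the defaults, γ_eqv ≥ α_eqv holds exactly for the distance families the
package builds (0/1, Euclidean, patristic): all are conditionally negative
semidefinite, which makes Q concave on the simplex, so Q(p̄) ≥ mean Q. This
would *not* be guaranteed for an arbitrary symmetric matrix in [0, 1]; the
property tests therefore draw from the three facet constructions.

Relative-abundance vectors must sum to 1 within 1e-9. Renormalization happens
only after an explicit, logged species drop (see the phylogenetic facet),
never silently.

## Distance matrices

- **Taxonomic**: d_ij = 1 for i ≠ j. Rao's Q then equals the Gini–Simpson
  index and the equivalent number the inverse Simpson index — this identity
  is asserted to 1e-12 in the tests.
- **Functional**: each of the 20 traits is min–max scaled to [0, 1] to give
  traits equal weight (a constant column, which carries no dissimilarity
  information, maps to zeros with a warning rather than an error); distances
  are Euclidean and divided by the maximum observed pair, so the rescaling is
  order-preserving and the largest dissimilarity is exactly 1.
- **Phylogenetic**: a strict majority-rule consensus of the candidate tree
  set — a bipartition enters iff it occurs in *strictly more than* the
  threshold fraction (default 0.5) of trees; ties at the threshold are
  excluded. Tip-to-tip patristic distances on the consensus are divided by
  the maximum pair.

**Consensus branch lengths** are undefined in the abstract majority-rule
construction; common consensus tools variously store clade frequencies or
summaries there. Here each consensus branch receives the **mean length of its
bipartition across the input trees that contain it** (leaf branches: mean
across all trees). This is deterministic, preserves the scale of the input
branch lengths, and reduces to the input lengths when all trees agree.
Species absent from the consensus (possible only when tip sets vary) would be
dropped from the phylogenetic facet only, with a logged list and abundance
renormalization; the taxonomic and functional facets always keep the full
pool.

## Regression layer

The six predictors are screened with variance inflation factors
(VIF_j = 1/(1 − R²_j)); any VIF ≥ 3 aborts the run with a report.

The **model chooser** (`select_and_fit`) codifies a residual-diagnostics
workflow into a deterministic rule:

1. fit OLS;
2. if |skewness| of the OLS residuals exceeds 0.5 (configurable) and the
   response is strictly positive, refit as a Gamma GLM with identity link
   (OLS starting values, IRLS, up to 500 iterations); a Gamma candidate that
   cannot reach convergence with positive fitted means falls back to the OLS
   fit (recorded in the diagnostics) rather than aborting;
3. run a Moran's I permutation test on the current residuals; if p < 0.05,
   refit as a spatial error model — on the log response (with exp
   back-transform of fitted values) when the skewed branch had fired, since
   the spatial ML fit has no Gamma analogue here.

The skewness threshold replaces a visual normality check; 0.5 is a
conventional boundary between approximate symmetry and moderate skew.
Response-scale residuals are Moran-tested for the GLM (a flag could expose
deviance residuals; response residuals are what the spatial refit models).

**Moran's I** is I = (n/S0)·(z′Wz)/(z′z) with z centered. The permutation
test permutes z, centers on the permutation mean, and uses the two-sided
+1-corrected p-value p = (1 + #{|I* − E| ≥ |I − E|})/(n_perm + 1) — never
exactly zero, slightly conservative (observed type-I ≈ 0.03–0.05 at nominal
0.05). It is invariant to positive rescaling of the residuals.

**Spatial weights** are k-nearest-neighbour (default k = 8), symmetrized by
union and row-standardized. kNN is robust on irregular subsets of a grid
where contiguity neighbourhoods can leave islands; distance ties are broken
deterministically by unit order. Because the underlying adjacency is
symmetric, the row-standardized W is similar to a symmetric matrix and has a
real spectrum.

**Spatial error model**: y = Xβ + u, u = λWu + ε, ε ~ N(0, σ²I), fitted by
maximum likelihood with the likelihood concentrated over (β, σ²). For trial
λ, β is OLS on the filtered variables (I − λW)y, (I − λW)X; the profile
log-likelihood adds the exact Jacobian ln|I − λW| = Σ ln(1 − λe_i) from the
eigenvalues of W. λ is optimized by bounded scalar minimization (tolerance
1e-8) on the admissible interval (1/e_min, 1/e_max); a solution at the
boundary warns. Eigenvalue-based evaluation is exact and fast for the
hundreds of units this package targets; no sparse approximations are used.
Standard errors: cov(β̂) = σ̂²(X_A′X_A)⁻¹ with X_A = (I − λ̂W)X; the λ
standard error comes from the curvature of the profile likelihood at λ̂
(valid because β and λ are information-orthogonal in this model). At λ = 0
the fit reproduces the OLS estimates and Gaussian log-likelihood to 1e-8.
Reported residuals are the whitened innovations ε̂ = (I − λ̂W)(y − Xβ̂),
which a post-fit autocorrelation check should see; the spatially structured
residuals y − Xβ̂ are kept in the diagnostics.

No multiple-testing correction is applied across the nine responses or seven
coefficients; per-coefficient p-values are reported as-is and the run
metadata says so implicitly by reporting raw p-values only.

## Synthetic data

The generators emulate a state-wide breeding-bird point-count design:

- **Landscape**: `n_units` (default 287) unit centroids on a near-regular
  grid with spacing 19.3 (km-scale planar units; only relative positions
  matter). Covariates are simultaneous-autoregressive (SAR) fields
  (I − ρW)⁻¹ε on the unit kNN graph with ρ = 0.6 by default. HFI and forest
  loss load on one shared latent field with opposite signs (correlation
  ≈ −0.5), mimicking the spatial segregation of settled areas and areas of
  forest loss; HFI is centered near 30 (sd 15, clipped to [0, 100]), forest
  loss is right-skewed (median ≈ 4%), NPP ≈ 0.5 ± 0.08 kg C/m²/yr,
  habitat diversity ≈ 4 ± 1.2 on a 1–11 scale, mean temperature
  ≈ 4.5 ± 1.5 °C. Points per unit are 3 + beta-binomial on 0–15
  (mean ≈ 7.2, sd ≈ 2.9, max 18). The default correlation structure keeps
  all VIFs well below 3 so the screening step passes by construction.
- **Species pool** (default 162 species): diet (10 categories) and foraging
  stratum (8 categories) proportions on a 10-unit grid summing to 100, with
  per-species Dirichlet concentration drawn uniformly so the pool mixes
  specialists and generalists; activity time on a 20-unit grid skewed toward
  fully diurnal; log-normal body mass (median 30 g). The phylogeny is a Yule
  tree; the candidate tree set holds `n_trees` (default 1000) variants with
  NNI moves (probability 0.1 per internal branch) and multiplicative
  branch-length jitter, so consensus building is exercised nontrivially.
- **Communities**: species-level baseline log-abundances and occupancy
  logits are drawn once per pool; expected log-abundance per community adds
  standardized-covariate effects and a unit random effect (sd 0.3); counts
  are negative binomial (size 2) — point counts are overdispersed, and the
  pipeline must not assume equidispersion. *Specialism* is the trait-space
  distance from the pool centroid (scaled to [0, 1]); specialist occupancy
  decays with unit HFI as exp(−h·s_i·HFI_u) with h =
  `homogenization_strength`. In **local** mode the decay thins each
  community independently (eroding alpha while gamma is comparatively
  spared — beta rises with HFI); in **uniform** mode whole-unit presence
  decays (eroding alpha and gamma together — communities share a smaller
  pool and beta falls with HFI). Empty communities are redrawn up to ten
  times, then the most abundant species is forced in with count 1.

Every generator is a pure function of (config, seed); independent seed
streams per stage keep the landscape, pool and communities reproducible in
isolation.

**What the synthetic data do not emulate**: the detection process (distance
sampling, observer or date effects), raster-derived covariates, range
dynamics, trait–phylogeny correlation (traits and tree are independent), and
any real species identities. Passing tests therefore establish that the
*computational pipeline* is correct and that the *inferential layer* detects
the mechanisms it is pointed at with the stated power — not that any
particular ecological conclusion holds in real data.

## Problem sizes and numerical tolerances

- Oracle equivalences (Rao vs brute force, inverse-Simpson identity, Moran
  vs double loop, functional distances vs per-pair computation) are asserted
  to 1e-12 on 50–1000 random instances of ≤ 12 species / ≤ 30 units.
- Spatial-error recovery uses λ = 0.6, β = (1, 0.5, −0.3), n = 300 units,
  200 replicates (mean absolute bias of λ̂ and β̂ below 0.05); the chooser
  audit 50 replicates per regime at n = 150; Gamma GLM recovery 100
  replicates at n = 1000; Moran calibration 1000 datasets of n = 100 with
  199 permutations.
- End-to-end experiments run 50 replicate pipelines at the default 287-unit,
  162-species scale with the functional facet (a single candidate tree,
  since the phylogenetic facet is not under test there), and the analysis
  permutation count at 199; single complete runs use all three facets with
  the full 1000-tree set.

## Known limitations

- The Gamma GLM with identity link is not guaranteed to converge for every
  positive response; the chooser's OLS fallback keeps runs alive but means a
  skewed response can be modeled as Gaussian in rare replicates.
- Majority-rule consensus branch lengths are a convention (mean over
  supporting trees), not an estimate of evolutionary distance; patristic
  distances on a consensus inherit that convention.
- The spatial error ML uses dense eigenvalue decomposition: exact, but
  O(n³) — appropriate for hundreds of units, not tens of thousands.
- The greedy pairwise point-deduplication filter processes pairs in
  deterministic order; like any greedy rule it does not maximize the number
  of retained points.
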