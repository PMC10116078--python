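# betascape

Diversity partitioning and spatial regression for landscape-scale bird
community data — a tested, fully synthetic-data-capable pipeline for asking
whether human pressure homogenizes communities.

## The problem

Biotic homogenization is the loss of compositional differences among local
communities: beta-diversity declines as specialists drop out and widespread
generalists take over. Detecting it at landscape scale requires (1) measuring
beta-diversity per sampling unit in a way that is comparable across units with
different numbers of local communities and across *facets* of diversity
(taxonomic, functional, phylogenetic), and (2) regressing those measures on
human-pressure gradients while respecting the spatial structure of the data.

`betascape` implements that workflow for point-count data: local communities
(point counts) nested in landscape units, a species trait table, a set of
candidate phylogenies, and unit-level covariates (human footprint index,
forest loss, NPP, habitat diversity, mean temperature, sampling intensity).

## The statistic at the core

For a unit with local communities *k* = 1..K and species relative abundances
p, diversity is Rao's quadratic entropy with pairwise species dissimilarities
d_ij ∈ [0, 1]:

    Q(p) = Σ_i Σ_j d_ij p_i p_j

converted to an equivalent number (Jost's correction) D = 1/(1 − Q). Then

    α_eqv = 1 / (1 − mean_k Q(p_k))          mean local diversity
    γ_eqv = 1 / (1 − Q(p̄)),  p̄ = mean_k p_k   pooled unit diversity
    β_prop = 100 · (γ_eqv − α_eqv) / γ_eqv    proportional beta (0–100)

β_prop is the share of unit-level diversity due to differences among local
communities, comparable across units with unequal K and across facets. The
three facets differ only in d_ij:

- **taxonomic** — d_ij = 1 for i ≠ j (Rao reduces to Gini–Simpson, D to
  inverse Simpson);
- **functional** — Euclidean distance between min–max-scaled 20-trait
  vectors (diet, foraging stratum, activity time, body mass), rescaled by
  the maximum pair;
- **phylogenetic** — patristic distance on a strict (>50%) majority-rule
  consensus of a tree set, rescaled by the maximum pair.

Each of the nine responses (3 facets × α/β/γ) is regressed on six unit
covariates through a deterministic model chooser mirroring standard residual
diagnostics: OLS; Gamma GLM (identity link) if the OLS residuals are skewed
and the response is positive; and a maximum-likelihood spatial error model
(y = Xβ + u, u = λWu + ε) if a Moran's I permutation test finds residual
spatial autocorrelation — on the log response when the skewed branch had
fired. VIF screening (< 3) runs first.

## Worked example

All stages run on synthetic data with realistic structure (a near-regular
grid of ~landscape units, spatially autocorrelated covariate fields, a Yule
phylogeny with noisy candidate trees, negative-binomial counts, and a tunable
specialist-loss mechanism). From a shell:

```bash
cat > example.yaml <<EOF
simulation:
  n_units: 60
  n_species: 40
  n_trees: 50
  homogenization_strength: 0.05
analysis:
  n_perm: 999
EOF
betascape --config example.yaml --seed 42 --outdir demo all
```

This simulates inputs (written under `demo/inputs/`), runs the full pipeline,
writes `demo/diversity.csv`, nine `demo/coef_*.csv` tables and a
`demo/run_summary.yaml`, and prints a summary per response. The functional
beta-diversity block reads:

```
Response: functional_beta    family: gamma-identity-glm
n = 60    log-likelihood = -199.5770
             Estimate  Std. error  t value    p value
Intercept       3.133       9.758   0.3211     0.7482
hfi             0.705     0.07226    9.757  1.723e-22
forest_loss    0.3958      0.1745    2.268    0.02336
npp             10.77       12.88   0.8363      0.403
habitat_div    0.0848      0.7757   0.1093     0.9129
mean_temp     -0.9451      0.6208   -1.522     0.1279
n_points       0.5393       0.301    1.792    0.07317
residual Moran's I = -0.0912 (perm. p = 0.193)
VIF: hfi=1.39, forest_loss=1.29, npp=1.36, habitat_div=1.25, mean_temp=1.12, n_points=1.04
model chooser branch: gamma-glm
```

The generating mechanism here thins specialist occupancy within communities
as the human footprint index (HFI) rises, eroding local (alpha) functional
diversity while leaving the unit-level pool largely intact — so functional
β_prop rises with HFI, and the fitted HFI coefficient is positive and highly
significant. The chooser selected the Gamma GLM because the OLS residuals of
the (bounded-below, right-skewed) beta response were skewed; no residual
spatial autocorrelation remained, so no spatial error refit was needed.

The same objects are available as a library:

```python
from betascape import SimulationConfig, simulate_dataset, run_analysis

data = simulate_dataset(SimulationConfig(seed=42, n_units=60, n_species=40, n_trees=50,
                                         homogenization_strength=0.05))
report = run_analysis(data, seed=42)
print(report.models["functional_beta"].summary())
```

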