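# islandveg

Plot-scale analysis of island vegetation: which parts of the local
environment and the surrounding seascape structure explain the composition,
species richness and species evenness of plant communities in contrasting
insular habitats (rocky shore, semi-natural grassland, coniferous forest)?

The package is aimed at vegetation ecologists working with plot-based
(relevé) survey data from archipelago landscapes.  It implements the whole
chain from raw ordinal cover codes to variance-partitioning report tables,
and ships a seeded synthetic-archipelago generator so the entire pipeline is
testable without any field data.

## What it computes

**Community data.**  Ordinal cover-abundance codes (nine-step extended
Braun-Blanquet scale, configurable dialect) are converted to class-midpoint
proportions, arcsine-square-root transformed, and rare species are
down-weighted (weight `f / (f_max/5)` for species with occurrence frequency
`f < f_max/5`).  Predictors are min-max scaled to [0, 1] per habitat and
screened for collinearity (Pearson `|r| > 0.6`, the higher-priority variable
is kept).

**Diversity proxies.**  Species richness; Smith–Wilson evenness

    E_var = 1 − (2/π)·arctan( (1/S) Σ_s (ln x_s − mean ln x)² )

over the S species present; and the cover-weighted mean Ellenberg moisture
value (EIV_M) as a soil-water proxy.

**Grazing-history index (GHI).**  Grassland indicator species are classed by
their trajectory after grazing abandonment (A: early decline/extinction,
B: medium-term decline, C: long-term decline).  All admissible
phase-change combinations are ranked and projected linearly onto 0–100
(most grazing-dependent trajectory → 100).  A plot's GHI is the mean value
of its indicator species present, so recently grazed plots score high.

**Landscape predictors.**  Relative wave-exposure index
`REI = Σ_i V_i P_i F_i` over eight compass directions (speed × frequency ×
fetch, fetch by ray-casting against the island geometry); proximity index
`PROX = Σ_j a_j / d_j²` over landmasses within 500 m; distance to the
mainland or nearest island ≥ 50 ha (DMI); and island-configuration metrics
(ISL_A, HAB_A, R_COV, T_COV).

**Composition (constrained ordination).**  Total inertia, CA, CCA and
partial CCA built from the χ²-standardised plot × species table; Monte-Carlo
permutation forward selection within each variable-set (region always
partialled out; Benjamini–Hochberg FDR on the step p-values); a full CCA on
all surviving variables; and gross/net variance partitioning: per set, ETV%
(canonical inertia over total inertia) and EMV% (share of the full-model
canonical inertia), controlling for region only (gross) or for all other
selected variables (net).  Gradient lengths come from DCA axis 1 with
nonlinear rescaling, in SD units of species turnover.

**Diversity (mixed models).**  Richness and evenness are modelled with
region/island nested random intercepts, fitted by an in-package REML/ML
optimiser (cross-checked against lme4).  Backward selection by single-term
likelihood-ratio tests yields a minimal adequate model; marginal and
conditional pseudo-R² (fixed-effects variance over total, and fixed plus
random over total) quantify explained variance, and the marginal R² is
attributed to variable-sets in proportion to the absolute fixed-effect
estimates on the common [0, 1] predictor scale.

## Worked example

```bash
islandveg simulate --seed 1 --out simulated
islandveg analyze-composition --input simulated --habitat grassland \
    --seed 1 --n-perm 199 --out results
```

which prints (seed 1):

```
grassland: TI=1.811 ETV=43.7% F=10.65 p=0.0050 gradient=2.75 SD
reports in results
```

Reading: the grassland plot × species table carries a total inertia of 1.81;
the forward-selected environmental variables jointly explain 43.7 % of it
(permutation p = 0.005 at 199 permutations), and the first DCA axis spans
2.75 SD of species turnover.  `results/composition_partition.csv` holds the
per-set gross/net ETV%/EMV% table; on this synthetic archipelago the
grazing-history set explains 9.7 % ETV (22.3 % EMV) of grassland
composition gross, 9.4 % ETV net of all other sets, and sets simulated
without effects are reported `n.s.`.

The diversity workflow is analogous:

```bash
islandveg analyze-diversity --input simulated --habitat grassland \
    --seed 1 --out results
```

prints `mR²`, `cR²` and the full-model explained variance (cR²·100) per
proxy:

```
grassland/richness: mR2=0.244 cR2=0.661 full-model ETV=66.1%
grassland/evenness: mR2=0.514 cR2=0.535 full-model ETV=53.5%
```

and writes the per-set attribution table to
`results/diversity_partition.csv`.

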