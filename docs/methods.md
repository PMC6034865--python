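# Methods

This note documents the models, numerical choices and open design decisions
behind `islandveg`, in the order of the analysis chain.

## Cover scale and preprocessing

Cover is recorded on a nine-step ordinal scale (r, +, 1, 2m, 2a, 2b, 3, 4, 5).
The default dialect maps each code to its class-interval midpoint as a
proportion: r = 0.001, + = 0.005, 1 = 0.025, 2m = 0.05, 2a = 0.10,
2b = 0.205, 3 = 0.375, 4 = 0.625, 5 = 0.875.  Exact class boundaries vary
between field traditions, so the dialect is a configurable object; readers
also accept plain percentages (divided by 100), since deposited datasets
sometimes store them directly.  `discretize` inverts the mapping by class
interval, so midpoints are fixed points of the round trip.

Cover proportions are arcsine-square-root transformed before ordination
(variance stabilisation for proportions; 0 maps to 0, 1 to pi/2).  Rare
species are down-weighted with the proportional rule used by constrained
ordination software: species with occurrence frequency `f < f_max/5` get
weight `f/(f_max/5)`, others 1; the weights multiply the chi-square
standardised residual columns by `sqrt(weight)`, which scales each species'
inertia contribution by its weight.  The exact formula behind "rare species
down-weighted" in published CCA workflows is a software convention; this
choice is documented rather than guaranteed to match any specific program.

Predictors are min-max scaled to [0, 1] within each habitat's plot subset
(0/1 design dummies exempt).  The collinearity screen drops, from every pair
with Pearson `|r|` strictly above 0.6, the variable lower in a user-supplied
priority order ("ecological significance" is a judgement the caller makes);
dummies bypass the screen because factors such as region are design
variables, not candidates for removal.  Region enters every analysis as
drop-first dummy coding rebuilt per habitat, so the dummies stay full rank
when a habitat spans only two regions.  Soil-type dummies (three categories
summing to one) likewise drop their reference level (rock).

## Diversity proxies

Richness is the count of species present.  Evenness is Smith-Wilson
`E_var = 1 - (2/pi) arctan(Var(ln x))` with the population variance over the
species present; it is invariant to rescaling abundances.  A one-species
plot is assigned E_var = 1 (zero log-variance) as a guarded convention —
observed plots can have as few as two species, so the case occurs only in
degenerate data.  Whether evenness should be computed on transformed or raw
covers is not standardised; the default is raw cover proportions, switchable.
The moisture proxy EIV_M is the cover-weighted mean Ellenberg moisture value
over the present species that have one (a presence-weighted variant is
available; "weighted mean indicator value" in the survey literature usually
means cover-weighted).

## Grazing-history index

Indicator species fall into categories by their post-abandonment trajectory
across three phases (T1 early, T2 intermediate, T3 late), with phase codes
ordered `dead < -2 < -1 < X < +1 < +2`.  Admissible combinations per
category ship as an editable CSV; the bundled default is a synthetic
stand-in constructed from the category definitions (category A declines or
dies out in T1; B holds or increases in T1 and collapses by T2; C increases
through T2 and declines in T3), not a transcription of any published table.
Combinations are ranked by the sum of their phase-code ordinals (ties broken
lexicographically), i.e. by how early and completely the species' quantity
collapses, and projected linearly onto 0-100 with rank 1 (earliest collapse,
the most grazing-dependent trajectory) at 100.  A plot's GHI is the
unweighted mean of the values of indicator species present (cover-weighted
variant available), and is only defined for grassland plots; the scale
direction is invertible by flag.  GHI is relative — it orders plots along
post-abandonment regression and makes no claim about calendar years.

## Landscape predictors

Geometry is planar metric; islands are shapely polygons.  Fetch is computed
by casting a ray per compass direction and taking the distance to the first
intersected landmass, capped at a configurable open-sea maximum (default
25 km in the generator); bathymetry-weighted wave models are out of scope,
so REI here is the wind-climate product-sum `sum_i V_i P_i F_i`.  PROX uses
squared edge-to-edge distance (the FRAGSTATS convention) over landmasses
within 500 m; a site lying on another landmass is an error (exclude the home
island).  DMI takes the minimum edge distance to the mainland or any island
of at least 50 ha.

## Constrained ordination

All correspondence-analysis machinery operates on the chi-square
standardised matrix `S = (P - rc') / sqrt(rc')` of the table scaled to unit
total.  Total inertia is `||S||_F^2` (the chi-square statistic over the
table total); CA is the SVD of S.  CCA projects the rows of S onto the
orthonormalised span of the mass-centred, `sqrt(mass)`-scaled constraint
columns before the SVD; pCCA first removes the covariable span from both S
and the constraints.  These reductions were verified against vegan's
`cca()` to 6+ significant digits.  Eigenvalues below 1e-12 are discarded;
collinear constraint sets raise an error naming the dependent columns
(rank loss after partialling is legitimate and tolerated).

The pseudo-F statistic is
`F = (canonical/q) / ((TI - canonical - covariable)/(n - q - q_cov - 1))`.
Permutation tests are unrestricted: the constraint table is residualised on
the covariables under plot-mass weighting, its plot rows are permuted, each
permutation is refit (including re-residualisation), and
`p = (1 + #{F* >= F}) / (1 + n_perm)`.  Forward selection runs within each
variable-set with region as a permanent covariable: greedily add the
candidate with the largest additional canonical inertia, record its
permutation p, and after the set is exhausted FDR-adjust (Benjamini-
Hochberg) and drop members with adjusted p above alpha; an empty selection
is reported as non-significant, not an error.  Variance partitioning fits
the full CCA on all selected variables of all sets; per set, the gross
effect partials out region only (region's own gross effect has no
covariables) and the net effect partials out all other selected variables.
ETV% divides canonical inertia by TI, EMV% by the full-model canonical
inertia; EMV values of disjoint sets need not sum to 100 because sets share
variance.

DCA axis 1 equals CA axis 1 up to rescaling (detrending by segments affects
higher axes only).  The nonlinear rescaling iterates: plot scores are
abundance-weighted means of species scores; the axis is cut into segments
(default 26); per segment the mass-weighted mean within-plot variance of
species scores is estimated, interpolated across empty segments and
smoothed with a (1/4, 1/2, 1/4) kernel; the axis is stretched so local
within-plot SD is one; four iterations by default.  The reported gradient
length is the range of rescaled plot scores in SD units.  This is the
largest numerical-compatibility risk relative to legacy DCA programs;
against vegan's `decorana` the lengths agree to roughly 10-20% on test
coenoclines, and a simulated gradient spanning four tolerance units measures
3.8-3.95 SD.

## Mixed models

Diversity responses are modelled as `y = X beta + a_region + b_island + e`
with independent Gaussian intercepts.  The covariance `sigma2 W` with
`W = I + g_r Z_r Z_r' + g_i Z_i Z_i'` is low-rank, so the profiled REML (or
ML) log-likelihood is evaluated through Woodbury/determinant identities on
the (regions + islands)-dimensional cross-products — exact and fast for any
nesting.  Optimisation runs over `(log g_r, log g_i)` with explicitly
evaluated boundary sub-models (either or both ratios zero) and three
deterministic Nelder-Mead multistarts; the best candidate wins, and ratios
below 1e-9 are reported as exact boundary zeros.  Against lme4 the fits
agree to ~1e-5 in coefficients, variance components and the REML criterion;
in balanced nested designs the estimates match closed-form nested-ANOVA
method-of-moments estimators to 1e-6.

Model reduction uses single-term-deletion likelihood-ratio tests on ML
refits (chi-square, 1 df), dropping the largest-p term while it exceeds
alpha; the minimal adequate model is refit by REML.  This is a deliberate,
documented choice where software traditions differ (Satterthwaite-type
denominator degrees of freedom would give slightly different p-values).

Pseudo-R2 follows the fixed-vs-random variance decomposition:
`mR2 = var(X beta) / (var(X beta) + s2_region + s2_island + s2_resid)` with
the population variance of the fixed predictor across observations, and cR2
adds the random-intercept variances to the numerator.  With all random
components at the boundary, an ML fit reproduces the OLS coefficient of
determination exactly.  Set attribution divides the marginal R2 among
variable-sets in proportion to the sums of absolute fixed-effect estimates
on the common [0, 1] predictor scale — the only aggregation of "estimators"
that is dimensionally coherent across variables; squared estimates are
available by flag, and the intercept belongs to no set and is excluded.
The random term contributes `cR2 - mR2`; EMV% rescales by cR2 so set plus
random contributions sum to 100.

## Synthetic archipelago

The generator targets the statistical structure the analyses assume, not
spatial mechanism.  Defaults: 3 regions of 10 islands; up to 3 plots per
habitat per island; rocky shore in all regions, grassland and forest each
absent from one region (mirroring a three-archipelago design with partial
overlap); habitat species pools of 165/155/128.  Species respond to two
latent gradients (a soil-pH axis and a moisture axis; grassland adds the
abandonment-time axis) with Gaussian response curves — tolerance 1 on a
span-4 gradient — times lognormal noise (sigma 0.5), truncated at 1,
discretised to cover codes, with covers below 0.002 unrecorded.  Plot
suitability carries region and island random intercepts (sd 0.5 each) and a
pH effect, and thins species occurrence through a logistic link, so
richness inherits the nested random structure.  Grassland indicator
occurrence declines logistically with island abandonment time at
category-specific thresholds (A 0.25, B 0.55, C 1.2 on the unit interval —
C species decline only beyond the observed window, so GHI is defined for
every plot, as in a field survey where indicator-free pastures would not be
scored).  Island geometry is circles in three 60-km-offset region boxes
with a rectangular mainland coastline south of all regions (so distance to
the mainland varies within, not between, regions); landscape predictors are
computed from this geometry with the landscape module.  Moisture traits are
noisy linear images of the species' moisture optima, so EIV_M is a
community-derived, imperfect proxy of the true gradient — as in real data.

What the generator does not emulate: spatially autocorrelated environments,
species dispersal and co-occurrence structure beyond shared gradients,
observer error in cover estimation beyond discretisation, and temporal
change.  Passing recovery tests therefore demonstrates correctness of the
estimators under the assumed model, not robustness to violations of it.

A separate direct generator (`simulate_lmm_dataset`) draws
`y = X beta + a_region + b_island + e` with uniform predictors for
mixed-model recovery tests.

## Problem sizes in the test-suite and acceptance runs

Unit and property tests run on reduced configurations (e.g. 3 regions x 5
islands x 2 plots, pools of 35-45 species) chosen so the full suite
completes in a few minutes; the acceptance script runs the generator
defaults (210 plots, 448 observed taxa at seed 1) with 999 permutations.
Monte-Carlo property checks use 1000 null datasets (permutation size),
200 selection replicates and 500 REML replicates, matching the scales at
which their tolerances (0.05 ± 0.01 type-I rate, ≥ 95% driver recovery,
4-standard-error unbiasedness bands) are meaningful.

## Known limitations

- DCA rescaling is a reimplementation of an under-specified legacy
  algorithm; gradient lengths can differ from other programs by ~10-20%.
- The GHI rules file is a constructed default; reproducing a specific
  published indicator system requires supplying its actual combination
  tables.
- Permutation p-values use the `(1 + x)/(1 + N)` convention; programs using
  `x/N` differ at the resolution limit.
- The LMM assumes Gaussian responses for richness (count data); this
  follows the analysis design the package mirrors rather than best count
  practice.
- Forward selection does not refit earlier steps after FDR-dropping later
  ones; with strongly collinear within-set candidates the surviving set can
  differ from an exhaustive search.
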