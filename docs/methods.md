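# Methods

## Trait model and estimation targets

All analyses are built around one Gaussian linear mixed model for a ring
trait y of tree i (genet j, spatial group k) in year t:

    y_ijkt = μ + year_t + β·cDBH_it + g_j + s_k + u_i + e_ijkt

with independent Gaussian effects g ~ N(0, σ²G) (genet), s ~ N(0, σ²S)
(spatial group), u ~ N(0, σ²tree), and a residual e that is a stationary
first-order autoregressive series within each tree (coefficient ρ, lag
measured in calendar years, marginal variance σ²R optionally scaled by a
per-group SD multiplier). Year enters as a categorical fixed effect —
the common climate signal — and cumulative DBH as a covariate proxying
tree size. In a layering population genets are spatially nested in
groups, so g and s are confounded by design; the package's synthetic
generator can either reproduce that nesting (`confounded=True`, the
default) or cross the two factors, which is the clean design a field
study cannot achieve.

## REML engine

Variance parameters are estimated by restricted maximum likelihood with
the nlme convention l_R = −½[log|V| + log|XᵀV⁻¹X| + rᵀV⁻¹r +
(n−p)·log 2π]. Writing V = σ²R·V0(γ, ρ, m) with γ = σ²rand/σ²R and m the
per-level residual SD multipliers (reference level fixed at 1 for
identification), σ²R and the fixed effects are profiled out exactly, so
the optimizer (L-BFGS-B with numerical derivatives) works on the
unconstrained scales log γ, atanh ρ and log m only. V0 is block-diagonal
over random-factor levels; within a block the AR(1) correlation is
ρ^|Δyear|, so missing years are handled by powers of ρ. Three optimizer
starts are used by default (a deterministic start plus two seeded
jitters; replicated simulation studies use one start — the profiled
surface is well-behaved at these sizes). Proposals with non-positive-
definite covariance get a large finite penalty rather than an infinity,
keeping finite differences defined. γ is bounded below at e⁻²⁵; fits at
that boundary report σ²rand = 0.

AICc = −2·l_R + 2k + 2k(k+1)/(n−k−1) with k counting fixed-effect
coefficients plus all variance parameters (σ²rand, σ²R, ρ if present,
and the free multipliers). Models with different fixed-effect structures
are compared by REML AICc — the procedure this analysis chain defines —
despite the textbook caveat about REML likelihoods and fixed effects;
the model-selection simulation studies validate the operating
characteristics of exactly this procedure. Fits are cross-checked in the
tests against statsmodels MixedLM (random-intercept case) and against
brute-force numerical maximization of an independently coded dense
restricted likelihood (AR(1) + heteroscedastic case, ≤ 12 observations,
agreement to 1e-4 in l_R).

Sequential (type-I) F tests of the fixed terms whiten the data with the
estimated V̂ and difference the residual sums of squares term by term;
because σ̂²R is the REML profile estimate, the whitened full-model RSS
equals n−p exactly and no further rescaling is involved. Denominator
degrees of freedom follow the containment rule: columns constant within
random-factor levels are tested against (levels − between-level
columns), the rest against (n − levels − within-level columns). A
1000-replicate null simulation puts the grouping-term rejection rate at
the nominal 5% within Monte-Carlo error.

## Heritability estimators

Only trees growing in clonal groups enter the estimators.

* **H²_raw** — one-way ANOVA method of moments on the tree-year values:
  σ̂²G = (MSB − MSW)/n₀ with the unequal-group-size correction
  n₀ = (N − Σn²ᵢ/N)/(a−1), σ̂²P the total sample variance, ratio clamped
  to [0, 1] (negative moment estimates reported as 0 and flagged). The
  estimator runs on tree-year values, not per-tree means: averaging 11
  years would shrink the within-clone variance ≈ 11-fold and push H²_raw
  toward 1 regardless of the truth, and only the tree-year form makes
  σ²P the total phenotypic variance that the definition divides by. The
  price is that the common year signal inflates σ²P, so H²_raw is
  conservative when year-to-year variance is large.
* **H²_pred** — the identical ANOVA applied to fixed-effects-only
  predictions of the model trait ~ genet + year + cDBH (tree random,
  AR(1), per-genet residual multipliers) evaluated on data where every
  tree follows the across-tree mean cDBH trajectory of its year. The
  predictions vary within a clone only through the year effects, so the
  ANOVA must run per tree-year (per-tree averaging would leave zero
  within-clone variance and a degenerate H² ≡ 1). Standardization
  removes size-driven and tree-level noise, which is why H²_pred tends
  to be the largest of the three.
* **H²_mod** — σ̂²G/(σ̂²G + σ̂²R) from the REML components of
  trait ~ year + cDBH with the *clonal group* as the random intercept.
  This model is fitted without the AR(1) and heteroscedasticity options:
  the variance-extraction model is specified with random genet, fixed
  year and size only, and serial correlation enters the analysis chain
  through the prediction and comparison models instead.

Each method reports CV = σ̂²G/x̄ — the genetic variance over the trait
mean, exactly as this dispersion measure is conventionally printed
alongside these estimates (a √-variant is available behind a flag for
sensitivity checks, default off).

A deliberate consequence of the confounded design: with clones nested in
spatial groups, σ̂²G from the clone-random model absorbs σ²S. The
`confounded` scenario (all structure spatial, true σ²G = 0) demonstrates
the resulting upward bias — mean H²_mod ≈ 0.29 for a true 0 — which is
the central caveat for in-situ heritability estimation in layering
populations.

## Clone identification

Genotypes are 11 unordered diploid allele pairs (fragment sizes);
null-allele states are an allele value, missing loci carry no call.
Trees with more than two null-allele loci are removed. Pairwise distance
is the number of loci where both calls are present and the unordered
pairs differ; loci missing on either side never count as deviations
(missing data must not split clones — genotyping errors split rather
than merge). Clones are the connected components of the graph with edges
at ≤ 2 mismatches, i.e. single-linkage transitive closure; the threshold
algorithm this mirrors does not pin down a linkage rule, and single
linkage is the choice consistent with merging through chains of pairwise
similarity. Components are numbered by their smallest member id;
single-member components are non-clonal trees. Recovery is scored per
tree: correct means clustered with true clone-mates only (a ramet that
splits off its genet is one error, not a broken genet); at 5% per-locus
genotyping error the default stand recovers ≈ 98–99% of trees.

## Anatomy derivations

Cell-level inputs are lumen area LA, mean wall thickness CWT and the
radial extent of each tracheid. Lumen diameter is the equivalent-circle
diameter d = 2·√(LA/π) — radial diameters are not part of the input
contract, so the circular approximation is used and documented. The
single-cell wall area is the band around that circle,
CWA = 4·CWT·(d + CWT); exact cell geometry is out of scope. Zone
classification is per cell by Mork's index 4·CWT/d ≥ 1 (the
wall-to-lumen formulation; a fully occluded cell is latewood by
convention). Zone traits: widths are summed radial extents; CWT is the
zone mean; DEN pools CWA and LA over the zone before taking the ratio
(the aggregate form of the density definition, rather than a mean of
per-cell ratios); DH = Σd⁵/Σd⁴ over the zone's cells. Rings with an
empty zone get width 0 and NaN zone traits, flagged. The PCA summary
standardizes traits and eigen-decomposes the correlation matrix;
fractions of variance explained sum to one by construction.

## Detrending

Per tree and width series, degree-1 and degree-1+2 polynomials in year
are fitted by least squares and compared by Gaussian AICc with k
counting intercept, slopes and the residual variance; ties and series
too short for the quadratic correction go to the linear model
(parsimony). The detrended series is residuals + series mean, preserving
mean growth exactly (residual variance is floored at 1e-12 of the mean
square so that exact fits of both degrees tie rather than being ranked
by rounding noise).

## Model comparison rules

Null, genetic and spatial models (all with year + cDBH fixed, tree
random intercept, AR(1); the grouped models add the grouping fixed
effect and per-group residual multipliers) are compared by AICc. "Best
by more than four units against every competitor" is strict: equality at
exactly 4 is not a win. If genetic and spatial are within 4 units of
each other and both beat the null by more than 4 the verdict is
"grouped"; everything else is "null". The |ΔAICc(spatial − genetic)|
magnitude classes are ≤ 4 none, (4, 10] considerable, > 10 essential —
boundary values resolve to the lower class. Grouping-term significance
letters come from the sequential ANOVA at α = 0.05 and are reported
independently of the AICc verdict. A failed fit produces a flagged row
rather than aborting the other traits.

## Synthetic data generator

The generator emulates the study design end to end: 47 trees in 11
spatially clustered groups (members inside a 1.4 m disc, so pairwise
distances respect the 3 m clustering rule), 35 trees in 9 clonal groups
(five clone-only groups, four mixed, two non-clonal-only), 12 non-clonal
trees, years 2007–2017. cDBH grows linearly with a tree-specific rate
(start ≈ 11 cm, ≈ 0.1 cm/yr — matching the average-growth
standardization arithmetic) and is non-decreasing. Genotypes give every
genet a founder drawn from eight equifrequent alleles per locus; each
tree's locus calls are then independently perturbed (one allele replaced)
with the error rate and null-flagged with the null rate.

Trait panels follow the mixed model above. The default panel simulates
widths, zone CWT and zone DH independently at realistic means (EWW 450,
LWW 150 μm; CWT 2.5/3.5 μm; DH 30/9 μm) with total CVs of 20% (widths)
and 4% (others), variance fractions σ²G 0.15 / σ²S 0.25 / σ²tree 0.15 /
σ²R 0.45, ρ = 0.3, and fixed year effects with SD equal to 0.8× the
random-component SD (ring traits are strongly year-structured; the
prediction-based H² estimator also needs that dispersion to be
non-degenerate).

Anatomical density is *derived*, not independently drawn: under the
wall-band cell geometry, DEN is nearly pinned by (CWT, DH), so an
independent DEN draw would usually be geometrically unrealizable. Each
ring's DEN comes from a latent unit-variance "density tendency" (same
variance structure) mapped into the feasible band of the within-zone
diameter-ramp spread γ, through the closed profile-implied density.
DEN therefore inherits clonal/spatial/tree structure both directly and
through CWT and DH.

Cell tables are tracheidograms: within each ring, lumen diameter falls
and wall thickness rises monotonically (linear ramps, multiplicative
jitter), so Mork's index crosses 1 exactly once. Zone widths and
zone-mean CWT are reproduced exactly by construction, DH exactly by
scale equivariance (diameters are rescaled after jittering), and DEN by
a root find over γ; targets within 0.02 (the documented round-trip
tolerance) of the achievable band are clamped to the band edge, larger
gaps raise an infeasibility error. Mork-marginal targets flatten the
wall gradient progressively (keeping the zone-mean CWT exact) before
giving up, and the γ search is capped so every generated cell stays on
its intended side of the index threshold.

What the generator does *not* emulate: trait–trait correlations beyond
the DEN coupling, spatially continuous environmental fields (microsite
effects are exchangeable group effects), SSR mutation or linkage, and
non-Gaussian trait distributions. Passing recovery tests therefore shows
the estimators are correct under the stated model, not that real stands
satisfy it — in particular the confounding results show what happens
precisely when one of its assumptions (independent spatial and genetic
effects) is broken.

## Simulation-study problem sizes

The replicated studies use: H² recovery/null/confounded — 34 clonal
groups × 3 ramets (102 trees), 11 years, 200/200/100 replicates;
model-selection consistency — the 47-tree layout, 100 replicates
(spatial-only) and 30 (no-structure); significance calibration — 18
trees in 6 clonal groups, 6 years, 1000 replicates; clone recovery —
100 replicates of the default stand. These sizes were chosen so each
study's Monte-Carlo error is small relative to the effect it measures.

## Known limitations

* The REML engine supports a single random intercept; crossed random
  effects and spatially continuous correlation are out of scope.
* AICc model comparison across fixed-effect structures uses restricted
  likelihoods (by design, see above); the parameter count k includes all
  variance parameters, and the simulated verdicts are robust to ±1 in k.
* The "grouped" verdict effectively requires the genetic and spatial
  partitions to be commensurate: with many singleton genets the genetic
  model pays a large parameter penalty, and on the default stand a
  shared group effect yields "spatial" rather than "grouped". The
  pattern fixture therefore demonstrates "grouped" on a stand whose
  partitions coincide.
* Heritability standard errors (e.g. parametric bootstrap) are not
  implemented; CV = σ²G/x̄ is reported as the dispersion measure.
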