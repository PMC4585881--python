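# Methods

This note documents the models, estimators, numerical choices and known
limitations of `stomascale`, in the package's own terms.

## The upscaling model

Community-level stomatal traits are ground-area totals obtained by weighting
leaf-level values with species-specific leaf area index:

    SD_C = Σᵢ SD_Lᵢ · LAIᵢ         [stomata mm⁻² ground]
    SL_C = Σᵢ SD_Lᵢ · SL_Lᵢ · LAIᵢ [μm mm⁻² ground]

LAI is dimensionless (m² leaf m⁻² ground), so SD_C inherits the units of
leaf-level density and SL_C those of density × length. SL_C is therefore
*total stomatal length per unit ground area*, and SL_C/SD_C is an
SD·LAI-weighted mean stomatal length that must lie inside the range of the
contributing species' SL_L — the algebraic identity the property tests sweep.
Three further identities follow directly and are enforced exactly:
homogeneity (scaling all LAIᵢ by c scales both totals by c), linearity under
merging species lists, and additivity under splitting a species' stems into
pseudo-species.

**Species LAI.** For woody species, per-stem foliar biomass comes from a
power-law allometric equation — either a·DBH^b or a·(DBH²·H)^b, DBH in cm
(basal stem diameter for shrubs), H in m, biomass in kg — summed over stems
and converted by LAIᵢ = biomass × SLA / plot area. An equation registry is
searched along a strict fallback chain: species match, then genus, then PFT
label, then the site's mixed-forest equation; resolution is independent of
registry order (level decides; within a level, a stable lexicographic
tie-break on the source string). Herb foliar biomass is the measured
aboveground biomass; multiplying it by SLA overestimates leaf area for
stemmy herbs, which is accepted and documented since herbs contribute
little LAI in closed forests. Per-stem summation is the default; a
mean-stem mode (equation applied once to the mean DBH/height, times stem
count) emulates field protocols that record only stand means — the two
agree exactly only when b = 1.

**Aggregation.** Plot community traits aggregate to sites as unweighted
means ± SE over plots (default); a pooling mode that merges all plots'
species lists (LAI averaged over plots) is provided for comparison. Trait
coverage of a plot's LAI below a configurable fraction (default: full
coverage) is a hard error naming the uncovered species and their LAI share.

## Statistical toolkit

**SMA regression.** Stomatal traits are log10-transformed before all
bivariate and group analyses. The SMA slope is sign(r)·s_y/s_x — the
minimizer of the summed areas of the triangles between points and the
line — with the line through (x̄, ȳ); tests verify this against a dense
1-D numerical search over candidate slopes. The 95% slope CI uses the
construction b·(√(B+1) ± √B), B = F₀.₉₅(1, n−2)·(1−r²)/(n−2); the p-value
is the two-sided correlation test.

For g groups, the common-slope machinery works on the correlation r_rf(b)
between residual scores (y − b·x) and axis scores (y + b·x): at a group's
own SMA slope this correlation vanishes. The heterogeneity statistic is
−Σ (nᵢ − 2.5)·log(1 − r²_rf,i(b̂)) at the pooled slope b̂, referred to
χ²(g−1); the weights use the Bartlett-type small-sample correction
(nᵢ − 2.5; an uncorrected nᵢ − 2 variant sits behind a flag). The empirical
size of this test is checked by simulation (type-I rate 0.05 ± 0.02 over
1000 two-group nulls). The pooled slope solves the estimating equation
dLR/db = 0 by bracketed Brent root-finding over the interval spanned by the
group slopes (widened geometrically if needed, kept on one side of the pole
at b = 0); mixed-sign group slopes are a hard error, and reproducibility is
to 1e−10. Elevations aᵢ = ȳᵢ − b̂·x̄ᵢ are compared by a Wald χ² test with
covariance diag(s²_res,i/nᵢ) + var(b̂)·x̄x̄ᵀ, var(b̂) taken from the
curvature of the LR objective at its minimum; pairwise letters use
unadjusted Wald z tests (Holm adjustment optional, off by default, since
the two-group comparisons this workflow needs are unaffected). The
elevation stage runs only when the heterogeneity test does not reject at
α = 0.05, mirroring the standard two-stage workflow.

**Mixed models.** The model is y = Xβ + Zu + e with one random intercept
per site. Estimation profiles λ = σ²_site/σ² in a single dimension: each
site's compound-symmetric block inverts in closed form (Woodbury), giving
GLS solves and the profiled restricted or full log-likelihood in O(n) per
λ. The optimum is located by bounded scalar minimization over log₁₀λ in
[−10, 8] (xatol 1e−13), polished by Brent root-finding on the numerical
profile score, with an explicit λ = 0 boundary check; on balanced one-way
layouts the REML components equal the classical ANOVA estimators to 1e−8,
and the restricted/full log-likelihoods (constants included) match
statsmodels' MixedLM, which serves as an independent oracle in the tests —
never as the implementation. AIC is always computed from the ML refit
(k = p + 2), so candidates with different fixed-effect structures are
comparable; candidates must share the observation set, and ties break to
fewer parameters, then input order. Variance components are reported from
REML.

Fixed-effect F tests are Wald tests with a containment-style denominator
df: terms constant within sites are tested against (number of sites −
site-level parameters), observation-level terms against n − p. This is an
approximation, documented as such, and not claimed to match any particular
software's df convention. Categorical predictors use treatment contrasts
with the first alphabetical level as reference; term-wise F tests make the
choice immaterial.

The per-term "variance explained" ledger is a drop-term, marginal-R²-style
reconstruction: a fixed term's raw contribution is the decrease in
var(Xβ̂) when the term is removed and the model refitted (floored at 0);
the site and residual rows carry σ²_site and σ²; all entries are rescaled
to sum to 100. This is one reasonable definition among several — it is not
claimed to reproduce any published table numerically.

**Nested variance components.** The within/among-site partition uses the
classical nested random-effects ANOVA (species within sites) by method of
moments with the unbalanced-design n₀ coefficients; negative component
estimates are truncated at zero. When every species-at-site has exactly one
record — the usual layout for these trait tables — the species and residual
strata are confounded and the estimator collapses to the one-way site /
within-site split, which the output flags. Balanced designs reproduce the
closed-form moment estimators exactly.

**Collinearity screen.** Environmental covariates enter models only after a
greedy screen: candidates are visited in a deterministic priority order
(MAT, MAP, soil N, soil P, SWC, insolation by default) and kept only if
every pairwise Pearson correlation with already-kept covariates has
p > α. With nine sites this is a permissive filter; it reproduces the
practice of excluding significantly inter-correlated covariates rather
than a formal model-selection step.

**Gradients and NPP.** Species-level latitudinal trends are OLS lines;
community-level trends fit both a line and a quadratic and report the
AIC-preferred form (an exponential-decay option exists behind a flag) —
the operational reading of a "nonlinear" decline, since site-level n is
small. NPP in dry matter converts to carbon by the factor 0.5. The NPP
linkage fits separate OLS lines NPP~SD_C and NPP~SL_C, then a two-predictor
general linear model with sequential (type-I) sums of squares; SD_C enters
first by default because the two community traits are nearly collinear
(their shared LAI factor typically gives r² > 0.95, which the result
flags), and both entry orders are always reported. Percent attributions
plus the residual sum to 100 exactly.

## The synthetic study generator

The generator emulates a nine-site forest transect spanning 18.7–51.8 °N.
What it reproduces, and the defaults that encode it:

- **Climate.** Latitudes evenly spaced; MAT exactly linear through
  23.15 °C (south) and −3.67 °C (north); MAP declining northwards with
  noise; soil N rising northwards; soil P, SWC and insolation weakly
  structured.
- **Composition.** Five PFTs (herb, shrub, deciduous broadleaf, evergreen
  broadleaf, conifer tree) drawn from a softmax over MAT whose logits make
  evergreen broadleaf trees dominate the warm end, conifers the cold end,
  and deciduous broadleaf trees the middle.
- **Traits.** log₁₀ SD_L = PFT mean + weak latitude trend (−0.003 per
  degree) + site effect (SD 0.05) + within-site scatter (SD 0.22);
  log₁₀ SL_L follows a negative per-PFT line in log₁₀ SD_L (slopes −0.38
  to −0.62, herbs steepest; scatter 0.10). PFT means were set so the
  realized moments sit in the regime of published transect data
  (species mean SD_L ≈ 220–260 stomata mm⁻² with CV ≈ 0.6–0.7, SL_L ≈
  30 μm with CV ≈ 0.4) and so the among-site share of log-trait variance
  averages ≈ 12–14% across seeds — at nine sites the single-study moment
  estimate of that share is itself very noisy (roughly ±50% relative), so
  recovery is asserted as a mean over seeds.
- **Canopy.** Target plot LAI runs linearly from 7.5 (south) to 2.6
  (north) with 10^N(0, 0.05) plot noise. Provisional censuses (lognormal
  DBH ≥ 2 cm, allometric heights, Poisson stem counts, 85% plot presence)
  are pushed through the same equation registry the analysis uses, and stem
  counts / herb biomass are then thinned or replicated so the realized plot
  LAI meets its target — abundance calibration, not a shortcut around the
  allometry. The registry gives 80% of woody species a species-level
  equation; the rest resolve at genus, PFT (tree PFTs only) or site level,
  exercising the full fallback chain.
- **Productivity.** Site NPP (dry matter) = 1000 + 0.9·SD_C + N(0, σ), σ
  chosen per study so the coupling targets R² = 0.5 against the realized
  SD_C spread; draws are floored at 1 g m⁻² yr⁻¹ (production cannot be
  negative; at the default intercept the floor binds in ≪5% of draws).
  With nine sites the realized R² of a single draw ranges roughly from 0
  to 0.9; the calibration claim is about the replicate mean, which the
  acceptance suite checks over 200 replicates (20 studies × 10 draws).

All randomness descends from one seed through named `SeedSequence`
substreams (environment, species, census, NPP), so regenerating one stage
never perturbs another and identical configurations are byte-identical on
disk.

**What the generator does not emulate** — and hence what passing tests do
not show about field data: species are site-unique (no shared species
across sites, no phylogenetic structure), trait scatter is log-normal with
a single within-site variance, plot presence/abundance is unstructured
(no dispersal, size structure or mortality), measurement error on SD/SL is
not separated from biological variation, and NPP noise is homoscedastic.
Results on synthetic studies validate the *pipeline* — estimators,
identities, calibrations — not the biology.

## Problem sizes and determinism

Default study: 9 sites × 3 plots (30 × 40 m, 1200 m²) × 100 species per
site ≈ 900 species-at-site records and ~10⁴ stems; one study simulates in
about a second, and the acceptance suite's replicate checks use 200
replicates per simulated quantity (1000 for the test-size check), sizes at
which Monte-Carlo error is well inside the asserted bands. All tests and
the acceptance script are seeded and deterministic; analysis re-runs on the
same inputs are byte-identical.

## Known limitations

- The elevation test treats the estimated common slope's variance by a
  curvature approximation and ignores cross-group correlation beyond the
  shared-slope term; for very small groups its p-values are approximate.
- The F-test denominator df convention is containment-style and will not
  match every mixed-model implementation; term significance near the
  α boundary should not be over-interpreted.
- The variance-explained ledger is order-free but drop-term based: with
  correlated predictors the rescaled shares are a decomposition, not a
  causal attribution.
- `aic_select` refits every candidate from scratch; for large candidate
  pools this is O(candidates × fits) with no warm starting.
- The collinearity screen is greedy and priority-ordered; it does not
  search for the globally largest compatible covariate subset.
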