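# Methods

This note documents the models, conventions and defaults behind each stage
of the pipeline, the design choices made where several reasonable options
existed, and what the synthetic-data tests do and do not establish.

## Experimental design model

All analyses assume a split-plot layout: spatial blocks each containing one
control and one suppression zone, focal plots nested in zones, plot
quarters, and repeated sampling events. The default layout is 3 blocks × 2
zones × 2 plots × 4 quarters × 4 events (192 pitfall samples); ecosystem
functions are assessed in two quarters per plot (48 observations per
treatment arm per function), with 80 baits per plot per ground function and
32 for plant protection, carried everywhere as (successes, offered) pairs
rather than pre-divided rates.

Treatment is assigned at the zone level, so inference must respect
clustering above the sample. Two error structures are used:

* **Gaussian responses** (ENS, uniqueness, FRic, FDis, path components):
  linear mixed models with a block random intercept and plot-in-block
  variance components (statsmodels MixedLM, REML; L-BFGS then Powell, since
  the block variance often sits on the boundary with three blocks). If the
  mixed fit fails, the model falls back — flagged in the result — to OLS
  with block fixed effects and plot-cluster-robust standard errors.
* **Count responses** (abundance, richness, functions-above-threshold
  treatment tests): because treatment is constant within plots, counts are
  summed to plot totals and fitted with a quasi-Poisson GLM
  (`treatment + block`, Pearson-scaled covariance, t reference). In
  calibration simulations this keeps the type-I error near nominal
  (measured 6% at α = 0.05 over 150 null experiments), where per-sample
  Wald tests with 12 clusters were anti-conservative (11–15%). The
  threshold-sweep *slope* models stay at sample level — diversity varies
  within plots — as Poisson GLMs with block fixed effects and
  plot-cluster-robust intervals.

## Trait space

**Gower dissimilarity.** Continuous and ordinal traits contribute
|xᵢ − xⱼ|/range; binary and categorical traits contribute a 0/1 mismatch;
contributions are averaged over traits non-missing in both species. Numeric
traits with zero range are excluded with a warning (normalization
undefined); constant categorical traits remain with zero contribution. A
table with no varying trait is an error.

**Weighted PCoA.** Classical scaling with species weighted by site-wide
incidence: weights (scaled to mean 1 so uniform weights reproduce ordinary
PCoA eigenvalues) enter the double-centring and the metric, so the
trait-space origin is the incidence-weighted centroid. When any eigenvalue
is below −10⁻⁸ the Cailliez additive constant is applied and the embedding
recomputed; variance explained is reported over the corrected positive
spectrum. Gower matrices on mixed traits are typically non-Euclidean, so
the correction is routinely active.

**Groupings and dominants.** Trait groups come from
partitioning-around-medoids on the Gower matrix (k configurable, default 5;
seeded multi-start, best of 10 initialisations). The algorithm behind the
original grouping analysis is not specified anywhere we could follow, so
both k and the clustering method are exposed as configuration rather than
asserted. Each group's dominant is its highest-incidence species; ties
break lexicographically and are reported.

**FRic / FDis.** FRic is the convex-hull volume of the species present, in
the first two PCoA axes by default (configurable); samples with fewer than
axes+1 species, or degenerate (collinear) coordinate sets, get FRic = 0.
FDis is Σ aⱼ‖xⱼ − c‖ / Σ aⱼ with c the abundance-weighted centroid; it is 0
for singletons and undefined (NaN) for empty samples.

## Diversity metrics

ENS uses Hill numbers: ^qD = (Σ pᵢ^q)^{1/(1−q)}, with the Shannon limit
exp(−Σ pᵢ ln pᵢ) at q = 1 (default). Richness-type metrics are computed
after removing the suppressed target species when the analysis concerns the
response of the remaining community (the default in the pipeline).

**Compositional uniqueness.** For each sample pair, null communities are
drawn preserving each sample's richness, with species sampled without
replacement proportionally to their occurrence frequency (Gumbel top-k
sampling; 999 draws by default). The pairwise score is
RC = 2·(P(null shared > observed) + ½·P(=)) − 1, so +1 means the pair
shares fewer species than chance expects; a sample's uniqueness is its mean
RC over all partners. The exact variant used by the original field analysis
lives in supplementary material we do not reproduce; this convention
(standard Raup–Crick practice, ties counted half, configurable) is
documented as this package's own, and a closed-form hypergeometric version
is provided for equal-frequency pools as a testing oracle.

## Multifunctionality

Rates are standardized as F_std = min(rate / F_max, 1) with F_max the mean
of the top 5% of observed rates for that function (fewer than 20
observations: the single maximum, flagged). Effective multifunctionality at
order q is M_q = A · (^qN / N_f): the arithmetic mean A of standardized
rates discounted by the Hill-number evenness of their proportions. The
source framework's exact formula is not printed in the originating article,
so this evenness-discounted form is isolated in one function
(`effective_mf`) and trivially swappable.

The multiple-thresholds sweep counts, per sample, the functions with
F_std ≥ t for every t from 5% to 95% in 1% steps and regresses that count
on diversity (S or ENS) per treatment arm. Slopes are reported on the
response scale as average marginal effects (β·mean μ̂ for the Poisson fit,
delta-method 95% intervals) so that 1/R_mde reads directly as
species-per-function; the link-scale coefficient is retained in the fitted
objects. T_min/T_max are the extreme thresholds whose interval excludes
zero, R_mde the largest significant slope and T_mde its threshold.
Degenerate thresholds (constant count) get slope 0 with a flag and are
never significant. The treatment test at the mean of the two arms' T_mde
uses the plot-aggregated quasi-Poisson model above. An 84% interval option
is available for descriptive plots.

Between-function covariance is the pairwise Pearson correlation of
standardized rates across observations within an arm (plot means
optionally), with seeded permutation p-values (999 permutations).

## SR–FR shape

Penalized cubic B-splines test linear versus saturating richness–functional
richness relationships. The basis follows the P-spline convention — k′ = 9
basis functions on equally spaced knots extended past the data range — with
a second-order difference penalty, so the penalty's null space is exactly
the linear functions and infinite smoothing reproduces the least-squares
line. The smoothing parameter minimizes the Gaussian REML score
(coordinate-descent over a 27-point log-spaced grid; near-ties resolve to
heavier smoothing, which also handles the noiseless case). The effective
degrees of freedom of the smooth is the trace of its block of the influence
matrix; edf ≈ 1 means the fit is effectively a line, edf > 2 real
curvature. The F statistic for the smooth uses the standard
penalized-regression approximation ((RSS₀ − RSS)/edf) / (RSS/(n − edf_total));
exact equality with other packages' F is not promised — sign and shape
conclusions are the contract. On identical simulated data the edf
distribution matches mgcv's `gam(..., bs="ps", m=c(2,2), method="REML")`
closely, including the minority of pure-noise draws where REML reports
spurious curvature.

Five candidates of increasing complexity — intercept-only, treatment-only,
single smooth, treatment intercepts + shared smooth, treatment intercepts +
per-treatment smooths — are compared by AIC = n·log(RSS/n) + 2(edf + 1),
with ties resolved to the simpler model. Block fixed intercepts stand in
for the nested random effects (three balanced blocks, treatment within
block). The response is modelled as Gaussian FRic, untransformed.

## Path analysis

Treatment effects on each function (and on M_q) are decomposed piecewise:
`mediator ~ treatment` and `response ~ treatment + mediator`
(+ treatment × mediator where specified, e.g. granivory), each fitted with
the split-plot error structure. Standardized coefficients are
β = b·sd(x)/sd(y), with the 0/1 treatment indicator standardized by its own
sd — a documented convention, since standardizing binary predictors has no
canonical answer. The indirect effect is the product of the two
mediator-path βs with a Sobel standard error; the direct effect is the
treatment β at the mediator held at its mean. No global
directed-separation test is computed (extension point).

## Species–function association

Within an arm, each species × function cell gets the least-squares slope of
function rate on species abundance across samples; the null distribution
comes from permuting the rate vector across samples (abundances fixed,
999 randomizations, seeded), under the assumption that abundance drives
functioning rather than the reverse. SES = (observed − null mean)/null sd;
|SES| > 1.96 is flagged. ΔSES = SES_suppression − SES_control, ranked
ascending with species-id tie-breaks; Spearman's ρ of control SES against
ΔSES tests whether the most functionally important species shift most under
suppression. Rates are permuted as whole plot-level vectors within arm
(whether the original analysis permuted within sampling events is unstated;
this default is configurable).

## Synthetic generator

The generator emulates the field design above with ~34 species in 5 planted
trait groups. Defaults, chosen once so that recovery analyses are
well-powered at this design's sample sizes (not fitted to any field data):

* **Traits:** 6 continuous + 1 ordinal + 2 binary + 1 categorical; group
  means separated by 2 within-group sd (3 in "well-separated" test
  scenarios); one high-incidence dominant per group (incidence 0.65–0.9 vs
  ≤ 0.5).
* **Abundance:** negative binomial, dispersion size 4 (Poisson as the
  infinite-size limit); dominant mean counts 8–18 per sample, others
  lognormal (median 0.6, σ = 1.1), giving realistic per-trap richness
  (~15 of 34). Targets (dominants of groups 1–3) are multiplied by
  0.06/0.04/0.01 in suppression zones — the 94/96/99% reductions — with a
  small floor for long-range foragers; non-targets are released by ×1.4.
* **Functions:** success probability inverse-logit(α_f + β_S(S − S̄) + β_T·T
  + performer effect + correlated noise), binomial over the protocol's bait
  numbers. Default signs echo the field findings (richness raises three
  functions, lowers granivory; direct suppression effect positive on
  granivory, negative on plant protection); one planted performer species
  per function (effect 1.0 per centered log-abundance); noise sd 0.25 with
  a correlation structure giving negative granivory–protection covariance.
  An identity-link variant makes the planted β the exact estimand of the
  linear path models for coverage experiments.
* **Seeding:** one scenario seed; each table draws from its own
  deterministic sub-stream, so regenerating one table never shifts another.

Named study conditions (`mufunlab.scenarios`) fix the configurations used
in validation: the default paper-like scenario, the identity-link mediation
chain (true mediator slope 0.025/species, true direct effect 0), a uniform
positive-treatment scenario for threshold-test power, a fully null scenario
for size/false-positive calibration, and a strong negative-covariance
scenario.

## Monte-Carlo problem sizes

Validation experiments run at sizes chosen to give adequate Monte-Carlo
precision while keeping the default suite fast: 120 simulations for path
CI coverage in the test suite (100 in the acceptance script), 40 (30) for
threshold-range recovery, 8 null + 12 (10) default experiments for SES
calibration and power, and 100 (50) for SR–FR shape discrimination.
Reference calibration values measured at these sizes: direct-effect
coverage ~96%, mediator-path coverage ~94%, SES false-positive rate ~4.7%,
performer power ≥ 95%, threshold-range recovery ~90%, linear-truth median
edf 1.00, saturating-truth median edf ~3.4.

## What the synthetic tests do not show

The generator draws independent samples within zones given treatment — no
temporal autocorrelation across events, no spatial structure within plots,
no colony dynamics or species interactions beyond the planted
release/suppression multipliers, and no observation process beyond
NB/binomial sampling. Passing recovery tests therefore demonstrates that
the estimators are correct and calibrated under the declared design, not
that real pitfall data meet those assumptions. Field data additionally
violate the generator's clean link between richness and function rates;
the pipeline's mixed-effect structures address the design-induced
correlation only.

Other known limitations: Poisson-family path components standardize
coefficients on the observation scale (documented, not the only
convention); the Raup–Crick variant and the effective-multifunctionality
formula follow this package's documented conventions where the original
analysis's exact choices are unpublished; FRic in two axes discards
higher-axis trait variation; and the PAM grouping is one of several
defensible clusterings of a Gower matrix.
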