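# mufunlab

Biodiversity–ecosystem multifunctionality analysis for dominant-species
suppression experiments.

When a community's most abundant species decline, do the remaining species
buffer ecosystem functioning (functional redundancy), or does functioning
hinge on species doing different jobs (complementarity)? `mufunlab`
implements the statistical pipeline used to answer this in split-plot field
experiments where dominant species — e.g. the top ant species of several
functional trait groupings — are experimentally suppressed and several
ecosystem functions (scavenging, myrmecochory, granivory, plant protection)
are measured as binomial bait trials. It is written for community
ecologists, but the diversity machinery (Hill numbers, Gower/PCoA trait
spaces, null models) is the same used in microbiome and metagenomics work.

## What it computes

**Trait space and dominants** — Gower dissimilarity over mixed-type traits,
principal coordinates analysis with species weighted by site-wide incidence
(Cailliez correction for non-Euclidean distances), partitioning-around-medoids
trait groupings, and per-group dominant selection by incidence.
Functional richness FRic (convex-hull volume in the first ordination axes)
and functional dispersion FDis (abundance-weighted mean distance to the
weighted centroid) per community.

**Diversity** — richness *S*, abundance *N*, effective number of species
as Hill numbers, ^q*D* = (Σᵢ pᵢ^q)^{1/(1−q)} with ENS = exp(−Σ pᵢ ln pᵢ) at
*q* = 1, and a Raup–Crick-style compositional uniqueness score from a
richness-preserving, occurrence-weighted null model.

**Multifunctionality** — rates standardized against the mean of the top 5%
of observed rates per function; effective multifunctionality
*M_q* = *A* · (^q*N* / *N_f*), the arithmetic mean *A* of standardized rates
discounted by the effective number of functions; and a multiple-thresholds
sweep: at every threshold *t* ∈ {5%, …, 95%} the number of functions
performed above *t* is regressed on diversity (Poisson, split-plot errors),
giving a diversity-effect curve with *T*min/*T*max (the significant range)
and *R*mde (the strongest significant slope, whose reciprocal is the number
of species needed to add one function).

**Attribution** — piecewise confirmatory path models decomposing the
treatment effect on each function into a direct path and a
richness/ENS-mediated path (nested split-plot random effects, standardized
coefficients β = b·sd(x)/sd(y)); and a permutation null model giving each
species a standardized effect size (SES) of association with each function,
its shift under suppression (ΔSES), and Spearman rank tests of whether
functionally important species respond most to suppression.

**Synthetic experiments** — a generator reproducing the full design
(3 blocks × paired control/suppression zones × 2 plots × 4 quarters ×
4 events, ~34 species, negative-binomial pitfall counts, binomial bait
trials) with planted trait groups, suppression effects (94/96/99%
reductions), diversity–function slopes and between-function covariance, so
every stage has a parameter-recovery test against known truth.

## Worked example

```python
import mufunlab as ml
from mufunlab import community_metrics as cm, multifunctionality as mf

cfg = ml.ScenarioConfig(seed=42)          # a full synthetic experiment
ds = ml.gen_dataset(cfg)

effects = cm.community_effects(ds.community, ds.design, n_null=199, seed=0)
print(effects[["estimate", "Z", "p_value"]].round(3))

std, f_max, _ = mf.standardize(ds.functions)
prof = cm.diversity_profile(ds.community)
curves = mf.threshold_sweep(std, prof, ds.design)
for arm, c in curves.items():
    print(f"{arm}: T_min={c.t_min:.0f}%  T_max={c.t_max:.0f}%  "
          f"R_mde={c.r_mde:.3f}  species/function={c.species_per_function:.1f}")
res = mf.mde_test(std, ds.design, curves)
print(f"treatment test at mean T_mde: Z = {res.z:.2f}, p = {res.p_value:.3f}")
```

prints

```
            estimate       Z  p_value
response
abundance      0.340   8.555    0.000
richness       0.161  10.341    0.000
ENS            0.236   0.593    0.553
uniqueness     0.075   2.382    0.017
control: T_min=14%  T_max=95%  R_mde=0.190  species/function=5.3
suppression: T_min=41%  T_max=93%  R_mde=0.219  species/function=4.6
treatment test at mean T_mde: Z = 1.85, p = 0.102
```

Read: suppressing the three dominants *increased* non-target abundance and
richness (positive Z, the generator's planted compensatory release); the
diversity effect on multifunctionality is significant over a broad threshold
range in both arms, strongest in the suppression arm (R_mde = 0.219), where
each additional ~4.6 species is predicted to push one more function above
the threshold of strongest effect.

The same stages are available from the shell — `mufunlab simulate`,
`validate`, `traitspace`, `diversity`, `srfr`, `multifun`, `paths`, `ses` —
each taking a YAML config of paths, parameters and seeds so field tables
(e.g. a deposited dataset) can be mapped in without code changes.

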