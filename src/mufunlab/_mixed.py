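"""Shared mixed-model machinery for the split-plot design.

Gaussian responses are fitted with nested random intercepts (block groups,
plot-in-block variance components) via statsmodels MixedLM; on
non-convergence the fit falls back, flagged, to OLS with cluster-robust
(plot-level) standard errors.  Count responses use Poisson GLM with block
fixed effects and cluster-robust plot-level errors — the split-plot
equivalent of a Poisson GLMM for this balanced 3-block design — with a
Pearson dispersion check flagged when chi2/df exceeds 1.5.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

OVERDISPERSION_LIMIT = 1.5


@dataclass
class EffectResult:
    """Wald test of one model term (default: the treatment contrast)."""

    response: str
    term: str
    estimate: float
    se: float
    z: float
    p_value: float
    family: str                      # "gaussian" | "poisson"
    random_effects: str              # descriptor of the RE / robust structure
    method: str                      # "mixedlm" | "ols_cluster" | "glm_cluster"
    flags: list[str] = field(default_factory=list)


def fit_mixedlm(df: pd.DataFrame, formula: str):
    """Nested-random-intercept MixedLM fit, retrying optimizers.

    Block is the grouping factor with a plot-in-block variance component;
    with few blocks the block variance often sits on the boundary, where
    gradient optimizers stall, so Powell is tried next.  Raises on failure
    so callers can apply the documented robust fallback.
    """
    last_exc: Exception | None = None
    for method in ("lbfgs", "powell"):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = smf.mixedlm(formula, df, groups=df["block"],
                                    re_formula="1",
                                    vc_formula={"plot": "0 + C(plot)"})
                fit = model.fit(reml=True, method=method, maxiter=300)
                ok = bool(fit.converged and np.isfinite(fit.bse_fe).all()
                          and (fit.bse_fe > 0).all())
            if ok:
                return fit
            last_exc = RuntimeError(f"MixedLM ({method}) did not converge")
        except Exception as exc:     # singular fits, LinAlgError, ...
            last_exc = exc
    raise last_exc


def _term_name(params: pd.Series, term: str) -> str:
    if term in params.index:
        return term
    hits = [p for p in params.index if p.startswith(term)]
    if len(hits) != 1:
        raise KeyError(f"term {term!r} not identifiable among {list(params.index)}")
    return hits[0]


def fit_gaussian_mixed(data: pd.DataFrame, response: str, fixed: str,
                       term: str = "treatment") -> EffectResult:
    """``response ~ fixed`` with nested random intercepts (block, plot)."""
    df = data.dropna(subset=[response]).copy()
    flags: list[str] = []
    if df[response].nunique() <= 1:
        return EffectResult(response, term, 0.0, np.nan, 0.0, 1.0, "gaussian",
                            "block + plot-in-block", "degenerate",
                            ["constant response"])
    formula = f"{response} ~ {fixed}"
    try:
        fit = fit_mixedlm(df, formula)
        name = _term_name(fit.fe_params, term)
        est = float(fit.fe_params[name])
        se = float(fit.bse_fe[name])
        z = est / se
        return EffectResult(response, term, est, se, z,
                            float(2 * stats.norm.sf(abs(z))), "gaussian",
                            "block + plot-in-block random intercepts",
                            "mixedlm", flags)
    except Exception as exc:  # documented fallback
        flags.append(f"mixed fit failed ({exc}); OLS + cluster-robust SEs")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = smf.ols(f"{response} ~ {fixed} + C(block)", df).fit(
                cov_type="cluster", cov_kwds={"groups": df["plot"]})
        name = _term_name(fit.params, term)
        est, se = float(fit.params[name]), float(fit.bse[name])
        z = est / se if se > 0 else 0.0
        return EffectResult(response, term, est, se, z,
                            float(2 * stats.norm.sf(abs(z))), "gaussian",
                            "block fixed effects + plot clusters",
                            "ols_cluster", flags)


def fit_poisson_cluster(data: pd.DataFrame, response: str, fixed: str,
                        term: str = "treatment") -> EffectResult:
    """Split-plot Poisson treatment test on plot-aggregated counts.

    Treatment is assigned at the zone level and constant within plots, so
    counts are summed to plot totals and fitted with a quasi-Poisson GLM
    (``treatment + block`` fixed effects, Pearson-scaled covariance,
    t reference) — the count analogue of the classical split-plot ANOVA,
    with well-calibrated small-sample error rates where per-sample
    cluster-robust Wald tests are anti-conservative.
    """
    df = data.dropna(subset=[response]).copy()
    flags: list[str] = []
    if df[response].nunique() <= 1:
        return EffectResult(response, term, 0.0, np.nan, 0.0, 1.0, "poisson",
                            "plot-aggregated, block fixed effects",
                            "degenerate", ["constant response"])
    agg = df.groupby(["block", "plot", "treatment"], observed=True)[
        response].sum().reset_index()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = smf.glm(f"{response} ~ {fixed} + C(block)", agg,
                      family=sm.families.Poisson()).fit(
            scale="X2", use_t=True)
    dispersion = float(fit.pearson_chi2 / fit.df_resid)
    if dispersion > OVERDISPERSION_LIMIT:
        flags.append(f"overdispersion (pearson chi2/df = {dispersion:.2f}); "
                     "quasi-Poisson scale absorbs it")
    name = _term_name(fit.params, term)
    est, se = float(fit.params[name]), float(fit.bse[name])
    z = est / se if se > 0 else 0.0
    return EffectResult(response, term, est, se, z,
                        float(fit.pvalues[name]), "poisson",
                        "plot-aggregated, block fixed effects, "
                        "quasi-Poisson t", "glm_quasipoisson_plot", flags)
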