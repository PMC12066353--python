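"""Piecewise confirmatory path analysis of suppression effects.

Decomposes the treatment effect on a function rate (or on effective
multifunctionality) into a direct path and a diversity-mediated path using
two component mixed models fitted separately, in the piecewise tradition:

* ``mediator ~ treatment``  (non-target richness S, or ENS)
* ``response ~ treatment + mediator (+ treatment:mediator)``

each with the split-plot error structure (nested random intercepts with a
flagged robust fallback — see :mod:`mufunlab._mixed`).  Standardized
coefficients are ``beta = b * sd(x) / sd(y)`` with the 0/1 treatment
indicator standardized by its own sd; the indirect effect is the product
of the two mediator-path betas with a Sobel standard error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats

from ._mixed import fit_mixedlm


class PathError(ValueError):
    pass


@dataclass
class ComponentFit:
    """One fitted component model (all fixed-effect terms)."""

    response: str
    params: pd.Series
    se: pd.Series
    p: pd.Series
    method: str                  # "mixedlm" | "ols_cluster"
    flags: list[str] = field(default_factory=list)


@dataclass
class PathModel:
    """Direct and mediated paths of one treatment -> response chain."""

    mediator: str
    response: str
    edges: pd.DataFrame          # from, to, b, se, p, beta
    direct: float                # standardized treatment beta (m2)
    indirect: float              # product of standardized mediator-path betas
    indirect_se: float           # Sobel SE on the standardized scale
    interaction: float | None    # standardized treatment x mediator beta
    components: dict[str, ComponentFit]

    @property
    def total(self) -> float:
        return self.direct + self.indirect


def _fit_component(df: pd.DataFrame, response: str, fixed: str) -> ComponentFit:
    """Gaussian mixed fit returning every fixed-effect coefficient."""
    flags: list[str] = []
    formula = f"{response} ~ {fixed}"
    try:
        fit = fit_mixedlm(df, formula)
        params, se = fit.fe_params, fit.bse_fe
        method = "mixedlm"
    except Exception as exc:
        flags.append(f"mixed fit failed ({exc}); OLS + cluster-robust SEs")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = smf.ols(f"{response} ~ {fixed} + C(block)", df).fit(
                cov_type="cluster", cov_kwds={"groups": df["plot"]})
        keep = [p for p in fit.params.index if not p.startswith("C(block)")]
        params, se = fit.params[keep], fit.bse[keep]
        method = "ols_cluster"
    z = params / se
    p = pd.Series(2 * stats.norm.sf(np.abs(z)), index=params.index)
    return ComponentFit(response, params, se, p, method, flags)


def standardize_coefficients(fit: ComponentFit,
                             data: pd.DataFrame) -> pd.Series:
    """``beta = b * sd(x) / sd(y)`` per predictor of a fitted component.

    The binary treatment indicator is standardized by the sd of its 0/1
    coding; interaction terms use the sd of the realized product column.
    Zero-variance predictors yield NaN.
    """
    sdy = float(data[fit.response].std(ddof=1))
    out = {}
    for term, b in fit.params.items():
        if term == "Intercept":
            continue
        x = _term_values(term, data)
        sdx = float(np.std(x, ddof=1))
        out[term] = b * sdx / sdy if sdx > 0 and sdy > 0 else np.nan
    return pd.Series(out, name="beta")


def _term_values(term: str, data: pd.DataFrame) -> np.ndarray:
    """Realized design-column values for a formula term."""
    if ":" in term:
        parts = [p.strip() for p in term.split(":")]
        vals = np.ones(len(data))
        for p in parts:
            vals = vals * _term_values(p, data)
        return vals
    name = term.split("[")[0].replace("C(", "").rstrip(")")
    col = data[name]
    if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
        level = term.split("T.")[-1].rstrip("]")
        return (col.astype(str) == level).to_numpy(dtype=float)
    return col.to_numpy(dtype=float)


def fit_paths(data: pd.DataFrame, mediator: str, response: str,
              with_interaction: bool = False) -> PathModel:
    """Fit the two-component path model on a joined per-sample table.

    ``data`` must carry ``block``, ``plot``, ``treatment`` plus the
    mediator and response columns; the mediator is expected to already
    exclude the suppressed target species.
    """
    for col in ("block", "plot", "treatment", mediator, response):
        if col not in data.columns:
            raise PathError(f"missing column {col!r}")
    df = data.copy()
    df["_treat"] = (df["treatment"].astype(str) == "suppression").astype(float)

    m1 = _fit_component(df, mediator, "_treat")
    fixed2 = f"_treat + {mediator}"
    if with_interaction:
        fixed2 += f" + _treat:{mediator}"
    m2 = _fit_component(df, response, fixed2)

    b1 = standardize_coefficients(m1, df.rename(columns={mediator: mediator}))
    b2 = standardize_coefficients(m2, df)

    a_beta = float(b1["_treat"])
    b_beta = float(b2[mediator])
    # Sobel SE on the standardized scale
    sd_t = float(df["_treat"].std(ddof=1))
    sd_m = float(df[mediator].std(ddof=1))
    sd_y = float(df[response].std(ddof=1))
    sa = float(m1.se["_treat"]) * sd_t / sd_m if sd_m > 0 else np.nan
    sb = float(m2.se[mediator]) * sd_m / sd_y if sd_y > 0 else np.nan
    sobel = float(np.sqrt(b_beta ** 2 * sa ** 2 + a_beta ** 2 * sb ** 2))

    edges = [
        {"from": "treatment", "to": mediator, "b": float(m1.params["_treat"]),
         "se": float(m1.se["_treat"]), "p": float(m1.p["_treat"]),
         "beta": a_beta},
        {"from": "treatment", "to": response, "b": float(m2.params["_treat"]),
         "se": float(m2.se["_treat"]), "p": float(m2.p["_treat"]),
         "beta": float(b2["_treat"])},
        {"from": mediator, "to": response, "b": float(m2.params[mediator]),
         "se": float(m2.se[mediator]), "p": float(m2.p[mediator]),
         "beta": b_beta},
    ]
    interaction = None
    iterm = f"_treat:{mediator}"
    if with_interaction and iterm in m2.params.index:
        interaction = float(b2[iterm])
        edges.append({"from": "treatment x " + mediator, "to": response,
                      "b": float(m2.params[iterm]),
                      "se": float(m2.se[iterm]), "p": float(m2.p[iterm]),
                      "beta": interaction})

    return PathModel(
        mediator=mediator, response=response, edges=pd.DataFrame(edges),
        direct=float(b2["_treat"]), indirect=a_beta * b_beta,
        indirect_se=sobel, interaction=interaction,
        components={"mediator": m1, "response": m2})


def join_path_data(design: pd.DataFrame, profiles: pd.DataFrame,
                   responses: pd.DataFrame) -> pd.DataFrame:
    """Join design, diversity profiles and per-sample responses on sample id."""
    out = design.set_index("sample_id").join(profiles, how="inner").join(
        responses, how="inner").reset_index()
    return out
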