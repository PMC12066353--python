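"""Effective multifunctionality and the multiple-thresholds analysis.

Function rates are standardized against a top-5% maximum (the mean of the
top 5% of observed rates per function), combined into an effective
multifunctionality index (arithmetic mean discounted by the Hill-number
evenness of the standardized rates, q = 1 by default), and swept across
performance thresholds from 5% to 95%: at each threshold a Poisson
regression of the number of functions performed above threshold on
diversity yields a response-scale slope ("diversity effect") with a 95%
Wald interval.  ``T_min`` / ``T_max`` bound the threshold range with a
significant diversity effect and ``R_mde`` is the strongest significant
slope; its reciprocal is the number of species predicted to add one
function at that threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from ._mixed import EffectResult, fit_poisson_cluster
from .community_metrics import hill_number
from .core_io import FUNCTIONS, FunctionObservations

DEFAULT_THRESHOLDS = np.arange(5, 96)  # percent


class MultifunctionalityError(ValueError):
    pass


@dataclass
class ThresholdCurve:
    """Diversity-effect slopes across function-performance thresholds."""

    treatment: str
    curve: pd.DataFrame              # threshold, beta, lo, hi, significant
    t_min: float | None
    t_max: float | None
    r_mde: float | None
    t_mde: float | None

    @property
    def species_per_function(self) -> float | None:
        """1 / R_mde: species needed to add one function at T_mde."""
        if self.r_mde is None or self.r_mde == 0:
            return None
        return 1.0 / self.r_mde


def standardize(obs: FunctionObservations, top_frac: float = 0.05
                ) -> tuple[pd.DataFrame, dict[str, float], list[str]]:
    """Standardize raw rates against the top-``top_frac`` maximum.

    ``F_max`` per function is the mean of the ``ceil(top_frac * n)``
    largest observed rates; ``F_std = min(rate / F_max, 1)``.  Functions
    with fewer than 20 observations fall back, flagged, to the single
    maximum.  An all-zero function is an error (its maximum is undefined).
    """
    df = obs.obs.copy()
    df["rate"] = df["n_success"] / df["n_offered"]
    f_max: dict[str, float] = {}
    flags: list[str] = []
    for fn, sub in df.groupby("function"):
        rates = np.sort(sub["rate"].to_numpy())[::-1]
        if len(rates) < 20:
            flags.append(f"{fn}: <20 observations, top set = maximum value")
            top = rates[:1]
        else:
            top = rates[: int(np.ceil(top_frac * len(rates)))]
        fm = float(top.mean())
        if fm <= 0:
            raise MultifunctionalityError(
                f"function {fn!r} has all-zero rates; F_max undefined")
        f_max[fn] = fm
    df["F_max"] = df["function"].map(f_max)
    df["F_std"] = np.minimum(df["rate"] / df["F_max"], 1.0)
    return df, f_max, flags


def std_wide(std: pd.DataFrame) -> pd.DataFrame:
    """Samples x functions matrix of standardized rates."""
    return std.pivot_table(index="sample_id", columns="function",
                           values="F_std", aggfunc="mean")


@dataclass
class EffectiveMF:
    table: pd.DataFrame              # sample_id -> A, qN, M_q
    q: float
    flags: list[str] = field(default_factory=list)


def effective_mf(std: pd.DataFrame, q: float = 1.0) -> EffectiveMF:
    """Evenness-discounted effective multifunctionality per sample.

    ``A`` is the arithmetic mean of the standardized rates, ``qN`` the Hill
    number of order ``q`` of their proportions, and
    ``M_q = A * qN / N_f`` — equal to ``A`` exactly when all functions
    perform evenly, and discounted otherwise.  Samples whose standardized
    rates are all zero get ``M_q = 0`` with a flag.
    """
    wide = std_wide(std)
    n_f = wide.shape[1]
    flags = []
    rows = {}
    for sid, r in wide.iterrows():
        vals = r.to_numpy(dtype=float)
        a = float(np.nanmean(vals))
        tot = np.nansum(vals)
        if tot <= 0:
            flags.append(f"{sid}: all standardized rates zero")
            rows[sid] = {"A": a, "qN": np.nan, "M_q": 0.0}
            continue
        qn = hill_number(vals, q)
        rows[sid] = {"A": a, "qN": qn, "M_q": a * qn / n_f}
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "sample_id"
    return EffectiveMF(table, q, flags)


def functions_above_threshold(std: pd.DataFrame,
                              thresholds: np.ndarray = DEFAULT_THRESHOLDS
                              ) -> pd.DataFrame:
    """Per sample, the count of functions with F_std >= t for each t (%)."""
    wide = std_wide(std)
    out = {int(t): (wide >= t / 100.0).sum(axis=1) for t in thresholds}
    return pd.DataFrame(out, index=wide.index)


def _poisson_ame(df: pd.DataFrame, xcol: str, ycol: str):
    """Response-scale slope (average marginal effect) of a Poisson fit.

    Returns (ame, lo, hi, flag).  The AME of ``x`` is ``b_x * mean(mu)``;
    its CI comes from the delta method on the cluster-robust covariance.
    """
    if df[ycol].nunique() <= 1:
        return 0.0, 0.0, 0.0, "degenerate"
    X = pd.get_dummies(df[["block"]], drop_first=True, dtype=float)
    X.insert(0, "const", 1.0)
    X.insert(1, xcol, df[xcol].to_numpy(dtype=float))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = sm.GLM(df[ycol].to_numpy(dtype=float), X,
                     family=sm.families.Poisson()).fit(
            cov_type="cluster", cov_kwds={"groups": df["plot"]})
    mu = fit.fittedvalues.to_numpy()
    b = fit.params
    d = b.index.get_loc(xcol)
    ame = float(b.iloc[d] * mu.mean())
    Xv = X.to_numpy(dtype=float)
    grad = b.iloc[d] * (mu[:, None] * Xv).mean(axis=0)
    grad[d] += mu.mean()
    var = float(grad @ fit.cov_params().to_numpy() @ grad)
    half = 1.959963984540054 * np.sqrt(max(var, 0.0))
    return ame, ame - half, ame + half, ""


def threshold_sweep(std: pd.DataFrame, profiles: pd.DataFrame,
                    design: pd.DataFrame, diversity_var: str = "S",
                    thresholds: np.ndarray = DEFAULT_THRESHOLDS
                    ) -> dict[str, ThresholdCurve]:
    """Diversity-effect slope at every threshold, per treatment arm.

    For each threshold t the count of functions performed above t is
    regressed (Poisson, block fixed effects, plot-cluster errors) on the
    chosen diversity variable; the slope is reported on the response scale
    so its reciprocal reads as species-per-function.  Thresholds whose 95%
    interval excludes zero are significant; ``T_min`` / ``T_max`` are the
    extremes of that range and ``R_mde`` the largest significant slope.
    """
    m = functions_above_threshold(std, thresholds)
    data = design.set_index("sample_id").join(
        profiles[[diversity_var]], how="inner").join(m, how="inner")
    out: dict[str, ThresholdCurve] = {}
    for arm, sub in data.groupby("treatment", observed=True):
        rows = []
        for t in thresholds:
            d = sub[["block", "plot", diversity_var, int(t)]].rename(
                columns={int(t): "m"})
            ame, lo, hi, flag = _poisson_ame(d, diversity_var, "m")
            sig = bool(lo > 0 or hi < 0) and flag == ""
            rows.append({"threshold": int(t), "beta": ame, "lo": lo,
                         "hi": hi, "significant": sig, "flag": flag})
        curve = pd.DataFrame(rows)
        sig = curve[curve["significant"]]
        if len(sig):
            t_min = float(sig["threshold"].min())
            t_max = float(sig["threshold"].max())
            best = sig.loc[sig["beta"].idxmax()]
            r_mde, t_mde = float(best["beta"]), float(best["threshold"])
        else:
            t_min = t_max = r_mde = t_mde = None
        out[str(arm)] = ThresholdCurve(str(arm), curve, t_min, t_max,
                                       r_mde, t_mde)
    return out


def species_per_function(r_mde: float) -> float:
    """Reciprocal-slope conversion: species needed per additional function."""
    if r_mde == 0:
        raise MultifunctionalityError("R_mde = 0 has no reciprocal")
    return 1.0 / r_mde


def mde_test(std: pd.DataFrame, design: pd.DataFrame,
             curves: dict[str, ThresholdCurve]) -> EffectResult:
    """Treatment test at the mean-``T_mde`` threshold.

    The single testable threshold is the average of the two arms'
    strongest-effect thresholds; the count of functions above it is
    regressed on treatment (Poisson, split-plot errors).
    """
    t_stars = [c.t_mde for c in curves.values()]
    if any(t is None for t in t_stars):
        raise MultifunctionalityError(
            "T_mde undefined in at least one arm; no testable threshold")
    t_star = float(np.mean(t_stars))
    wide = std_wide(std)
    m = (wide >= t_star / 100.0).sum(axis=1).rename("m")
    df = design.merge(m, left_on="sample_id", right_index=True)
    df["treatment"] = pd.Categorical(df["treatment"],
                                     categories=["control", "suppression"])
    res = fit_poisson_cluster(df, "m", "treatment")
    res.flags.append(f"threshold = {t_star:.1f}%")
    return res


def function_covariance(std: pd.DataFrame, design: pd.DataFrame,
                        by_treatment: bool = True, n_perm: int = 999,
                        seed: int = 0, level: str = "sample"
                        ) -> pd.DataFrame:
    """Pairwise between-function correlations with permutation p-values.

    Correlations are computed across plot-level observations (the raw
    sample level by default, or plot means with ``level='plot'``); p-values
    come from ``n_perm`` seeded permutations of one function's vector.
    Zero-variance functions yield flagged undefined pairs.
    """
    wide = std_wide(std)
    meta = design.set_index("sample_id").loc[wide.index]
    rng = np.random.default_rng(seed)
    arms = meta["treatment"].unique() if by_treatment else ["all"]
    rows = []
    for arm in arms:
        sub = wide if arm == "all" else wide[meta["treatment"] == arm]
        if level == "plot":
            sub = sub.groupby(meta.loc[sub.index, "plot"]).mean()
        funcs = [f for f in FUNCTIONS if f in sub.columns]
        for i, f in enumerate(funcs):
            for g in funcs[i:]:
                x, y = sub[f].to_numpy(), sub[g].to_numpy()
                if np.std(x) == 0 or np.std(y) == 0:
                    rows.append({"treatment": arm, "f1": f, "f2": g,
                                 "correlation": np.nan, "p_value": np.nan,
                                 "flag": "zero variance"})
                    continue
                r = float(np.corrcoef(x, y)[0, 1])
                if f == g:
                    rows.append({"treatment": arm, "f1": f, "f2": g,
                                 "correlation": 1.0, "p_value": 0.0,
                                 "flag": ""})
                    continue
                null = np.empty(n_perm)
                for k in range(n_perm):
                    null[k] = np.corrcoef(x, rng.permutation(y))[0, 1]
                p = float((1 + np.sum(np.abs(null) >= abs(r))) / (n_perm + 1))
                rows.append({"treatment": arm, "f1": f, "f2": g,
                             "correlation": r, "p_value": p, "flag": ""})
    return pd.DataFrame(rows)
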