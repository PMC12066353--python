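"""Null-model species-function association and treatment shifts.

For every species x function cell within a treatment arm, the observed
least-squares slope of function rate on species abundance across samples
is compared with a null distribution obtained by permuting the rate
vector across samples (abundances fixed, 999 randomizations by default).
The standardized effect size SES = (obs - null mean) / null sd measures a
species' association with that function; |SES| > 1.96 is flagged
significant.  Subtracting control-arm SES from suppression-arm SES gives a
delta-treatment shift, and Spearman's rho between control SES and delta
tests whether functionally important species respond most to suppression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import CommunityMatrix

SES_CUTOFF = 1.96


class SpeciesAssocError(ValueError):
    pass


@dataclass
class SpearmanResult:
    function: str
    rho: float
    p_value: float
    n: int
    flag: str = ""


def _slopes(a_centered: np.ndarray, ssq: np.ndarray,
            rates: np.ndarray) -> np.ndarray:
    """OLS slopes of each rate column on each (centered) abundance column.

    ``a_centered``: samples x species; ``rates``: samples x k.  Returns a
    species x k slope matrix; columns with zero abundance variance are NaN.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (a_centered.T @ rates) / ssq[:, None]
    return out


def ses_null(comm: CommunityMatrix, rates: pd.DataFrame,
             design: pd.DataFrame, arm: str, n_rand: int = 999,
             seed: int = 0) -> pd.DataFrame:
    """SES table for one treatment arm.

    ``rates`` is a samples x functions table of (standardized or raw)
    rates.  Only samples of ``arm`` that appear in both tables are used.
    Species with zero abundance variance in the arm (e.g. never captured)
    get flagged NaN SES.
    """
    sids = design.loc[design["treatment"] == arm, "sample_id"]
    sids = [s for s in sids if s in rates.index and s in comm.counts.index]
    if len(sids) < 5:
        raise SpeciesAssocError(f"arm {arm!r} has <5 usable samples")
    A = comm.counts.loc[sids].to_numpy(dtype=float)
    R = rates.loc[sids].to_numpy(dtype=float)
    species = comm.counts.columns
    functions = rates.columns

    a_c = A - A.mean(axis=0)
    ssq = (a_c ** 2).sum(axis=0)
    obs = _slopes(a_c, ssq, R - R.mean(axis=0))

    rng = np.random.default_rng(seed)
    n = len(sids)
    null_sum = np.zeros_like(obs)
    null_sq = np.zeros_like(obs)
    for _ in range(n_rand):
        perm = rng.permutation(n)
        s = _slopes(a_c, ssq, R[perm] - R.mean(axis=0))
        null_sum += s
        null_sq += s ** 2
    null_mean = null_sum / n_rand
    null_var = null_sq / n_rand - null_mean ** 2
    null_sd = np.sqrt(np.maximum(null_var, 0.0))

    rows = []
    for i, sp in enumerate(species):
        for j, fn in enumerate(functions):
            flag = ""
            if ssq[i] == 0:
                ses = np.nan
                flag = "zero abundance variance"
            elif null_sd[i, j] == 0:
                ses = np.nan
                flag = "degenerate null (constant rates)"
            else:
                ses = (obs[i, j] - null_mean[i, j]) / null_sd[i, j]
            rows.append({
                "species": sp, "function": fn, "treatment": arm,
                "slope": obs[i, j] if ssq[i] > 0 else np.nan,
                "null_mean": null_mean[i, j], "null_sd": null_sd[i, j],
                "SES": ses,
                "significant": bool(np.isfinite(ses) and abs(ses) > SES_CUTOFF),
                "flag": flag,
            })
    return pd.DataFrame(rows)


def delta_and_rank(control: pd.DataFrame,
                   suppression: pd.DataFrame) -> pd.DataFrame:
    """Treatment shift per cell: ``delta = SES_suppression - SES_control``.

    Cells present in only one arm are dropped (reported in the ``dropped``
    attribute is overkill; they simply do not appear).  Deltas are ranked
    smallest to largest per function, ties broken by species id.
    """
    key = ["species", "function"]
    c = control.set_index(key)["SES"]
    s = suppression.set_index(key)["SES"]
    common = c.index.intersection(s.index)
    if len(common) == 0:
        raise SpeciesAssocError("control and suppression share no cells")
    out = pd.DataFrame({"SES_control": c.loc[common],
                        "SES_suppression": s.loc[common]})
    out["delta"] = out["SES_suppression"] - out["SES_control"]
    out = out.reset_index().sort_values(["function", "delta", "species"])
    out["rank"] = out.groupby("function")["delta"].rank(method="first")
    return out.reset_index(drop=True)


def importance_response_correlation(delta_table: pd.DataFrame
                                    ) -> list[SpearmanResult]:
    """Spearman's rho of control-arm SES versus delta, per function."""
    results = []
    for fn, sub in delta_table.groupby("function"):
        sub = sub.dropna(subset=["SES_control", "delta"])
        if len(sub) < 5:
            results.append(SpearmanResult(fn, np.nan, np.nan, len(sub),
                                          "fewer than 5 usable species"))
            continue
        rho, p = stats.spearmanr(sub["SES_control"], sub["delta"])
        results.append(SpearmanResult(fn, float(rho), float(p), len(sub)))
    return results
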