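"""Shape of the species-richness -> functional-richness relationship.

Penalized cubic B-spline regressions (second-order difference penalty,
smoothing parameter chosen by GCV) test whether functional richness
saturates with species richness.  The effective degrees of freedom (edf)
of the smooth read as curvature: edf ~ 1 means the penalty has shrunk the
fit to a line; edf > 2 signals real nonlinearity such as an asymptote.
Five candidate models of increasing complexity — intercept-only,
treatment-only, a single richness smooth, treatment intercepts plus a
shared smooth, and treatment intercepts plus per-treatment smooths — are
compared by AIC.  Block fixed intercepts stand in for the nested random
effects of the split-plot design (three balanced blocks; treatment varies
within block).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import BSpline

CANDIDATES = ("null", "treatment_only", "richness_only", "additive",
              "interaction")


class SRFRError(ValueError):
    pass


@dataclass
class SplineFit:
    """One penalized-spline fit of FRic on S."""

    edf: float                   # edf of the smooth (excludes its linear-null intercept share)
    edf_total: float
    k_basis: int
    lam: float
    f_stat: float
    p_value: float
    aic: float
    rss: float
    n: int
    fitted: pd.DataFrame         # grid: S, fit, lo, hi
    flags: list[str] = field(default_factory=list)


@dataclass
class ModelComparison:
    table: pd.DataFrame          # candidate, aic, delta_aic, edf, converged
    selected: str
    tie: bool


def _smooth_basis(x: np.ndarray, k_basis: int, degree: int = 3,
                  xmin: float | None = None, xmax: float | None = None):
    """Sum-to-zero-constrained B-spline basis and its difference penalty.

    Returns (Z-basis design, penalty, reconstruction info) where the raw
    ``k_basis`` columns are reparametrized to ``k_basis - 1`` columns
    orthogonal to the intercept.
    """
    if k_basis < 4:
        raise SRFRError("k_basis must be >= 4 for a cubic spline")
    xmin = float(np.min(x)) if xmin is None else xmin
    xmax = float(np.max(x)) if xmax is None else xmax
    if xmax <= xmin:
        raise SRFRError("richness has zero range")
    # P-spline convention: equally spaced knots extended past the data so
    # the difference penalty's null space is exactly the linear functions
    h = (xmax - xmin) / (k_basis - degree)
    t = xmin + h * np.arange(-degree, k_basis + 1)
    B = BSpline.design_matrix(np.clip(x, xmin, xmax), t, degree).toarray()
    D = np.diff(np.eye(k_basis), n=2, axis=0)
    S = D.T @ D
    c = B.mean(axis=0, keepdims=True)
    _, _, vt = np.linalg.svd(c)
    Z = vt[1:].T                               # null space of the constraint
    return B @ Z, Z.T @ S @ Z, (t, degree, Z)


def _pls_fit(y: np.ndarray, Xp: np.ndarray, smooths, lambdas):
    """Penalized least squares with parametric block and smooth blocks.

    ``smooths`` is a list of (design, penalty) pairs; ``lambdas`` one
    smoothing parameter per smooth.  Returns coefficients, per-column edf,
    RSS and the penalized normal-matrix inverse.
    """
    blocks = [Xp] + [b for b, _ in smooths]
    X = np.hstack(blocks)
    p = X.shape[1]
    P = np.zeros((p, p))
    off = Xp.shape[1]
    for (b, s), lam in zip(smooths, lambdas):
        k = b.shape[1]
        P[off:off + k, off:off + k] = lam * s
        off += k
    XtX = X.T @ X
    A = XtX + P
    Ainv = np.linalg.inv(A + 1e-10 * np.eye(p))
    beta = Ainv @ X.T @ y
    edf_cols = np.diag(Ainv @ XtX)
    resid = y - X @ beta
    return X, beta, edf_cols, float(resid @ resid), Ainv


def _reml_score(y, Xp, smooths, lambdas):
    """Negative restricted likelihood (up to constants) of one lambda vector.

    Gaussian REML with the error variance profiled out:
    ``(n - M_p)/2 log(RSS + pen) + 1/2 log|X'X + P| - sum_j rank(S_j)/2 log(lam_j)``
    where ``M_p`` counts the unpenalized dimensions (parametric block plus
    penalty null spaces).
    """
    blocks = [Xp] + [b for b, _ in smooths]
    X = np.hstack(blocks)
    p = X.shape[1]
    P = np.zeros((p, p))
    off = Xp.shape[1]
    pen_logdet = 0.0
    m_p = Xp.shape[1]
    for (b, s), lam in zip(smooths, lambdas):
        k = b.shape[1]
        P[off:off + k, off:off + k] = lam * s
        rank = np.linalg.matrix_rank(s)
        m_p += k - rank
        pen_logdet += rank * np.log(lam)
        off += k
    A = X.T @ X + P
    sign, logdet = np.linalg.slogdet(A)
    if sign <= 0:
        return np.inf
    beta = np.linalg.solve(A + 1e-10 * np.eye(p), X.T @ y)
    resid = y - X @ beta
    rss_pen = float(resid @ resid + beta @ P @ beta)
    n = len(y)
    if n <= m_p:
        return np.inf
    # floor guards the noiseless case; ties then resolve to heavier smoothing
    rss_pen = max(rss_pen, 1e-12 * (1.0 + float(y @ y)))
    return (n - m_p) / 2 * np.log(rss_pen) + 0.5 * logdet - 0.5 * pen_logdet


_LAM_GRID = np.logspace(-4, 9, 27)


def _select_lambdas(y, Xp, smooths):
    """Coordinate-descent REML over a log-spaced grid, one lambda per smooth."""
    lams = [1.0] * len(smooths)
    for _ in range(3 if len(smooths) > 1 else 1):
        for j in range(len(smooths)):
            scores = []
            for lam in _LAM_GRID:
                trial = list(lams)
                trial[j] = lam
                scores.append(_reml_score(y, Xp, smooths, trial))
            best = np.min(scores)
            # among near-ties prefer the largest lambda (heavier smoothing)
            close = np.flatnonzero(np.asarray(scores) <= best + 1e-8)
            lams[j] = float(_LAM_GRID[close[-1]])
    return lams


def _gaussian_aic(n: float, rss: float, edf: float) -> float:
    return n * np.log(rss / n) + 2.0 * (edf + 1.0)


def fit_srfr(data: pd.DataFrame, k_basis: int = 9,
             grid_points: int = 50) -> SplineFit:
    """Penalized smooth of FRic on S (single group of observations).

    ``data`` needs columns ``S``, ``FRic`` and ``block``.  The reported
    ``edf`` is the effective degrees of freedom of the smooth term; the
    F statistic compares the smooth against the block-only model (a
    standard penalized-regression approximation).
    """
    if len(data) < 10:
        raise SRFRError("need >= 10 observations")
    if k_basis > len(data):
        raise SRFRError("k_basis exceeds the number of observations")
    y = data["FRic"].to_numpy(dtype=float)
    x = data["S"].to_numpy(dtype=float)
    Xp = pd.get_dummies(data["block"].astype(str), dtype=float).to_numpy()
    B, S, (t, degree, Z) = _smooth_basis(x, k_basis)
    smooths = [(B, S)]
    lam = _select_lambdas(y, Xp, smooths)
    X, beta, edf_cols, rss, Ainv = _pls_fit(y, Xp, smooths, lam)
    n = len(y)
    p_par = Xp.shape[1]
    edf_total = float(edf_cols.sum())
    edf_smooth = float(edf_cols[p_par:].sum())

    # F test of the smooth against the parametric-only fit
    beta0 = np.linalg.lstsq(Xp, y, rcond=None)[0]
    rss0 = float(((y - Xp @ beta0) ** 2).sum())
    df2 = max(n - edf_total, 1.0)
    if edf_smooth > 1e-8 and rss > 0:
        f = ((rss0 - rss) / edf_smooth) / (rss / df2)
        p = float(stats.f.sf(f, edf_smooth, df2))
    else:
        f, p = 0.0, 1.0

    sigma2 = rss / df2
    grid = np.linspace(x.min(), x.max(), grid_points)
    Bg = BSpline.design_matrix(grid, t, degree).toarray() @ Z
    Xg = np.hstack([np.full((grid_points, p_par), Xp.mean(axis=0)), Bg])
    fit_mean = Xg @ beta
    cov = sigma2 * (Ainv @ (X.T @ X) @ Ainv)
    se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", Xg, cov, Xg), 0.0))
    fitted = pd.DataFrame({"S": grid, "fit": fit_mean,
                           "lo": fit_mean - 1.96 * se,
                           "hi": fit_mean + 1.96 * se})
    return SplineFit(edf_smooth, edf_total, k_basis, lam[0], float(f), p,
                     _gaussian_aic(n, rss, edf_total), rss, n, fitted)


def fit_srfr_by_treatment(data: pd.DataFrame,
                          k_basis: int = 9) -> dict[str, SplineFit]:
    """Separate penalized smooths for the control and suppression arms."""
    out = {}
    for arm, sub in data.groupby("treatment", observed=True):
        out[str(arm)] = fit_srfr(sub, k_basis=k_basis)
    return out


def _candidate_design(data: pd.DataFrame, candidate: str, k_basis: int):
    """Parametric block + smooth blocks for one candidate model."""
    y = data["FRic"].to_numpy(dtype=float)
    x = data["S"].to_numpy(dtype=float)
    blocks = pd.get_dummies(data["block"].astype(str), dtype=float).to_numpy()
    treat = (data["treatment"].astype(str) == "suppression"
             ).to_numpy(dtype=float)[:, None]
    smooths = []
    if candidate == "null":
        Xp = blocks
    elif candidate == "treatment_only":
        Xp = np.hstack([blocks, treat])
    elif candidate == "richness_only":
        Xp = blocks
        smooths.append(_smooth_basis(x, k_basis)[:2])
    elif candidate == "additive":
        Xp = np.hstack([blocks, treat])
        smooths.append(_smooth_basis(x, k_basis)[:2])
    elif candidate == "interaction":
        Xp = np.hstack([blocks, treat])
        xmin, xmax = float(x.min()), float(x.max())
        for arm_val in (0.0, 1.0):
            mask = (treat[:, 0] == arm_val).astype(float)
            B, S, _ = _smooth_basis(x, k_basis, xmin=xmin, xmax=xmax)
            smooths.append((B * mask[:, None], S))
    else:
        raise SRFRError(f"unknown candidate {candidate!r}")
    return y, Xp, smooths


def compare_candidates(data: pd.DataFrame,
                       k_basis: int = 9) -> ModelComparison:
    """AIC comparison of the five candidate models on identical data.

    Ties (within 1e-9 AIC) resolve to the simpler candidate; candidates
    that fail numerically are excluded with a flag in the table.
    """
    rows = []
    for cand in CANDIDATES:
        try:
            y, Xp, smooths = _candidate_design(data, cand, k_basis)
            lams = _select_lambdas(y, Xp, smooths) if smooths else []
            _, _, edf_cols, rss, _ = _pls_fit(y, Xp, smooths, lams)
            edf = float(edf_cols.sum())
            aic = _gaussian_aic(len(y), rss, edf)
            rows.append({"candidate": cand, "aic": aic, "edf": edf,
                         "converged": True})
        except Exception as exc:
            rows.append({"candidate": cand, "aic": np.nan, "edf": np.nan,
                         "converged": False, "flag": str(exc)})
    table = pd.DataFrame(rows)
    ok = table[table["converged"]]
    if ok.empty:
        raise SRFRError("no candidate model converged")
    best_aic = ok["aic"].min()
    table["delta_aic"] = table["aic"] - best_aic
    # tie-break to the simpler model: CANDIDATES is ordered by complexity
    tied = ok[np.isclose(ok["aic"], best_aic, rtol=0, atol=1e-9)]
    order = {c: i for i, c in enumerate(CANDIDATES)}
    selected = min(tied["candidate"], key=order.get)
    return ModelComparison(table, selected, tie=len(tied) > 1)
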