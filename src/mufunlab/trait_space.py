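"""Mixed-trait distances, weighted ordination and functional diversity.

Builds the functional trait space of the species pool: a Gower distance
matrix over ten mixed-type traits, an incidence-weighted principal
coordinates analysis (PCoA), distance-based trait groupings
(partitioning-around-medoids), dominant-species selection by site-wide
incidence, and the per-community functional diversity metrics FRic
(convex-hull volume in reduced trait space) and FDis (abundance-weighted
mean distance to the weighted centroid).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError

from .core_io import CommunityMatrix, TraitTable


class TraitSpaceError(ValueError):
    pass


@dataclass
class PCoAResult:
    coords: pd.DataFrame          # species x axes ("PCo1", ...)
    eigvals: np.ndarray           # positive eigenvalues, non-increasing
    var_explained: np.ndarray     # fraction of positive-spectrum variance
    correction: float             # Cailliez constant applied (0 if none)


@dataclass
class TraitSpace:
    """Distance matrix, ordination, groupings and dominants of the pool."""

    distance: pd.DataFrame
    pcoa: PCoAResult
    groups: pd.Series             # species -> group label
    dominants: pd.Series          # group -> species id
    tie_flags: dict[int, list[str]]


def gower_matrix(traits: TraitTable) -> pd.DataFrame:
    """Gower dissimilarity over the mixed trait table.

    Continuous and ordinal traits contribute ``|x_i - x_j| / range``;
    binary and categorical traits contribute a 0/1 mismatch.  The distance
    is the average contribution over traits that are non-missing in both
    species.  Numeric traits with zero range are excluded with a warning
    (their normalization is undefined); constant categorical traits simply
    contribute zero mismatch.  If every trait is constant the distance is
    undefined.
    """
    df = traits.traits
    n = len(df)
    if n < 2:
        raise TraitSpaceError("need >= 2 species for a distance matrix")
    num = np.zeros((n, n))
    den = np.zeros((n, n))
    used = 0
    for col in df.columns:
        kind = traits.trait_types[col]
        x = df[col]
        valid = x.notna().to_numpy()
        both = np.outer(valid, valid)
        if kind in ("continuous", "ordinal"):
            xv = pd.to_numeric(x, errors="coerce").to_numpy(dtype=float)
            rng = np.nanmax(xv) - np.nanmin(xv)
            if not np.isfinite(rng) or rng == 0:
                warnings.warn(f"trait {col!r} has zero range; excluded")
                continue
            contrib = np.abs(xv[:, None] - xv[None, :]) / rng
            used += 1
        else:
            xv = x.to_numpy()
            contrib = (xv[:, None] != xv[None, :]).astype(float)
            if len(pd.unique(x.dropna())) >= 2:
                used += 1      # constant categorical traits add 0 mismatch
        contrib = np.where(both, contrib, 0.0)
        num += np.nan_to_num(contrib)
        den += both
    if used == 0:
        raise TraitSpaceError("all traits constant; Gower distance undefined")
    with np.errstate(invalid="ignore"):
        d = np.where(den > 0, num / den, np.nan)
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=df.index, columns=df.index)


def _check_distance(dist: pd.DataFrame) -> np.ndarray:
    d = np.asarray(dist, dtype=float)
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T, atol=1e-10):
        raise TraitSpaceError("distance matrix must be symmetric")
    return d


def _cailliez_constant(d: np.ndarray) -> float:
    """Smallest c such that d_ij + c (i != j) is Euclidean (Cailliez 1983)."""
    n = d.shape[0]
    one = np.ones((n, n)) / n
    center = np.eye(n) - one
    delta1 = center @ (-0.5 * d ** 2) @ center
    delta2 = center @ (-0.5 * d) @ center
    upper = np.block([[np.zeros((n, n)), 2.0 * delta1],
                      [-np.eye(n), -4.0 * delta2]])
    ev = np.linalg.eigvals(upper)
    return float(np.max(ev.real))


def pcoa(distance: pd.DataFrame, weights: pd.Series | None = None,
         negative_tol: float = 1e-8) -> PCoAResult:
    """Row-weighted classical scaling of a distance matrix.

    Weights (site-wide incidence) enter the double-centring step so that
    the trait-space origin reflects species occurrence; uniform weights
    recover ordinary PCoA.  If any eigenvalue is below ``-negative_tol``
    the Cailliez additive correction is applied and the analysis re-run;
    ``var_explained`` is reported over the corrected positive spectrum.
    """
    d = _check_distance(distance)
    index = distance.index
    n = d.shape[0]
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights.reindex(index), dtype=float)
        if np.any(w < 0) or not np.isfinite(w).all():
            raise TraitSpaceError("weights must be finite and >= 0")
        if w.sum() <= 0:
            raise TraitSpaceError("weights must not all be zero")
        w = w * n / w.sum()       # mean-1 scaling: uniform == classical PCoA
    p = w / n                     # probability weights for centring

    def _embed(dmat: np.ndarray):
        a = -0.5 * dmat ** 2
        row = (a * p[None, :]).sum(axis=1)
        tot = float(row @ p)
        g = a - row[:, None] - row[None, :] + tot     # weighted double-centring
        sw = np.sqrt(w)
        m = (sw[:, None] * g) * sw[None, :]
        m = (m + m.T) / 2
        vals, vecs = np.linalg.eigh(m)
        order = np.argsort(vals)[::-1]
        return vals[order], vecs[:, order], sw

    vals, vecs, sw = _embed(d)
    correction = 0.0
    if vals.min() < -negative_tol:
        correction = _cailliez_constant(d)
        d2 = d + correction
        np.fill_diagonal(d2, 0.0)
        vals, vecs, sw = _embed(d2)

    pos = vals > negative_tol
    lam = vals[pos]
    with np.errstate(divide="ignore", invalid="ignore"):
        coords = (vecs[:, pos] / sw[:, None]) * np.sqrt(lam)[None, :]
    cols = [f"PCo{i + 1}" for i in range(pos.sum())]
    return PCoAResult(
        coords=pd.DataFrame(coords, index=index, columns=cols),
        eigvals=lam,
        var_explained=lam / lam.sum(),
        correction=correction,
    )


def cluster_trait_groups(distance: pd.DataFrame, k_groups: int,
                         seed: int = 0, n_init: int = 10,
                         max_iter: int = 100) -> pd.Series:
    """Partitioning-around-medoids on a distance matrix.

    Deterministic given ``seed``: ``n_init`` random medoid initialisations
    are refined by alternating assignment and medoid update, and the
    solution with the lowest total within-group distance is kept.
    """
    d = _check_distance(distance)
    n = d.shape[0]
    if k_groups < 1:
        raise TraitSpaceError("k_groups must be >= 1")
    if k_groups > n:
        raise TraitSpaceError("k_groups cannot exceed the number of species")
    if k_groups == n:
        return pd.Series(np.arange(n), index=distance.index, name="group")
    rng = np.random.default_rng(seed)
    best_cost, best_labels = np.inf, None
    for _ in range(n_init):
        medoids = rng.choice(n, size=k_groups, replace=False)
        for _ in range(max_iter):
            labels = np.argmin(d[:, medoids], axis=1)
            new_medoids = medoids.copy()
            for g in range(k_groups):
                members = np.flatnonzero(labels == g)
                if members.size == 0:
                    continue
                within = d[np.ix_(members, members)].sum(axis=1)
                new_medoids[g] = members[np.argmin(within)]
            if np.array_equal(np.sort(new_medoids), np.sort(medoids)):
                break
            medoids = new_medoids
        labels = np.argmin(d[:, medoids], axis=1)
        cost = d[np.arange(n), medoids[labels]].sum()
        if cost < best_cost - 1e-12:
            best_cost, best_labels = cost, labels
    # canonical label order: group of the first species is 0, etc.
    remap, out = {}, np.empty(n, dtype=int)
    for i, lab in enumerate(best_labels):
        out[i] = remap.setdefault(lab, len(remap))
    return pd.Series(out, index=distance.index, name="group")


def select_dominants(groups: pd.Series,
                     incidence: pd.Series) -> tuple[pd.Series, dict[int, list[str]]]:
    """Per group, the species with the highest site-wide incidence.

    Ties are broken by lexicographic species id and reported in the
    returned tie mapping (group -> tied species ids).
    """
    if set(groups.index) != set(incidence.index):
        raise TraitSpaceError("groups and incidence must cover the same species")
    dominants, ties = {}, {}
    for g, members in groups.groupby(groups):
        sp = members.index
        if len(sp) == 0:
            raise TraitSpaceError(f"group {g} is empty")
        inc = incidence.loc[sp]
        top = inc.max()
        tied = sorted(inc.index[inc == top])
        dominants[g] = tied[0]
        if len(tied) > 1:
            ties[g] = tied
    return pd.Series(dominants, name="dominant"), ties


def build_trait_space(traits: TraitTable, k_groups: int = 5,
                      seed: int = 0) -> TraitSpace:
    """Full trait-space construction: Gower -> PCoA -> groups -> dominants."""
    dist = gower_matrix(traits)
    ord_ = pcoa(dist, weights=traits.incidence)
    groups = cluster_trait_groups(dist, k_groups, seed=seed)
    dominants, ties = select_dominants(groups, traits.incidence)
    return TraitSpace(dist, ord_, groups, dominants, ties)


def fric(abundances: pd.Series, coords: pd.DataFrame,
         n_axes: int = 2) -> float:
    """Convex-hull volume of the present species in the first axes.

    Defined as 0 when fewer than ``n_axes + 1`` species are present or the
    point set is degenerate (collinear within Qhull tolerance).
    """
    if n_axes < 2:
        raise TraitSpaceError("FRic needs >= 2 ordination axes")
    present = abundances.index[abundances > 0]
    pts = coords.loc[coords.index.intersection(present)].iloc[:, :n_axes]
    if len(pts) < n_axes + 1:
        return 0.0
    try:
        return float(ConvexHull(pts.to_numpy()).volume)
    except QhullError:
        return 0.0


def fdis(abundances: pd.Series, coords: pd.DataFrame) -> float:
    """Abundance-weighted mean distance to the weighted centroid.

    ``FDis = sum_j a_j ||x_j - c|| / sum_j a_j`` with
    ``c = sum_j a_j x_j / sum_j a_j``.  NaN for all-zero abundance; 0 for a
    single species.
    """
    a = abundances[abundances > 0]
    if a.sum() <= 0:
        return float("nan")
    x = coords.loc[a.index].to_numpy(dtype=float)
    w = a.to_numpy(dtype=float)
    c = (w[:, None] * x).sum(axis=0) / w.sum()
    return float((w * np.linalg.norm(x - c, axis=1)).sum() / w.sum())


def fd_metrics(comm: CommunityMatrix, coords: pd.DataFrame,
               n_axes: int = 2, exclude_targets: bool = False) -> pd.DataFrame:
    """FRic and FDis per sample of a community matrix."""
    m = comm.nontarget() if exclude_targets else comm
    rows = {}
    for sid, row in m.counts.iterrows():
        rows[sid] = {"FRic": fric(row, coords, n_axes),
                     "FDis": fdis(row, coords)}
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "sample_id"
    return out
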