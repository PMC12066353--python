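"""Per-sample diversity metrics and mixed-model treatment tests.

Covers species richness and abundance, Hill-number effective number of
species (ENS; exp of Shannon entropy at order q = 1), a Raup-Crick-style
compositional uniqueness score, and split-plot treatment tests with nested
random effects (see :mod:`mufunlab._mixed`).

Richness-type metrics are computed after removing the suppressed target
species when ``exclude_targets`` is set, so that treatment tests measure
the response of the *remaining* community.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._mixed import EffectResult, fit_gaussian_mixed, fit_poisson_cluster
from .core_io import CommunityMatrix


def hill_number(abundances: np.ndarray | pd.Series, q: float = 1.0) -> float:
    """Effective number of species of order ``q`` from raw abundances.

    ``q = 1`` is the Shannon limit ``exp(-sum p ln p)``; the general Hill
    formula ``(sum p^q)^(1/(1-q))`` applies otherwise.  NaN for empty
    communities.
    """
    a = np.asarray(abundances, dtype=float)
    a = a[a > 0]
    if a.size == 0:
        return float("nan")
    p = a / a.sum()
    if abs(q - 1.0) < 1e-12:
        return float(np.exp(-(p * np.log(p)).sum()))
    return float((p ** q).sum() ** (1.0 / (1.0 - q)))


def diversity_profile(comm: CommunityMatrix, exclude_targets: bool = True,
                      q: float = 1.0) -> pd.DataFrame:
    """Richness S, abundance N and ENS per sample.

    ``S`` counts species with positive abundance; targets are removed first
    when ``exclude_targets`` (the default, matching a suppression analysis
    of the non-target community).  ENS is flagged NaN for empty samples.
    """
    m = comm.nontarget() if exclude_targets else comm
    counts = m.counts
    out = pd.DataFrame(index=counts.index)
    out["S"] = (counts > 0).sum(axis=1)
    out["N"] = counts.sum(axis=1)
    out["ENS"] = [hill_number(row, q) for _, row in counts.iterrows()]
    out.index.name = "sample_id"
    return out


def _null_shared_sums(pres: np.ndarray, freq: np.ndarray, richness: np.ndarray,
                      n_null: int, rng: np.random.Generator):
    """Accumulate pairwise shared-species counts over null draws.

    Null communities preserve each sample's richness and draw species
    without replacement with probability proportional to their occurrence
    frequency (Gumbel top-k sampling).
    """
    n, s = pres.shape
    logw = np.full_like(freq, -np.inf, dtype=float)
    np.log(freq, out=logw, where=freq > 0)
    greater = np.zeros((n, n), dtype=np.int64)
    equal = np.zeros((n, n), dtype=np.int64)
    obs = pres @ pres.T
    for _ in range(n_null):
        keys = logw[None, :] + rng.gumbel(size=(n, s))
        order = np.argsort(-keys, axis=1)
        null = np.zeros((n, s), dtype=np.int8)
        for i in range(n):
            null[i, order[i, : richness[i]]] = 1
        shared = null.astype(np.int64) @ null.T.astype(np.int64)
        greater += shared > obs
        equal += shared == obs
    return greater, equal, obs


def raup_crick_uniqueness(comm: CommunityMatrix, n_null: int = 999,
                          seed: int = 0, exclude_targets: bool = True,
                          tie_weight: float = 0.5,
                          freq: np.ndarray | None = None) -> pd.Series:
    """Mean Raup-Crick dissimilarity of each sample to all partners.

    For each sample pair the null distribution of shared-species counts is
    generated by drawing, ``n_null`` times, random communities that keep
    each sample's observed richness with species sampled proportionally to
    their occurrence frequency across samples.  The pairwise score is
    ``RC = 2 * (P(null_shared > obs) + tie_weight * P(null_shared = obs)) - 1``
    so +1 means the pair shares *fewer* species than the null expects
    (compositionally unique) and -1 more.  A sample's uniqueness is the
    mean RC over all partners (itself excluded).
    """
    if n_null < 1:
        raise ValueError("n_null must be >= 1")
    m = comm.nontarget() if exclude_targets else comm
    counts = m.counts
    if len(counts) < 2:
        raise ValueError("uniqueness needs >= 2 samples")
    pres = (counts.to_numpy() > 0).astype(np.int64)
    if freq is None:
        freq = pres.sum(axis=0).astype(float)   # occurrence frequencies
    else:
        freq = np.asarray(freq, dtype=float)
    richness = pres.sum(axis=1)
    rng = np.random.default_rng(seed)
    greater, equal, _ = _null_shared_sums(pres, freq, richness, n_null, rng)
    rc = 2.0 * (greater + tie_weight * equal) / n_null - 1.0
    np.fill_diagonal(rc, np.nan)
    uniq = np.nanmean(rc, axis=1)
    return pd.Series(uniq, index=counts.index, name="uniqueness")


def raup_crick_pair_exact(n_species: int, rich_i: int, rich_j: int,
                          obs_shared: int, tie_weight: float = 0.5) -> float:
    """Closed-form RC for one pair under an equal-frequency species pool.

    With equal occurrence frequencies every richness-sized subset is
    equally likely, so the null shared-species count is hypergeometric:
    ``shared ~ Hypergeom(N=n_species, K=rich_i, n=rich_j)``.
    """
    from scipy.stats import hypergeom
    h = hypergeom(n_species, rich_i, rich_j)
    p_greater = float(h.sf(obs_shared))
    p_equal = float(h.pmf(obs_shared))
    return 2.0 * (p_greater + tie_weight * p_equal) - 1.0


def raup_crick_pair_enumerated(pres_i: np.ndarray, pres_j: np.ndarray,
                               freq: np.ndarray,
                               tie_weight: float = 0.5) -> float:
    """Exact RC for one pair by exhausting all equally-likely null draws.

    Only valid when all species frequencies are equal (each richness-sized
    subset then has equal probability); used as the enumeration oracle.
    """
    from itertools import combinations
    if len(set(freq.tolist())) != 1:
        raise ValueError("exhaustive enumeration requires equal frequencies")
    s = len(freq)
    obs = int((pres_i * pres_j).sum())
    ri, rj = int(pres_i.sum()), int(pres_j.sum())
    greater = equal = total = 0
    for a in combinations(range(s), ri):
        for b in combinations(range(s), rj):
            shared = len(set(a) & set(b))
            total += 1
            greater += shared > obs
            equal += shared == obs
    return 2.0 * (greater + tie_weight * equal) / total - 1.0


def treatment_effect(values: pd.Series | pd.DataFrame, design: pd.DataFrame,
                     response: str, family: str = "gaussian") -> EffectResult:
    """Wald Z test of the suppression contrast on a per-sample response.

    Fits ``response ~ treatment`` with the split-plot error structure:
    Gaussian responses get nested random intercepts (block, plot-in-block)
    with a flagged OLS + cluster-robust fallback; Poisson responses get a
    GLM with block fixed effects and plot-cluster-robust errors plus an
    overdispersion flag.
    """
    if isinstance(values, pd.Series):
        values = values.rename(response).to_frame()
    df = design.merge(values, left_on="sample_id", right_index=True)
    df["treatment"] = pd.Categorical(df["treatment"],
                                     categories=["control", "suppression"])
    if family == "poisson":
        return fit_poisson_cluster(df, response, "treatment")
    if family == "gaussian":
        return fit_gaussian_mixed(df, response, "treatment")
    raise ValueError(f"unknown family {family!r}")


def community_effects(comm: CommunityMatrix, design: pd.DataFrame,
                      fd: pd.DataFrame | None = None,
                      n_null: int = 999, seed: int = 0) -> pd.DataFrame:
    """Treatment tests for the standard community responses.

    Abundance and richness (non-target) are Poisson; ENS, uniqueness and —
    when functional-diversity metrics are supplied — FRic and FDis are
    Gaussian.  Returns one row per response with estimate, Z and p.
    """
    prof = diversity_profile(comm, exclude_targets=True)
    uniq = raup_crick_uniqueness(comm, n_null=n_null, seed=seed)
    results = [
        treatment_effect(prof["N"], design, "abundance", family="poisson"),
        treatment_effect(prof["S"], design, "richness", family="poisson"),
        treatment_effect(prof["ENS"], design, "ENS", family="gaussian"),
        treatment_effect(uniq, design, "uniqueness", family="gaussian"),
    ]
    if fd is not None:
        results.append(treatment_effect(fd["FRic"], design, "FRic"))
        results.append(treatment_effect(fd["FDis"], design, "FDis"))
    rows = [{"response": r.response, "estimate": r.estimate, "se": r.se,
             "Z": r.z, "p_value": r.p_value, "family": r.family,
             "method": r.method, "flags": "; ".join(r.flags)}
            for r in results]
    return pd.DataFrame(rows).set_index("response")
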