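"""Synthetic split-plot suppression experiments with known ground truth.

The generator emulates the layout of a dominant-ant suppression field
experiment: 3 spatial blocks, each split into one control and one
suppression zone, 2 focal plots per zone, 4 plot quarters and 4 sampling
events.  Pitfall abundances are overdispersed counts (negative binomial;
Poisson as the ``nb_size = inf`` special case).  Targets — the dominant
species of the first ``n_targets`` trait groups — are multiplied by a
per-target suppression factor in suppression zones (defaults 0.06 / 0.04 /
0.01, i.e. 94% / 96% / 99% reductions) while non-targets experience
compensatory release.  Four bait-based ecosystem functions (scavenging,
myrmecochory, granivory, plant protection) are binomial trials whose
success probability responds to non-target richness, treatment, planted
"performer" species and correlated plot-level noise.

Every stochastic element is governed by ``ScenarioConfig.seed``; each table
draws from its own deterministic sub-stream so regenerating one table never
perturbs another.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit

from .core_io import (CommunityMatrix, Dataset, FunctionObservations,
                      TraitTable, ValidationReport, write_tables)

FUNCTIONS = ("scavenging", "myrmecochory", "granivory", "plant_protection")

#: trait name -> kind for the generated 10-trait mix
TRAIT_TYPES: dict[str, str] = {
    "weber_length": "continuous",
    "head_width": "continuous",
    "eye_width": "continuous",
    "leg_length": "continuous",
    "mandible_index": "continuous",
    "sculpturing": "continuous",
    "pilosity": "ordinal",
    "polymorphic": "binary",
    "spines": "binary",
    "foraging_strategy": "categorical",
}

_FORAGING_LEVELS = ("solitary", "group", "mass")


class ConfigError(ValueError):
    """Scenario configuration is degenerate or inconsistent."""


@dataclass
class FunctionParams:
    """Planted effects for one ecosystem function (link scale)."""

    alpha: float                  # baseline (logit or probability intercept)
    beta_richness: float          # slope per non-target species
    beta_treatment: float         # direct suppression effect
    performer: int | None = None  # species index (non-target) boosting rate
    performer_effect: float = 0.0


def _default_functions() -> dict[str, FunctionParams]:
    # Effect signs echo the field experiment: richness raises scavenging,
    # myrmecochory and plant protection but lowers granivory; the direct
    # suppression effect is positive on granivory, negative on plant
    # protection and absent elsewhere.
    return {
        "scavenging": FunctionParams(0.1, 0.10, 0.0, performer=5,
                                     performer_effect=1.0),
        "myrmecochory": FunctionParams(-0.3, 0.10, 0.0, performer=6,
                                       performer_effect=1.0),
        "granivory": FunctionParams(-0.5, -0.10, 0.5, performer=7,
                                    performer_effect=1.0),
        "plant_protection": FunctionParams(-0.2, 0.10, -0.6, performer=8,
                                           performer_effect=1.0),
    }


def _default_corr() -> np.ndarray:
    # positive covariance among scavenging / myrmecochory / plant protection,
    # negative between granivory and both myrmecochory and plant protection
    r = np.array([
        [1.0, 0.4, 0.0, 0.4],
        [0.4, 1.0, -0.4, 0.4],
        [0.0, -0.4, 1.0, -0.5],
        [0.4, 0.4, -0.5, 1.0],
    ])
    return r


@dataclass
class ScenarioConfig:
    """Parameters of one synthetic suppression experiment."""

    n_blocks: int = 3
    n_plots_per_zone: int = 2
    n_quarters: int = 4
    n_events: int = 4

    n_species: int = 34
    n_trait_groups: int = 5
    n_targets: int = 3
    target_suppression: tuple[float, ...] = (0.06, 0.04, 0.01)
    nontarget_release: float = 1.4
    nb_size: float = 4.0              # NB dispersion; np.inf -> Poisson
    dominant_mean_range: tuple[float, float] = (8.0, 18.0)
    rare_mean_median: float = 0.6     # lognormal median of non-dominant means
    rare_mean_sigma: float = 1.1      # lognormal sigma of non-dominant means
    group_separation: float = 2.0     # continuous-trait group mean spread (sd units)

    link: str = "logit"               # "logit" | "identity"
    functions: dict[str, FunctionParams] = field(default_factory=_default_functions)
    function_corr: np.ndarray = field(default_factory=_default_corr)
    noise_sd: float = 0.25            # sd of correlated per-sample noise
    n_offered_ground: int = 40        # per plot-quarter (80 per plot)
    n_offered_plant: int = 16         # per plot-quarter (32 per plot)
    function_quarters: tuple[str, ...] = ("1", "2")

    seed: int = 0

    def validate(self) -> None:
        if self.n_species < max(2, self.n_trait_groups):
            raise ConfigError("need at least one species per trait group")
        if self.n_targets > self.n_trait_groups:
            raise ConfigError("cannot have more targets than trait groups")
        if len(self.target_suppression) != self.n_targets:
            raise ConfigError("one suppression multiplier per target required")
        if any(not 0 <= s <= 1 for s in self.target_suppression):
            raise ConfigError("suppression multipliers must lie in [0, 1]")
        if self.link not in ("logit", "identity"):
            raise ConfigError(f"unknown link {self.link!r}")
        w = np.linalg.eigvalsh(np.asarray(self.function_corr))
        if w.min() < -1e-10:
            raise ConfigError("function_corr must be positive semi-definite")


def _rng(cfg: ScenarioConfig, stream: int) -> np.random.Generator:
    """Deterministic per-table sub-stream of the scenario seed."""
    return np.random.default_rng(np.random.SeedSequence([int(cfg.seed), stream]))


def species_ids(cfg: ScenarioConfig) -> list[str]:
    return [f"sp{i + 1:02d}" for i in range(cfg.n_species)]


def true_groups(cfg: ScenarioConfig) -> pd.Series:
    """Planted trait-group label per species (round-robin assignment)."""
    ids = species_ids(cfg)
    return pd.Series([i % cfg.n_trait_groups for i in range(cfg.n_species)],
                     index=ids, name="group")


def target_species(cfg: ScenarioConfig) -> list[str]:
    """The planted targets: dominants of the first ``n_targets`` groups."""
    return species_ids(cfg)[: cfg.n_targets]


def make_design(cfg: ScenarioConfig) -> pd.DataFrame:
    """Deterministic split-plot sample layout (no RNG involved)."""
    rows = []
    for b, zone, p, q, e in itertools.product(
            range(1, cfg.n_blocks + 1), ("control", "suppression"),
            range(1, cfg.n_plots_per_zone + 1),
            range(1, cfg.n_quarters + 1), range(1, cfg.n_events + 1)):
        z = "c" if zone == "control" else "s"
        plot = f"B{b}{z}P{p}"
        rows.append({
            "sample_id": f"{plot}-Q{q}-E{e}",
            "block": f"B{b}", "treatment": zone, "plot": plot,
            "quarter": str(q), "event": e,
        })
    return pd.DataFrame(rows)


def gen_traits(cfg: ScenarioConfig) -> TraitTable:
    """Draw the 10-trait table with planted group structure.

    Continuous traits get group-specific means separated by
    ``group_separation`` (in within-group sd units); binary and categorical
    traits get group-preferred levels.  The first species of each group is
    its planted dominant and receives the group's highest incidence.
    """
    cfg.validate()
    if cfg.n_species < 2:
        raise ConfigError("need >= 2 species")
    rng = _rng(cfg, 1)
    ids = species_ids(cfg)
    groups = true_groups(cfg)
    g = groups.to_numpy()
    n, k = cfg.n_species, cfg.n_trait_groups

    cont_names = [t for t, kind in TRAIT_TYPES.items() if kind == "continuous"]
    data: dict[str, np.ndarray] = {}
    for name in cont_names:
        mu = rng.normal(0.0, cfg.group_separation, size=k)
        data[name] = np.round(mu[g] + rng.normal(0.0, 1.0, size=n), 4)

    # ordinal pilosity 0..4 from a group-shifted latent scale
    latent = rng.normal(0.0, cfg.group_separation, size=k)[g] + \
        rng.normal(0.0, 1.0, size=n)
    data["pilosity"] = np.clip(np.round((latent + 4) / 2), 0, 4).astype(int)

    for name in ("polymorphic", "spines"):
        p_group = rng.choice([0.15, 0.85], size=k)
        data[name] = (rng.random(n) < p_group[g]).astype(int)

    pref = rng.integers(0, len(_FORAGING_LEVELS), size=k)
    cat = np.where(rng.random(n) < 0.8, pref[g],
                   rng.integers(0, len(_FORAGING_LEVELS), size=n))
    data["foraging_strategy"] = np.array(_FORAGING_LEVELS)[cat]

    traits = pd.DataFrame(data, index=pd.Index(ids, name="species"))
    traits = traits[list(TRAIT_TYPES)]

    # incidence: group dominants (species 0..k-1) high, the rest low
    incidence = np.round(0.5 * rng.beta(2.0, 6.0, size=n), 4)
    incidence[:k] = np.round(rng.uniform(0.65, 0.9, size=k), 4)
    incidence = pd.Series(incidence, index=traits.index, name="incidence")

    flags = pd.Series(False, index=traits.index)
    flags.iloc[: cfg.n_targets] = True
    return TraitTable(traits, dict(TRAIT_TYPES), incidence, flags)


def species_mean_abundance(cfg: ScenarioConfig) -> pd.Series:
    """Baseline per-sample mean count of each species (control conditions)."""
    rng = _rng(cfg, 2)
    n, k = cfg.n_species, cfg.n_trait_groups
    means = cfg.rare_mean_median * np.exp(
        rng.normal(0.0, cfg.rare_mean_sigma, size=n))
    means[:k] = rng.uniform(*cfg.dominant_mean_range, size=k)
    return pd.Series(means, index=species_ids(cfg), name="mean_abundance")


def gen_community(cfg: ScenarioConfig, traits: TraitTable) -> CommunityMatrix:
    """Draw the samples x species pitfall count matrix."""
    cfg.validate()
    rng = _rng(cfg, 3)
    design = make_design(cfg)
    means = species_mean_abundance(cfg).to_numpy()
    targets = set(target_species(cfg))
    supp = dict(zip(target_species(cfg), cfg.target_suppression))

    mult = np.ones(cfg.n_species)
    for j, sp in enumerate(species_ids(cfg)):
        if sp in targets:
            mult[j] = supp[sp]
        else:
            mult[j] = cfg.nontarget_release
    # floor keeps occasional long-range foragers of suppressed targets
    # (only where the species occurs at all)
    is_target = np.array([sp in targets for sp in species_ids(cfg)])
    mu_control = means
    mu_supp = np.where(is_target & (means > 0),
                       np.maximum(means * mult, 0.02), means * mult)

    is_supp = (design["treatment"] == "suppression").to_numpy()
    mu = np.where(is_supp[:, None], mu_supp[None, :], mu_control[None, :])

    if np.isinf(cfg.nb_size):
        counts = rng.poisson(mu)
    else:
        p = cfg.nb_size / (cfg.nb_size + mu)
        counts = rng.negative_binomial(cfg.nb_size, p)

    df = pd.DataFrame(counts.astype(np.int64), index=design["sample_id"],
                      columns=species_ids(cfg))
    flags = traits.target_flags.reindex(df.columns).astype(bool)
    return CommunityMatrix(df, flags)


def gen_function_obs(cfg: ScenarioConfig,
                     comm: CommunityMatrix) -> FunctionObservations:
    """Draw binomial bait-trial outcomes for the four functions.

    Success probability per sample and function:
    ``link^{-1}(alpha + beta_richness * (S - S_ref) + beta_treatment * T +
    performer contribution + correlated noise)`` where S is non-target
    richness, T the 0/1 suppression indicator, and the noise vector across
    the four functions is multivariate normal with correlation
    ``function_corr`` and sd ``noise_sd``.
    """
    cfg.validate()
    rng = _rng(cfg, 4)
    design = make_design(cfg)
    fdesign = design[design["quarter"].isin(cfg.function_quarters)]

    nt = comm.nontarget().counts
    richness = (nt > 0).sum(axis=1).astype(float)
    s_ref = float(richness.mean())
    log_ab = np.log1p(comm.counts)
    log_ab_c = log_ab - log_ab.mean(axis=0)

    cov = float(cfg.noise_sd) ** 2 * np.asarray(cfg.function_corr, dtype=float)
    eps = rng.multivariate_normal(np.zeros(len(FUNCTIONS)), cov,
                                  size=len(fdesign), method="svd")

    ids = species_ids(cfg)
    rows = []
    for i, (_, row) in enumerate(fdesign.iterrows()):
        sid = row["sample_id"]
        t = 1.0 if row["treatment"] == "suppression" else 0.0
        s = richness.loc[sid]
        for j, fn in enumerate(FUNCTIONS):
            par = cfg.functions[fn]
            lin = (par.alpha + par.beta_richness * (s - s_ref)
                   + par.beta_treatment * t + eps[i, j])
            if par.performer is not None and par.performer_effect \
                    and par.performer < len(ids):
                lin += par.performer_effect * log_ab_c.loc[sid, ids[par.performer]]
            if cfg.link == "logit":
                p = expit(lin)
            else:
                p = float(np.clip(lin, 0.02, 0.98))
            n_off = (cfg.n_offered_plant if fn == "plant_protection"
                     else cfg.n_offered_ground)
            rows.append({
                "sample_id": sid, "function": fn, "n_offered": n_off,
                "n_success": int(rng.binomial(n_off, p)),
                "assessment_window": 15 if fn == "plant_protection" else 60,
            })
    obs = FunctionObservations(pd.DataFrame(rows))
    obs.validate()
    return obs


def ground_truth(cfg: ScenarioConfig) -> dict:
    """Planted parameters as a plain serializable mapping."""
    return {
        "groups": {sp: int(g) for sp, g in true_groups(cfg).items()},
        "targets": {sp: float(s) for sp, s in
                    zip(target_species(cfg), cfg.target_suppression)},
        "nontarget_release": float(cfg.nontarget_release),
        "link": cfg.link,
        "noise_sd": float(cfg.noise_sd),
        "function_corr": np.asarray(cfg.function_corr).round(6).tolist(),
        "functions": {
            fn: {"alpha": p.alpha, "beta_richness": p.beta_richness,
                 "beta_treatment": p.beta_treatment,
                 "performer": (species_ids(cfg)[p.performer]
                               if p.performer is not None
                               and p.performer < cfg.n_species else None),
                 "performer_effect": p.performer_effect}
            for fn, p in cfg.functions.items()},
        "seed": int(cfg.seed),
    }


def gen_dataset(cfg: ScenarioConfig) -> Dataset:
    """Generate a full in-memory dataset (design, community, traits, functions)."""
    traits = gen_traits(cfg)
    comm = gen_community(cfg, traits)
    obs = gen_function_obs(cfg, comm)
    return Dataset(make_design(cfg), comm, traits, obs, ValidationReport())


def gen_scenario(cfg: ScenarioConfig, outdir: str | Path) -> dict[str, Path]:
    """Write a complete scenario (four tables + schema + truth sidecar)."""
    out = Path(outdir)
    ds = gen_dataset(cfg)
    files = write_tables(ds, out)
    files["truth"] = out / "truth.yaml"
    files["truth"].write_text(yaml.safe_dump(ground_truth(cfg), sort_keys=True))
    return files


def config_from_mapping(d: Mapping) -> ScenarioConfig:
    """Build a ScenarioConfig from a (YAML-loaded) plain mapping."""
    d = dict(d)
    if "functions" in d:
        d["functions"] = {fn: FunctionParams(**fp)
                          for fn, fp in d["functions"].items()}
    if "function_corr" in d:
        d["function_corr"] = np.asarray(d["function_corr"], dtype=float)
    for key in ("target_suppression", "function_quarters", "dominant_mean_range"):
        if key in d:
            d[key] = tuple(d[key])
    return ScenarioConfig(**d)


def with_overrides(cfg: ScenarioConfig, **kw) -> ScenarioConfig:
    """Return a copy of ``cfg`` with fields replaced (dataclass replace)."""
    return replace(cfg, **kw)
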