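"""Typed readers/writers and validation for the four experiment tables.

The pipeline is driven by four tidy CSV tables:

``design``
    one row per sample (pitfall set): ``sample_id, block, treatment, plot,
    quarter, event``.  Plots are nested in treatment zones nested in blocks;
    every block holds exactly one control and one suppression zone.
``community``
    samples x species abundance counts (wide, one column per species; a long
    ``sample_id, species, abundance`` layout is melted on load).
``traits``
    one row per species: ``species, incidence, is_target`` plus ten
    mixed-type trait columns.  Trait types (continuous / ordinal / binary /
    categorical) come from the schema config.
``functions``
    binomial bait trials: ``sample_id, function, n_offered, n_success``.

Rates are carried as (n_success, n_offered) pairs until the analysis stages
so no binomial information is discarded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

logger = logging.getLogger("mufunlab")

FUNCTIONS = ("scavenging", "myrmecochory", "granivory", "plant_protection")
TRAIT_KINDS = ("continuous", "ordinal", "binary", "categorical")

DESIGN_COLS = ["sample_id", "block", "treatment", "plot", "quarter", "event"]
FUNCTION_COLS = ["sample_id", "function", "n_offered", "n_success"]
TREATMENTS = ("control", "suppression")


class SchemaError(ValueError):
    """A table is missing required columns or has malformed values."""


class ReferentialError(ValueError):
    """Cross-table references (species, sample ids) do not reconcile."""


class BoundsError(ValueError):
    """A count violates its bounds (e.g. n_success > n_offered)."""


class DesignError(ValueError):
    """The split-plot design is inconsistent (nesting, balance, uniqueness)."""


@dataclass
class ValidationReport:
    """Accumulated findings from loading/validating a dataset."""

    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    dropped: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        lines = [f"errors: {len(self.errors)}", *self.errors,
                 f"warnings: {len(self.warnings)}", *self.warnings]
        return "\n".join(lines)


@dataclass
class TraitTable:
    """Species x mixed-type traits with site-wide incidence weights."""

    traits: pd.DataFrame              # index: species; columns: trait names
    trait_types: dict[str, str]       # trait -> kind in TRAIT_KINDS
    incidence: pd.Series              # species -> fraction of traps occupied
    target_flags: pd.Series           # species -> bool (suppressed target)

    @property
    def species(self) -> pd.Index:
        return self.traits.index

    def validate(self) -> None:
        if len(self.traits) < 2:
            raise SchemaError("trait table needs >= 2 species")
        unknown = set(self.trait_types.values()) - set(TRAIT_KINDS)
        if unknown:
            raise SchemaError(f"unknown trait kinds: {sorted(unknown)}")
        missing = set(self.traits.columns) - set(self.trait_types)
        if missing:
            raise SchemaError(f"traits without declared type: {sorted(missing)}")
        inc = self.incidence.reindex(self.traits.index)
        if inc.isna().any():
            raise ReferentialError("incidence missing for some species")
        if ((inc < 0) | (inc > 1)).any():
            raise BoundsError("incidence values must lie in [0, 1]")


@dataclass
class CommunityMatrix:
    """Samples x species abundance counts from pitfall traps."""

    counts: pd.DataFrame              # index: sample_id; columns: species
    target_flags: pd.Series           # species -> bool

    @property
    def species(self) -> pd.Index:
        return self.counts.columns

    @property
    def samples(self) -> pd.Index:
        return self.counts.index

    def nontarget(self) -> "CommunityMatrix":
        keep = self.target_flags.index[~self.target_flags.astype(bool)]
        cols = [c for c in self.counts.columns if c in set(keep)]
        return CommunityMatrix(self.counts[cols], self.target_flags.loc[cols])

    def validate(self) -> None:
        vals = self.counts.to_numpy()
        if (vals < 0).any():
            raise BoundsError("community counts must be non-negative")
        if (vals != vals.round()).any():
            raise BoundsError("community counts must be integers")


@dataclass
class FunctionObservations:
    """Binomial bait trials: per sample, per function, offered vs removed."""

    obs: pd.DataFrame                 # columns: FUNCTION_COLS (+ extras)

    def validate(self) -> None:
        missing = set(FUNCTION_COLS) - set(self.obs.columns)
        if missing:
            raise SchemaError(f"function table missing columns: {sorted(missing)}")
        bad = self.obs["n_success"] > self.obs["n_offered"]
        if bad.any():
            rows = self.obs.loc[bad, "sample_id"].tolist()[:5]
            raise BoundsError(f"n_success > n_offered for samples {rows}")
        if (self.obs["n_offered"] < 0).any() or (self.obs["n_success"] < 0).any():
            raise BoundsError("bait counts must be non-negative")

    def rates(self) -> pd.DataFrame:
        """Wide samples x functions table of raw rates (analysis stage only)."""
        out = self.obs.copy()
        out["rate"] = out["n_success"] / out["n_offered"]
        return out.pivot_table(index="sample_id", columns="function",
                               values="rate", aggfunc="mean")


@dataclass
class Dataset:
    """The four validated, cross-referenced tables of one experiment."""

    design: pd.DataFrame
    community: CommunityMatrix
    traits: TraitTable
    functions: FunctionObservations
    report: ValidationReport = field(default_factory=ValidationReport)


def _require_columns(df: pd.DataFrame, cols: Sequence[str], name: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{name} table missing columns: {missing}")


def read_design(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"sample_id": str, "block": str,
                                  "plot": str, "quarter": str})
    _require_columns(df, DESIGN_COLS, "design")
    bad = ~df["treatment"].isin(TREATMENTS)
    if bad.any():
        raise SchemaError(
            f"unknown treatment levels: {sorted(df.loc[bad, 'treatment'].unique())}")
    return df[DESIGN_COLS + [c for c in df.columns if c not in DESIGN_COLS]]


def read_community(path: str | Path,
                   target_species: Sequence[str] = ()) -> CommunityMatrix:
    """Read a community table; wide (default) or long layout auto-detected."""
    df = pd.read_csv(path, dtype={"sample_id": str})
    if {"species", "abundance"} <= set(df.columns):       # long layout
        wide = df.pivot_table(index="sample_id", columns="species",
                              values="abundance", aggfunc="sum", fill_value=0)
    else:
        _require_columns(df, ["sample_id"], "community")
        wide = df.set_index("sample_id")
    flags = pd.Series(
        [s in set(target_species) for s in wide.columns],
        index=wide.columns, dtype=bool)
    cm = CommunityMatrix(wide, flags)
    cm.validate()
    return cm


def read_traits(path: str | Path, trait_types: Mapping[str, str]) -> TraitTable:
    df = pd.read_csv(path, dtype={"species": str})
    _require_columns(df, ["species", "incidence"], "traits")
    df = df.set_index("species")
    is_target = df["is_target"].astype(bool) if "is_target" in df.columns else \
        pd.Series(False, index=df.index)
    trait_cols = [c for c in df.columns if c in trait_types]
    tt = TraitTable(df[trait_cols], dict(trait_types),
                    df["incidence"].astype(float), is_target)
    tt.validate()
    return tt


def read_functions(path: str | Path) -> FunctionObservations:
    df = pd.read_csv(path, dtype={"sample_id": str, "function": str})
    fo = FunctionObservations(df)
    fo.validate()
    return fo


def validate_design(design: pd.DataFrame) -> ValidationReport:
    """Check nesting, treatment balance and sample uniqueness of the design.

    The design is order-independent: reports are identical under row
    permutation (all findings are sorted).
    """
    rep = ValidationReport()
    if design.empty:
        rep.errors.append("empty design")
        return rep
    # plots nested in a single (block, treatment) zone
    nest = design.groupby("plot")[["block", "treatment"]].nunique()
    for plot in sorted(nest.index[(nest > 1).any(axis=1)]):
        rep.errors.append(f"plot {plot} assigned to multiple blocks/zones")
    # one control + one suppression zone per block
    for block, sub in sorted(design.groupby("block"), key=lambda kv: kv[0]):
        levels = sorted(sub["treatment"].unique())
        if levels != sorted(TREATMENTS):
            rep.errors.append(
                f"block {block} lacks paired control/suppression zones "
                f"(has {levels})")
    dup = design.duplicated(subset=["plot", "quarter", "event"])
    for _, row in design.loc[dup].sort_values(["plot", "quarter", "event"]).iterrows():
        rep.errors.append(
            f"duplicate sample for plot={row['plot']} quarter={row['quarter']} "
            f"event={row['event']}")
    return rep


def load_tables(paths: Mapping[str, str | Path],
                schema: Mapping | None = None) -> Dataset:
    """Load, cross-reference and validate the four tables.

    Parameters
    ----------
    paths
        Mapping with keys ``design``, ``community``, ``traits``,
        ``functions`` (file paths), or a single key ``dir`` pointing at a
        scenario directory written by :func:`mufunlab.synthetic_data.gen_scenario`.
    schema
        Mapping with ``trait_types`` (trait name -> kind) and optionally
        ``target_species``.  When a scenario directory is given, its
        ``schema.yaml`` supplies both.
    """
    paths = dict(paths)
    if "dir" in paths:
        d = Path(paths["dir"])
        paths = {k: d / f"{k}.csv"
                 for k in ("design", "community", "traits", "functions")}
        if schema is None and (d / "schema.yaml").exists():
            schema = yaml.safe_load((d / "schema.yaml").read_text())
    if schema is None:
        raise SchemaError("a schema (trait_types, target_species) is required")

    for key in ("design", "community", "traits", "functions"):
        if key not in paths:
            raise SchemaError(f"missing path for table '{key}'")
        if not Path(paths[key]).exists():
            raise FileNotFoundError(paths[key])

    targets = list(schema.get("target_species", []))
    design = read_design(paths["design"])
    community = read_community(paths["community"], target_species=targets)
    traits = read_traits(paths["traits"], schema["trait_types"])
    functions = read_functions(paths["functions"])

    report = validate_design(design)

    # reconcile species sets
    comm_sp = set(community.species)
    trait_sp = set(traits.species)
    orphans = sorted(comm_sp - trait_sp)
    if orphans:
        raise ReferentialError(
            f"species in community absent from trait table: {orphans}")
    unused = sorted(trait_sp - comm_sp)
    for sp in unused:
        report.warnings.append(f"species {sp} has traits but no captures")

    # reconcile sample ids
    known = set(design["sample_id"])
    stray = sorted(set(community.samples) - known)
    if stray:
        raise ReferentialError(f"community samples not in design: {stray[:5]}")
    stray_f = sorted(set(functions.obs["sample_id"]) - known)
    if stray_f:
        raise ReferentialError(f"function samples not in design: {stray_f[:5]}")

    # prefer explicit target flags from the trait table when present
    if traits.target_flags.any():
        flags = traits.target_flags.reindex(community.species).fillna(False)
        community = CommunityMatrix(community.counts, flags.astype(bool))

    ds = Dataset(design, community, traits, functions, report)
    logger.info("loaded dataset: %d samples, %d species, %d function rows",
                len(design), len(community.species), len(functions.obs))
    return ds


def write_tables(ds: Dataset, outdir: str | Path) -> dict[str, Path]:
    """Write the four tables back to CSV (inverse of :func:`load_tables`)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}

    files["design"] = out / "design.csv"
    ds.design.to_csv(files["design"], index=False)

    files["community"] = out / "community.csv"
    comm = ds.community.counts.copy()
    comm.insert(0, "sample_id", comm.index)
    comm.to_csv(files["community"], index=False)

    files["traits"] = out / "traits.csv"
    tr = ds.traits.traits.copy()
    tr.insert(0, "species", tr.index)
    tr.insert(1, "incidence", ds.traits.incidence)
    tr.insert(2, "is_target", ds.traits.target_flags.astype(bool))
    tr.to_csv(files["traits"], index=False)

    files["functions"] = out / "functions.csv"
    ds.functions.obs.to_csv(files["functions"], index=False)

    files["schema"] = out / "schema.yaml"
    schema = {
        "trait_types": ds.traits.trait_types,
        "target_species": sorted(
            ds.traits.target_flags.index[ds.traits.target_flags].tolist()),
    }
    files["schema"].write_text(yaml.safe_dump(schema, sort_keys=True))
    return files
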