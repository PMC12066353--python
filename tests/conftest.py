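import numpy as np
import pandas as pd
import pytest

from mufunlab import community_metrics as cm
from mufunlab import multifunctionality as mf
from mufunlab.core_io import TraitTable
from mufunlab.synthetic_data import ScenarioConfig, gen_dataset


@pytest.fixture(scope="session")
def default_cfg():
    return ScenarioConfig(seed=7)


@pytest.fixture(scope="session")
def dataset(default_cfg):
    """One default synthetic experiment shared across tests."""
    return gen_dataset(default_cfg)


@pytest.fixture(scope="session")
def std_rates(dataset):
    std, f_max, flags = mf.standardize(dataset.functions)
    return std


@pytest.fixture(scope="session")
def profiles(dataset):
    return cm.diversity_profile(dataset.community)


@pytest.fixture()
def tiny_traits():
    """Three species, one trait of each kind — hand-checkable Gower input."""
    df = pd.DataFrame(
        {"size": [1.0, 3.0, 2.0],
         "shiny": [0, 1, 0],
         "diet": ["x", "x", "y"]},
        index=pd.Index(["A", "B", "C"], name="species"))
    types = {"size": "continuous", "shiny": "binary", "diet": "categorical"}
    inc = pd.Series([0.9, 0.3, 0.5], index=df.index)
    flags = pd.Series(False, index=df.index)
    return TraitTable(df, types, inc, flags)


def make_binary_traits(rows: dict[str, list[int]]) -> TraitTable:
    df = pd.DataFrame(rows).T
    df.columns = [f"t{i}" for i in range(df.shape[1])]
    df.index.name = "species"
    types = {c: "binary" for c in df.columns}
    inc = pd.Series(0.5, index=df.index)
    return TraitTable(df, types, inc, pd.Series(False, index=df.index))
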