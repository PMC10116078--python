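import numpy as np
import pandas as pd
import pytest

from betascape.io import (
    DIET_COLS,
    FORAGE_COLS,
    TRAIT_COLS,
    CommunityTable,
    TraitTable,
)
from betascape.synthetic_data import SimulationConfig, simulate_dataset


def make_trait_table(values: dict[str, list[float]]) -> TraitTable:
    """Build a valid 20-trait table from per-species 20-vectors."""
    df = pd.DataFrame.from_dict(values, orient="index", columns=TRAIT_COLS)
    df.index.name = "species_id"
    return TraitTable(df.sort_index())


def toy_traits(n_species: int = 3) -> TraitTable:
    """Species differing only in two diet categories and body mass."""
    rows = {}
    for i in range(n_species):
        diet = [0.0] * 10
        diet[0] = 100.0 - 10.0 * i
        diet[1] = 10.0 * i
        forage = [100.0] + [0.0] * 7
        rows[f"sp{i + 1}"] = diet + forage + [100.0, 10.0 * (i + 1)]
    return make_trait_table(rows)


@pytest.fixture(scope="session")
def small_dataset():
    """A small but complete synthetic dataset shared across tests."""
    cfg = SimulationConfig(seed=11, n_units=40, n_species=25, n_trees=20)
    return cfg, simulate_dataset(cfg)


@pytest.fixture
def two_by_two() -> CommunityTable:
    ab = pd.DataFrame([[3, 1], [0, 2]], index=["c1", "c2"], columns=["spA", "spB"])
    ab.index.name = "community_id"
    return CommunityTable(
        abundance=ab,
        unit_of=pd.Series(["u1", "u1"], index=ab.index, name="unit_id"),
        unit_coords=pd.DataFrame({"x": [0.0], "y": [0.0]}, index=["u1"]),
    )
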