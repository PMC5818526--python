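"""Shared fixtures: small synthetic landscapes and pipeline runs."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from traitpd.io import Dataset
from traitpd.pipeline import PipelineConfig, analyse
from traitpd.simulate import SimulationConfig, generate_dataset
from traitpd.traits import TRAIT_NAMES


def small_config(seed: int = 0, **overrides) -> SimulationConfig:
    """A desk-sized scenario: fewer sites and species, same structure."""
    base = dict(
        seed=seed,
        sites_per_habitat={
            "forest": 4,
            "unmanaged_28yr": 2,
            "managed_7yr": 2,
            "managed_28yr": 2,
        },
        pool_size=40,
    )
    base.update(overrides)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def small_dataset():
    ds = generate_dataset(small_config(seed=7))
    return Dataset(
        traits=ds.traits,
        occurrences=ds.occurrences,
        sites=ds.sites.set_index("site_id"),
    )


@pytest.fixture(scope="session")
def small_result(small_dataset):
    cfg = PipelineConfig(seed=7, cells_per_dim=8, n_permutations=99)
    return analyse(small_dataset, cfg)


@pytest.fixture()
def trait_table():
    """Hand-sized individual trait table: 3 species, mixed sample sizes."""
    rng = np.random.default_rng(42)
    rows = []
    i = 0
    for sp, n in (("spA", 8), ("spB", 6), ("spC", 3)):
        base = rng.uniform(0.5, 1.5, len(TRAIT_NAMES))
        for _ in range(n):
            i += 1
            vals = base * np.exp(rng.normal(0, 0.05, len(TRAIT_NAMES)))
            row = {"individual_id": f"i{i}", "species_id": sp, "site_id": "s1"}
            row.update(dict(zip(TRAIT_NAMES, vals)))
            rows.append(row)
    return pd.DataFrame(rows)


def replace_config(cfg: SimulationConfig, **kw) -> SimulationConfig:
    return dataclasses.replace(cfg, **kw)
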