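"""Reading, validation and cross-referencing of the three input tables."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .traits import TRAIT_NAMES, validate_trait_table


class InputError(ValueError):
    """Raised for malformed or inconsistent input files."""


@dataclass
class Dataset:
    """Validated, cross-referenced in-memory inputs."""

    traits: pd.DataFrame
    occurrences: pd.DataFrame  # site x species counts, index = site_id
    sites: pd.DataFrame  # index = site_id; columns habitat, x, y


def read_traits(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path)
    try:
        return validate_trait_table(table)
    except ValueError as e:
        raise InputError(f"{path}: {e}") from e


def read_occurrences(path: str | Path) -> pd.DataFrame:
    occ = pd.read_csv(path)
    if occ.columns[0] != "site_id":
        raise InputError(f"{path}: first column must be 'site_id'")
    if occ["site_id"].duplicated().any():
        dups = occ.loc[occ["site_id"].duplicated(), "site_id"].tolist()
        raise InputError(f"{path}: duplicated site ids: {dups}")
    occ = occ.set_index("site_id")
    counts = occ.to_numpy()
    if not np.issubdtype(counts.dtype, np.number) or np.any(counts < 0):
        raise InputError(f"{path}: occurrence counts must be non-negative numbers")
    return occ


def read_sites(path: str | Path) -> pd.DataFrame:
    sites = pd.read_csv(path)
    required = ["site_id", "habitat", "x", "y"]
    missing = [c for c in required if c not in sites.columns]
    if missing:
        raise InputError(f"{path}: missing columns {missing}")
    if sites["site_id"].duplicated().any():
        dups = sites.loc[sites["site_id"].duplicated(), "site_id"].tolist()
        raise InputError(f"{path}: duplicated site ids: {dups}")
    return sites.set_index("site_id")


def read_inputs(
    traits_path: str | Path,
    occurrences_path: str | Path,
    sites_path: str | Path,
) -> Dataset:
    """Read and cross-reference the trait, occurrence and site tables.

    Every species occurring somewhere must have trait records; the site
    sets of the occurrence matrix and the metadata must match exactly.
    """
    traits = read_traits(traits_path)
    occ = read_occurrences(occurrences_path)
    sites = read_sites(sites_path)

    occ_sites = set(occ.index)
    meta_sites = set(sites.index)
    if occ_sites != meta_sites:
        raise InputError(
            f"site mismatch: only in occurrences {sorted(occ_sites - meta_sites)}, "
            f"only in site metadata {sorted(meta_sites - occ_sites)}"
        )
    occurring = set(occ.columns[(occ > 0).any(axis=0)])
    measured = set(traits["species_id"])
    orphans = sorted(occurring - measured)
    if orphans:
        raise InputError(
            f"species present in occurrences but absent from the trait table: {orphans}"
        )
    return Dataset(traits=traits, occurrences=occ, sites=sites)


def species_raw_trait_means(traits: pd.DataFrame) -> pd.DataFrame:
    """Species x trait matrix of raw-scale (mm) mean values."""
    return traits.groupby("species_id")[list(TRAIT_NAMES)].mean()
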