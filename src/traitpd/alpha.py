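"""Per-site (alpha) taxonomic and functional diversity indices.

Taxonomic alpha diversity is species richness. Functional indices are
computed from trait probability distributions:

* CWM — community-weighted mean of each raw trait (mm scale), weights =
  relative occurrence frequencies;
* FRic — functional richness, the trait-space volume occupied by the
  community (number of cells where the community TPD is positive times
  the cell volume; species TPDs are trimmed to their high-density region
  before mixing, so this is the community's occupied HDR volume);
* FRed — functional redundancy, the TPDc-weighted mean number of species
  overlapping each occupied cell, minus one (0 = no redundancy);
* Rao's Q — quadratic entropy, the expected pairwise dissimilarity
  (1 - TPD overlap) between two randomly drawn community members.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .tpd import CommunityTPD, SpeciesTPD, TraitGrid, _check_same_grid, tpd_overlap


def species_richness(counts: np.ndarray) -> int:
    """Number of species with a positive occurrence count."""
    counts = np.asarray(counts)
    if np.any(counts < 0):
        raise ValueError("occurrence counts must be non-negative")
    return int(np.count_nonzero(counts > 0))


def community_weighted_mean(
    species_trait_means: pd.DataFrame, weights: pd.Series
) -> pd.Series:
    """Occurrence-weighted mean trait values of a community (raw mm scale).

    ``species_trait_means`` is a species x trait table of raw-scale means;
    ``weights`` maps species ids to occurrence counts or frequencies for
    the species present at the site.
    """
    weights = weights[weights > 0]
    missing = [s for s in weights.index if s not in species_trait_means.index]
    if missing:
        raise KeyError(f"species present at site but absent from trait table: {missing}")
    w = weights / weights.sum()
    sub = species_trait_means.loc[w.index]
    return sub.mul(w, axis=0).sum(axis=0)


def functional_richness(tpdc: CommunityTPD) -> float:
    """Occupied trait-space volume: support cell count x cell volume."""
    n_support = int(np.count_nonzero(tpdc.probabilities > 0))
    if n_support == 0:
        raise ValueError(f"community {tpdc.site_id!r} has an empty TPD support")
    return n_support * tpdc.grid.cell_volume


def functional_redundancy(tpdc: CommunityTPD, tpds: list[SpeciesTPD]) -> float:
    """Mean species-overlap depth of the community, minus one.

    With M(cell) = number of contributing species whose trimmed TPD is
    positive at the cell, FRed = sum_cells TPDc(cell) * M(cell) - 1.
    A single-species community (M = 1 everywhere it matters) scores 0;
    n fully redundant species score n - 1.
    """
    if not tpds:
        raise ValueError("community has no contributing species")
    _check_same_grid(tpdc, *tpds)
    m = np.zeros(tpdc.grid.n_cells)
    for t in tpds:
        m += t.support
    return float(np.sum(tpdc.probabilities * m) - 1.0)


def rao_q(tpds: list[SpeciesTPD], weights: np.ndarray) -> float:
    """Rao's quadratic entropy from pairwise TPD dissimilarities.

    d_ij = 1 - overlap(TPD_i, TPD_j), d_ii = 0;
    Q = sum_ij w_i w_j d_ij with weights renormalized to sum to 1.
    Bounded above by 1 - sum(w^2) (attained when all pairs are disjoint).
    """
    if not tpds:
        raise ValueError("community has no species TPDs")
    w = np.asarray(weights, float)
    if w.shape != (len(tpds),):
        raise ValueError("one weight per species TPD is required")
    w = w / w.sum()
    n = len(tpds)
    q = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            d = 1.0 - tpd_overlap(tpds[i], tpds[j])
            q += 2.0 * w[i] * w[j] * d
    return q


def pairwise_dissimilarity(tpds: list[SpeciesTPD]) -> np.ndarray:
    """Symmetric matrix of 1 - overlap between species TPDs (zero diagonal)."""
    n = len(tpds)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = 1.0 - tpd_overlap(tpds[i], tpds[j])
    return d


def rao_q_from_dissimilarity(d: np.ndarray, weights: np.ndarray) -> float:
    """Rao's Q from a precomputed dissimilarity matrix (weights renormalized)."""
    w = np.asarray(weights, float)
    w = w / w.sum()
    return float(w @ d @ w)


def alpha_table(
    occurrences: pd.DataFrame,
    habitats: pd.Series,
    species_trait_means: pd.DataFrame,
    tpds_by_species: dict[str, SpeciesTPD],
    tpdcs_by_site: dict[str, CommunityTPD],
    species_dissimilarity: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Assemble the per-site alpha-diversity table.

    ``occurrences`` is the site x species count matrix; ``habitats`` maps
    site ids to habitat classes. Returns one row per site with richness,
    the eight CWM columns (mm), FRic, FRed and Rao's Q. A precomputed
    species x species TPD dissimilarity matrix avoids recomputing the
    pairwise overlaps at every site.
    """
    rows = []
    for site in occurrences.index:
        counts = occurrences.loc[site]
        present = counts[counts > 0]
        tpdc = tpdcs_by_site[site]
        tpds = [tpds_by_species[s] for s in present.index]
        cwm = community_weighted_mean(species_trait_means, present)
        row = {
            "site_id": site,
            "habitat": habitats[site],
            "richness": species_richness(counts.to_numpy()),
        }
        row.update({f"cwm_{t}": cwm[t] for t in species_trait_means.columns})
        row["fric"] = functional_richness(tpdc)
        row["fred"] = functional_redundancy(tpdc, tpds)
        if species_dissimilarity is not None:
            d = species_dissimilarity.loc[present.index, present.index].to_numpy()
            row["rao_q"] = rao_q_from_dissimilarity(d, present.to_numpy(float))
        else:
            row["rao_q"] = rao_q(tpds, present.to_numpy(float))
        rows.append(row)
    return pd.DataFrame(rows)
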