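"""Self-validation studies: analytic oracles and ground-truth recovery.

These routines exercise the package against quantities that are known in
closed form (high-density-region volumes, Gaussian overlap integrals,
hand-computable PERMANOVA sums of squares, the Moran's I permutation
null) and against the synthetic generator's ground truth (habitat
filtering must be recovered as the expected diversity ordering, and a
null landscape must yield nominal type-I error rates). They back both
the test suite and the reproduction script.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy import stats

from .alpha import alpha_table, functional_richness, pairwise_dissimilarity, rao_q
from .beta import taxonomic_beta
from .inference import compare_groups, morans_i, permanova
from .io import Dataset, species_raw_trait_means
from .simulate import SimulationConfig, generate_dataset
from .tpd import TraitGrid, build_grid, community_tpd, species_tpd, tpd_overlap
from .traits import (
    fit_trait_pca,
    project_individuals,
    species_mean_matrix,
    standardize_traits,
    summarize_species,
)


def analytic_fric_2d(cells_per_dim: int = 200, trim_mass: float = 0.99) -> dict:
    """FRic of one isotropic 2-D unit Gaussian vs its analytic HDR area.

    The trim_mass high-density region of N(0, I_2) is a disc of area
    pi * chi2_2(trim_mass).
    """
    grid = TraitGrid(lower=(-5.0, -5.0), upper=(5.0, 5.0), cells_per_dim=cells_per_dim)
    t = species_tpd("sp", [0.0, 0.0], [1.0, 1.0], grid, trim_mass=trim_mass)
    c = community_tpd("site", [t], np.array([1.0]))
    return {
        "value": functional_richness(c),
        "target": float(np.pi * stats.chi2.ppf(trim_mass, 2)),
        "n": grid.n_cells,
    }


def analytic_overlap_1d(cells_per_dim: int = 1600) -> dict:
    """Overlap and Rao's Q of two unit Gaussians two SDs apart.

    The densities cross at the midpoint, so overlap = 2 * Phi(-1); for an
    equal-weight pair Q = 0.5 * (1 - overlap).
    """
    grid = TraitGrid(lower=(-7.0,), upper=(9.0,), cells_per_dim=cells_per_dim)
    a = species_tpd("a", [0.0], [1.0], grid, trim_mass=1.0)
    b = species_tpd("b", [2.0], [1.0], grid, trim_mass=1.0)
    ov = tpd_overlap(a, b)
    q = rao_q([a, b], np.array([0.5, 0.5]))
    return {
        "overlap": ov,
        "overlap_target": float(2 * stats.norm.cdf(-1)),
        "rao_q": q,
        "rao_q_target": float(0.5 * (1 - 2 * stats.norm.cdf(-1))),
        "n": cells_per_dim,
    }


def permanova_four_point() -> dict:
    """Hand-computable PERMANOVA: 4 points, all pairwise distances 1.

    SS_total = 6/4, SS_within = 1, so F = 1 for every labelling and the
    permutation p is exactly 1.
    """
    d = 1.0 - np.eye(4)
    res = permanova(d, np.array(["a", "a", "b", "b"]), n_perm=99, seed=0)
    return {"F": res.observed, "p": res.p, "n": 4}


def permanova_type_i_error(
    n_datasets: int = 1000, n_perm: int = 999, n_sites: int = 12, seed: int = 0
) -> dict:
    """Rejection rate of PERMANOVA at alpha = 0.05 under an exchangeable null."""
    rng = np.random.default_rng(seed)
    labels = np.repeat(["a", "b"], n_sites // 2)
    rejections = 0
    for k in range(n_datasets):
        pts = rng.normal(size=(n_sites, 3))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        res = permanova(d, labels, n_perm=n_perm, seed=int(rng.integers(2**31)))
        rejections += res.p <= 0.05
    return {"rate": rejections / n_datasets, "n": n_datasets}


def moran_null(n_sites: int = 25, n_perm: int = 10_000, seed: int = 0) -> dict:
    """Mean of the Moran's I permutation null vs the analytic -1/(n-1)."""
    rng = np.random.default_rng(seed)
    coords = rng.uniform(0, 1000, (n_sites, 2))
    values = rng.normal(size=n_sites)
    res = morans_i(values, coords, n_perm=n_perm, seed=seed)
    return {
        "null_mean": res.null_mean,
        "target": -1.0 / (n_sites - 1),
        "n": n_perm,
    }


def _alpha_core(dataset: Dataset, cells_per_dim: int) -> pd.DataFrame:
    """Minimal trait-space -> TPD -> alpha computation for studies."""
    standardized, constants = standardize_traits(dataset.traits)
    means = species_mean_matrix(standardized)
    model = fit_trait_pca(means, constants)
    coords = project_individuals(model, standardized, constants)
    summaries = summarize_species(coords)
    grid = build_grid(coords[model.axis_names()].to_numpy(), cells_per_dim=cells_per_dim)
    tpds = {
        s.species_id: species_tpd(s.species_id, s.axis_means, s.axis_sds, grid)
        for s in summaries
    }
    occ = dataset.occurrences
    tpdcs = {
        site: community_tpd(
            site,
            [tpds[s] for s in occ.columns[occ.loc[site] > 0]],
            occ.loc[site][occ.loc[site] > 0].to_numpy(float),
        )
        for site in occ.index
    }
    order = sorted(tpds)
    dmat = pd.DataFrame(
        pairwise_dissimilarity([tpds[s] for s in order]), index=order, columns=order
    )
    return alpha_table(
        occ,
        dataset.sites["habitat"],
        species_raw_trait_means(dataset.traits),
        tpds,
        tpdcs,
        dmat,
    )


def _as_dataset(sim) -> Dataset:
    return Dataset(
        traits=sim.traits,
        occurrences=sim.occurrences,
        sites=sim.sites.set_index("site_id"),
    )


def homogenization_recovery(
    n_seeds: int = 50,
    cells_per_dim: int = 10,
    n_perm: int = 499,
    seed0: int = 0,
) -> dict:
    """Ground-truth recovery on the default homogenization scenario.

    For each replicate landscape, checks that (a) mean forest FRic exceeds
    every plantation class's mean FRic, (b) mean forest-plantation
    taxonomic Sorensen dissimilarity exceeds the mean within-plantation
    dissimilarity, and (c) PERMANOVA detects the habitat effect on total
    taxonomic beta diversity at alpha = 0.05. Returns the fraction of
    replicates satisfying each.
    """
    ok_fric = ok_beta = ok_perm = 0
    for k in range(n_seeds):
        sim = generate_dataset(SimulationConfig(seed=seed0 + k))
        dataset = _as_dataset(sim)
        alpha = _alpha_core(dataset, cells_per_dim)
        fric = alpha.groupby("habitat")["fric"].mean()
        plantations = [h for h in fric.index if h != "forest"]
        ok_fric += all(fric["forest"] > fric[h] for h in plantations)

        mats = taxonomic_beta(dataset.occurrences)
        labels = dataset.sites.loc[list(mats.site_ids), "habitat"].to_numpy()
        plantation = labels != "forest"
        within_p, between = [], []
        for i, j in itertools.combinations(range(len(labels)), 2):
            if plantation[i] and plantation[j]:
                within_p.append(mats.total[i, j])
            elif plantation[i] != plantation[j]:
                between.append(mats.total[i, j])
        ok_beta += float(np.mean(between)) > float(np.mean(within_p))

        res = permanova(mats.total, labels, n_perm=n_perm, seed=seed0 + k)
        ok_perm += res.p <= 0.05
    return {
        "fric_fraction": ok_fric / n_seeds,
        "beta_fraction": ok_beta / n_seeds,
        "permanova_fraction": ok_perm / n_seeds,
        "n": n_seeds,
    }


def null_calibration(
    n_reps: int = 300, cells_per_dim: int = 8, seed0: int = 10_000
) -> dict:
    """Type-I error of the habitat comparisons on null landscapes.

    With all habitat filters equalized there is no habitat effect, so the
    gated group comparison of each alpha index should reject at ~5%.
    """
    indices = ("richness", "fric", "rao_q")
    rejections = dict.fromkeys(indices, 0)
    for k in range(n_reps):
        cfg = SimulationConfig(seed=seed0 + k).null_scenario()
        sim = generate_dataset(cfg)
        alpha = _alpha_core(_as_dataset(sim), cells_per_dim)
        groups = alpha["habitat"].to_numpy()
        for idx in indices:
            res = compare_groups(alpha[idx].to_numpy(), groups, index_name=idx)
            rejections[idx] += res.p < 0.05
    return {f"{idx}_rate": rejections[idx] / n_reps for idx in indices} | {"n": n_reps}
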