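"""End-to-end analysis pipeline and run manifest.

``run_pipeline`` wires the stages together: standardization ->
ordination -> TPD construction -> alpha indices -> beta partitions ->
group tests, PERMANOVA and spatial checks -> CSV outputs plus a JSON
manifest sufficient to reproduce the run bit-for-bit.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .alpha import alpha_table, pairwise_dissimilarity
from .beta import BetaMatrices, bray_curtis, functional_beta, taxonomic_beta
from .inference import compare_groups, mantel, morans_i, permanova
from .io import Dataset, read_inputs, species_raw_trait_means
from .tpd import build_grid, community_tpd, species_tpd
from .traits import (
    TRAIT_NAMES,
    fit_trait_pca,
    project_individuals,
    species_mean_matrix,
    standardize_traits,
    summaries_to_frame,
    summarize_species,
)

log = logging.getLogger("traitpd")

#: Identifier of the functional-redundancy formula in use (manifest field).
FRED_FORMULA = "mean_overlap_depth_minus_one"


@dataclass
class PipelineConfig:
    """All analysis knobs, echoed verbatim into the run manifest."""

    seed: int = 0
    retained_axes: int = 4
    cells_per_dim: int = 15
    buffer_fraction: float = 0.05
    trim_mass: float = 0.99
    beta_mode: str = "volume"  # functional beta: "volume" | "overlap"
    n_permutations: int = 9999
    alpha_level: float = 0.05
    include_timings: bool = False  # wall-clock in manifest breaks determinism

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "retained_axes": self.retained_axes,
            "cells_per_dim": self.cells_per_dim,
            "buffer_fraction": self.buffer_fraction,
            "trim_mass": self.trim_mass,
            "beta_mode": self.beta_mode,
            "n_permutations": self.n_permutations,
            "alpha_level": self.alpha_level,
        }


@dataclass
class PipelineResult:
    """In-memory results of one pipeline run."""

    alpha: pd.DataFrame
    taxonomic_beta: BetaMatrices
    functional_beta: BetaMatrices
    bray_curtis: pd.DataFrame
    tests: pd.DataFrame
    permanova_table: pd.DataFrame
    spatial: pd.DataFrame
    manifest: dict
    species_summaries: pd.DataFrame
    ordination: object = field(repr=False, default=None)


def _write_ordination_model(model, path: Path) -> None:
    """Plain-text key/value + matrix dump of the ordination for provenance."""
    lines = [
        f"retained_axes: {model.retained_axes}",
        f"fingerprint: {model.fingerprint}",
        "explained_fraction: " + " ".join(f"{v:.12g}" for v in model.explained_fraction),
        "center: " + " ".join(f"{v:.12g}" for v in model.center),
        "scale: " + " ".join(f"{v:.12g}" for v in model.scale),
        "loadings:",
    ]
    for row in model.loadings:
        lines.append("  " + " ".join(f"{v: .12g}" for v in row))
    path.write_text("\n".join(lines) + "\n")


def analyse(dataset: Dataset, config: PipelineConfig) -> PipelineResult:
    """Run the full analysis on an in-memory dataset."""
    timings: dict[str, float] = {}

    def tick(stage: str, t0: float) -> None:
        timings[stage] = time.perf_counter() - t0
        log.info("stage %s finished in %.2fs", stage, timings[stage])

    t0 = time.perf_counter()
    standardized, constants = standardize_traits(dataset.traits)
    species_means = species_mean_matrix(standardized)
    model = fit_trait_pca(species_means, constants, retained_axes=config.retained_axes)
    coords = project_individuals(model, standardized, constants)
    summaries = summarize_species(coords)
    tick("trait_space", t0)

    t0 = time.perf_counter()
    axis_cols = model.axis_names()
    grid = build_grid(
        coords[axis_cols].to_numpy(),
        cells_per_dim=config.cells_per_dim,
        buffer_fraction=config.buffer_fraction,
    )
    tpds = {
        s.species_id: species_tpd(
            s.species_id, s.axis_means, s.axis_sds, grid, trim_mass=config.trim_mass
        )
        for s in summaries
    }
    occ = dataset.occurrences
    tpdcs = {}
    for site in occ.index:
        present = occ.loc[site][occ.loc[site] > 0]
        tpdcs[site] = community_tpd(
            site, [tpds[s] for s in present.index], present.to_numpy(float)
        )
    tick("tpd", t0)

    t0 = time.perf_counter()
    species_order = sorted(tpds)
    dmat = pd.DataFrame(
        pairwise_dissimilarity([tpds[s] for s in species_order]),
        index=species_order,
        columns=species_order,
    )
    habitats = dataset.sites["habitat"]
    raw_means = species_raw_trait_means(dataset.traits)
    alpha = alpha_table(occ, habitats, raw_means, tpds, tpdcs, dmat)
    tick("alpha", t0)

    t0 = time.perf_counter()
    tax_beta = taxonomic_beta(occ)
    fun_beta = functional_beta([tpdcs[s] for s in occ.index], mode=config.beta_mode)
    bc = bray_curtis(occ)
    tick("beta", t0)

    t0 = time.perf_counter()
    index_cols = ["richness", "fric", "fred", "rao_q"] + [
        f"cwm_{t}" for t in TRAIT_NAMES
    ]
    group_labels = alpha["habitat"].to_numpy()
    test_rows = []
    for idx in index_cols:
        res = compare_groups(
            alpha[idx].to_numpy(), group_labels, index_name=idx, alpha=config.alpha_level
        )
        row = {
            "index": idx,
            "method": res.method,
            "statistic": res.statistic,
            "p": res.p,
            "shapiro_p": res.shapiro_p,
        }
        row.update({f"letters_{g}": l for g, l in res.letters.items()})
        test_rows.append(row)
    tests = pd.DataFrame(test_rows)

    perm_rows = []
    for flavor, mats in (("taxonomic", tax_beta), ("functional", fun_beta)):
        for comp, label in (("total", "All"), ("turnover", "turnover"), ("nested", "nested")):
            res = permanova(
                mats.component(comp),
                group_labels,
                n_perm=config.n_permutations,
                seed=config.seed,
            )
            perm_rows.append(
                {
                    "flavor": flavor,
                    "component": label,
                    "F": res.observed,
                    "R2": res.r_squared,
                    "p": res.p,
                }
            )
    permanova_table = pd.DataFrame(perm_rows)

    xy = dataset.sites.loc[occ.index, ["x", "y"]].to_numpy(float)
    spatial_rows = []
    for idx in ["richness", "fric", "fred", "rao_q"]:
        res = morans_i(
            alpha[idx].to_numpy(), xy, n_perm=config.n_permutations, seed=config.seed
        )
        spatial_rows.append(
            {"test": "morans_i", "variable": idx, "statistic": res.observed, "p": res.p}
        )
    spatial_dist = np.sqrt(((xy[:, None, :] - xy[None, :, :]) ** 2).sum(axis=2))
    mres = mantel(bc.to_numpy(), spatial_dist, n_perm=config.n_permutations, seed=config.seed)
    spatial_rows.append(
        {
            "test": "mantel",
            "variable": "bray_curtis~space",
            "statistic": mres.observed,
            "p": mres.p,
        }
    )
    spatial = pd.DataFrame(spatial_rows)
    tick("inference", t0)

    manifest = {
        "traitpd_version": __version__,
        "config": config.to_dict(),
        "grid": {
            "dims": grid.dims,
            "cells_per_dim": grid.cells_per_dim,
            "lower": [float(v) for v in grid.lower],
            "upper": [float(v) for v in grid.upper],
            "cell_volume": grid.cell_volume,
        },
        "design_settings": {
            "fred_formula": FRED_FORMULA,
            "functional_beta_mode": config.beta_mode,
            "trim_mass": config.trim_mass,
            "sd_imputation_threshold": 6,
        },
        "data_shape": {
            "n_sites": int(len(occ)),
            "n_species_occurring": int((occ > 0).any(axis=0).sum()),
            "n_individuals": int(len(dataset.traits)),
        },
        "pca_explained_fraction": [float(v) for v in model.explained_fraction],
        "scaling_fingerprint": model.fingerprint,
    }
    if config.include_timings:
        manifest["timings_s"] = {k: round(v, 3) for k, v in timings.items()}

    return PipelineResult(
        alpha=alpha,
        taxonomic_beta=tax_beta,
        functional_beta=fun_beta,
        bray_curtis=bc,
        tests=tests,
        permanova_table=permanova_table,
        spatial=spatial,
        manifest=manifest,
        species_summaries=summaries_to_frame(summaries),
        ordination=model,
    )


def _beta_long(mats: BetaMatrices) -> pd.DataFrame:
    ids = mats.site_ids
    rows = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            rows.append(
                {
                    "site_a": ids[i],
                    "site_b": ids[j],
                    "flavor": mats.flavor,
                    "total": mats.total[i, j],
                    "turnover": mats.turnover[i, j],
                    "nested": mats.nested[i, j],
                }
            )
    return pd.DataFrame(rows)


def write_outputs(
    dataset: Dataset, result: PipelineResult, out_dir: str | Path, config: PipelineConfig
) -> Path:
    """Write every declared output file of a run into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    standardized, _ = standardize_traits(dataset.traits)
    standardized.to_csv(out / "standardized_traits.csv", index=False)
    _write_ordination_model(result.ordination, out / "ordination_model.txt")
    result.species_summaries.to_csv(out / "species_summary.csv", index=False)
    result.alpha.to_csv(out / "alpha.csv", index=False)
    for mats in (result.taxonomic_beta, result.functional_beta):
        for comp, frame in mats.to_frames().items():
            frame.to_csv(out / f"{mats.flavor}_{comp}.csv")
    pd.concat(
        [_beta_long(result.taxonomic_beta), _beta_long(result.functional_beta)]
    ).to_csv(out / "beta_pairs.csv", index=False)
    result.bray_curtis.to_csv(out / "bray_curtis.csv")
    result.tests.to_csv(out / "tests.csv", index=False)
    result.permanova_table.to_csv(out / "permanova.csv", index=False)
    result.spatial.to_csv(out / "spatial.csv", index=False)
    (out / "manifest.json").write_text(
        json.dumps(result.manifest, indent=2, sort_keys=True) + "\n"
    )
    return out


def run_pipeline(
    traits_csv: str | Path,
    occurrences_csv: str | Path,
    sites_csv: str | Path,
    out_dir: str | Path,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Read the three input CSVs, run the analysis, write all outputs."""
    config = config or PipelineConfig()
    dataset = read_inputs(traits_csv, occurrences_csv, sites_csv)
    log.info(
        "inputs: %d individuals, occurrence matrix %s, %d sites",
        len(dataset.traits),
        dataset.occurrences.shape,
        len(dataset.sites),
    )
    result = analyse(dataset, config)
    write_outputs(dataset, result, out_dir, config)
    return result
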