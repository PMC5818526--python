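"""Trait standardization and ordination.

Raw morphological measurements (lengths in mm) are turned into a
low-dimensional functional space in three steps:

1. allometric standardization — every trait except Weber's length (the
   body-size proxy) is divided by Weber's length, then all traits are
   log-transformed and z-scored;
2. a PCA fitted on *species mean* trait vectors (so heavily sampled
   species do not dominate the axes), of which the first ``retained_axes``
   axes define the functional space;
3. projection of every measured individual into that space, followed by
   per-species summaries (axis means and standard deviations) that
   parameterize the species' trait probability distributions.

Species with fewer than six measured individuals borrow the average
standard deviation of the well-sampled species (the donor pool); the
``sd_imputed`` flag records this.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Canonical trait column order (all lengths in mm).
TRAIT_NAMES: tuple[str, ...] = (
    "head_width",
    "scape_length",
    "eye_mandible_distance",
    "eye_length",
    "interocular_distance",
    "webers_length",
    "leg_length",
    "petiole_length",
)

#: Body-size denominator for allometric standardization.
SIZE_TRAIT = "webers_length"

ID_COLUMNS = ("individual_id", "species_id", "site_id")

#: Minimum number of measured individuals for a species to estimate its own
#: axis standard deviations; below this the donor-pool average is imputed.
MIN_INDIVIDUALS_FOR_SD = 6


class TraitTableError(ValueError):
    """Raised for structurally invalid trait tables."""


def validate_trait_table(table: pd.DataFrame) -> pd.DataFrame:
    """Validate an individual-level trait table.

    Expects columns ``individual_id, species_id, site_id`` plus the eight
    trait columns of :data:`TRAIT_NAMES`. Rows with missing or non-positive
    trait values are rejected (lengths must be > 0 mm).
    """
    missing = [c for c in (*ID_COLUMNS, *TRAIT_NAMES) if c not in table.columns]
    if missing:
        raise TraitTableError(f"trait table is missing columns: {missing}")
    values = table[list(TRAIT_NAMES)]
    if values.isna().any().any():
        bad = table.loc[values.isna().any(axis=1), "individual_id"].tolist()
        raise TraitTableError(f"records with missing trait values: {bad}")
    nonpos = ~(values > 0).all(axis=1)
    if nonpos.any():
        bad = table.loc[nonpos, "individual_id"].tolist()
        raise TraitTableError(f"records with non-positive trait values: {bad}")
    if table["individual_id"].duplicated().any():
        dups = table.loc[table["individual_id"].duplicated(), "individual_id"]
        raise TraitTableError(f"duplicated individual ids: {dups.tolist()}")
    return table


def _log_ratio(table: pd.DataFrame) -> pd.DataFrame:
    """log(trait / Weber's length) per trait; log(Weber's length) itself."""
    out = table[list(ID_COLUMNS)].copy()
    weber = table[SIZE_TRAIT].to_numpy(float)
    for name in TRAIT_NAMES:
        x = table[name].to_numpy(float)
        out[name] = np.log(x) if name == SIZE_TRAIT else np.log(x / weber)
    return out


@dataclass(frozen=True)
class ScalingConstants:
    """Per-trait centering/scaling constants on the log-ratio scale.

    The constants are estimated from *species means* (the matrix the PCA
    consumes) and then applied unchanged to individuals, so species scores
    and individual projections live in the same space.
    """

    center: np.ndarray
    scale: np.ndarray

    @property
    def fingerprint(self) -> str:
        h = hashlib.sha256()
        h.update(np.round(self.center, 12).tobytes())
        h.update(np.round(self.scale, 12).tobytes())
        return h.hexdigest()[:16]


def standardize_traits(
    table: pd.DataFrame,
    constants: ScalingConstants | None = None,
) -> tuple[pd.DataFrame, ScalingConstants]:
    """Allometric + log + z standardization of an individual trait table.

    Every trait except Weber's length is divided by Weber's length; all
    traits are then log-transformed and z-scored. Unless ``constants`` is
    given, z-scoring constants (mean, sample SD) are computed from the
    per-species means of the log-ratio values and reused for individuals.

    Returns the standardized table (same id columns, dimensionless trait
    columns) and the scaling constants used.
    """
    table = validate_trait_table(table)
    logratio = _log_ratio(table)
    if constants is None:
        species_means = logratio.groupby("species_id")[list(TRAIT_NAMES)].mean()
        center = species_means.mean(axis=0).to_numpy(float)
        scale = species_means.std(axis=0, ddof=1).to_numpy(float)
        if np.any(~np.isfinite(scale)) or np.any(scale <= 0):
            raise TraitTableError(
                "cannot z-score: at least one trait has zero variance across species"
            )
        constants = ScalingConstants(center=center, scale=scale)
    out = logratio.copy()
    vals = logratio[list(TRAIT_NAMES)].to_numpy(float)
    out[list(TRAIT_NAMES)] = (vals - constants.center) / constants.scale
    return out, constants


def species_mean_matrix(standardized: pd.DataFrame) -> pd.DataFrame:
    """Species x trait matrix of mean standardized values, sorted by id."""
    return (
        standardized.groupby("species_id")[list(TRAIT_NAMES)].mean().sort_index()
    )


@dataclass
class OrdinationModel:
    """PCA of standardized species mean traits.

    ``loadings`` is the full 8 x 8 orthonormal rotation; projections use
    only the first ``retained_axes`` columns. ``explained_fraction`` holds
    the per-axis variance fractions over all 8 axes (non-increasing,
    summing to 1). ``center``/``scale`` echo the z-scoring constants so a
    model can refuse data standardized differently (``fingerprint``).
    """

    center: np.ndarray
    scale: np.ndarray
    loadings: np.ndarray
    explained_fraction: np.ndarray
    retained_axes: int
    fingerprint: str
    species_scores: pd.DataFrame = field(repr=False, default=None)

    def axis_names(self) -> list[str]:
        return [f"axis{i + 1}" for i in range(self.retained_axes)]


def fit_trait_pca(
    species_means: pd.DataFrame,
    constants: ScalingConstants,
    retained_axes: int = 4,
    cumulative_variance: float | None = None,
) -> OrdinationModel:
    """Fit a PCA on the species x trait matrix of standardized means.

    Parameters
    ----------
    species_means:
        Species x 8 matrix of standardized mean trait values (index =
        species_id), as produced by :func:`species_mean_matrix`.
    constants:
        The scaling constants used to standardize; stored for provenance
        and fingerprint checks at projection time.
    retained_axes:
        Number of PCA axes kept for the functional space (default 4).
    cumulative_variance:
        If given, overrides ``retained_axes`` with the smallest number of
        axes whose cumulative explained fraction reaches this threshold.

    Loading signs are fixed so the largest-magnitude entry of each column
    is positive, making the rotation deterministic.
    """
    X = species_means[list(TRAIT_NAMES)].to_numpy(float)
    n, p = X.shape
    if n < 2:
        raise ValueError("PCA requires at least 2 species")
    Xc = X - X.mean(axis=0)
    if np.allclose(Xc, 0):
        raise ValueError("PCA input matrix has zero variance")
    # full_matrices gives the complete 8x8 orthonormal basis even at rank < 8
    _, s, vt = np.linalg.svd(Xc, full_matrices=True)
    var = np.zeros(p)
    var[: len(s)] = s**2
    explained = var / var.sum()
    loadings = vt.T
    # deterministic sign: largest-|loading| entry of each column positive
    for j in range(p):
        k = np.argmax(np.abs(loadings[:, j]))
        if loadings[k, j] < 0:
            loadings[:, j] = -loadings[:, j]
    if cumulative_variance is not None:
        retained_axes = int(np.searchsorted(np.cumsum(explained), cumulative_variance) + 1)
    retained_axes = min(retained_axes, p)
    scores = Xc @ loadings[:, :retained_axes] + X.mean(axis=0) @ loadings[:, :retained_axes]
    # scores are computed from uncentered X so projection of raw standardized
    # vectors (below) reproduces them without re-centering
    species_scores = pd.DataFrame(
        scores,
        index=species_means.index,
        columns=[f"axis{i + 1}" for i in range(retained_axes)],
    )
    return OrdinationModel(
        center=constants.center.copy(),
        scale=constants.scale.copy(),
        loadings=loadings,
        explained_fraction=explained,
        retained_axes=retained_axes,
        fingerprint=constants.fingerprint,
        species_scores=species_scores,
    )


def project_individuals(
    model: OrdinationModel,
    standardized: pd.DataFrame,
    constants: ScalingConstants,
) -> pd.DataFrame:
    """Project standardized individuals onto the retained PCA axes.

    ``constants`` must be the same object (by fingerprint) used when the
    model was fitted; a mismatch means the individuals live in a different
    standardized space and projection would be meaningless.
    """
    if constants.fingerprint != model.fingerprint:
        raise ValueError(
            "scaling-constant mismatch: individuals were standardized with "
            "different constants than the ordination model"
        )
    X = standardized[list(TRAIT_NAMES)].to_numpy(float)
    coords = X @ model.loadings[:, : model.retained_axes]
    out = standardized[list(ID_COLUMNS)].copy()
    for i in range(model.retained_axes):
        out[f"axis{i + 1}"] = coords[:, i]
    return out


@dataclass(frozen=True)
class SpeciesTraitSummary:
    """Per-species functional-space summary used to build its TPD."""

    species_id: str
    n_individuals: int
    axis_means: np.ndarray
    axis_sds: np.ndarray
    sd_imputed: bool


def summarize_species(coords: pd.DataFrame) -> list[SpeciesTraitSummary]:
    """Per-species axis means and SDs, with the six-individual rule.

    Species with at least :data:`MIN_INDIVIDUALS_FOR_SD` measured
    individuals get sample SDs from their own individuals; species below
    the threshold receive, on every axis, the arithmetic mean of the SDs
    of all well-sampled species (``sd_imputed=True``). Raises if no
    species reaches the threshold, because the donor pool would be empty.
    """
    axis_cols = [c for c in coords.columns if c.startswith("axis")]
    if not axis_cols:
        raise ValueError("coords has no axis columns")
    grouped = coords.groupby("species_id")[axis_cols]
    means = grouped.mean()
    sds = grouped.std(ddof=1)
    counts = grouped.size()
    donors = counts[counts >= MIN_INDIVIDUALS_FOR_SD].index
    if len(donors) == 0:
        raise ValueError(
            f"no species has >= {MIN_INDIVIDUALS_FOR_SD} measured individuals: "
            "the SD-imputation donor pool is empty"
        )
    donor_sd = sds.loc[donors].mean(axis=0).to_numpy(float)
    out: list[SpeciesTraitSummary] = []
    for sp in means.index:
        n = int(counts[sp])
        imputed = n < MIN_INDIVIDUALS_FOR_SD
        sd = donor_sd.copy() if imputed else sds.loc[sp].to_numpy(float)
        out.append(
            SpeciesTraitSummary(
                species_id=sp,
                n_individuals=n,
                axis_means=means.loc[sp].to_numpy(float),
                axis_sds=sd,
                sd_imputed=imputed,
            )
        )
    return out


def summaries_to_frame(summaries: list[SpeciesTraitSummary]) -> pd.DataFrame:
    """Flatten summaries to the species-summary CSV layout."""
    k = len(summaries[0].axis_means)
    rows = []
    for s in summaries:
        row = {"species_id": s.species_id, "n_individuals": s.n_individuals}
        for i in range(k):
            row[f"mean_axis{i + 1}"] = s.axis_means[i]
        for i in range(k):
            row[f"sd_axis{i + 1}"] = s.axis_sds[i]
        row["sd_imputed"] = s.sd_imputed
        rows.append(row)
    return pd.DataFrame(rows)
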