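"""Trait probability distributions on a discretized trait-space grid.

A species' trait probability distribution (TPDs) is a multivariate
Gaussian (diagonal covariance, parameterized by the species' axis means
and SDs) evaluated at the centers of a regular grid over the retained
ordination axes, normalized, and trimmed to its highest-density region
(by default the cells holding 99% of the mass). A community's
distribution (TPDc) is the occurrence-frequency-weighted mixture of its
species' TPDs.

The grid is shared by every distribution in an analysis; all overlap and
diversity computations reduce to vector arithmetic over its cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


class GridMismatchError(ValueError):
    """Raised when distributions built on different grids are combined."""


@dataclass(frozen=True)
class TraitGrid:
    """Regular rectangular grid over the retained trait axes.

    ``lower``/``upper`` are per-axis bounds, each axis split into
    ``cells_per_dim`` equal cells. Distributions are stored as flat vectors
    of length ``cells_per_dim ** dims`` (C order over axes).
    """

    lower: tuple[float, ...]
    upper: tuple[float, ...]
    cells_per_dim: int

    def __post_init__(self):
        if self.cells_per_dim < 4:
            raise ValueError("cells_per_dim must be >= 4")
        if any(u <= lo for lo, u in zip(self.lower, self.upper)):
            raise ValueError("upper bounds must exceed lower bounds")

    @property
    def dims(self) -> int:
        return len(self.lower)

    @property
    def n_cells(self) -> int:
        return self.cells_per_dim**self.dims

    @property
    def steps(self) -> np.ndarray:
        return (np.asarray(self.upper) - np.asarray(self.lower)) / self.cells_per_dim

    @property
    def cell_volume(self) -> float:
        return float(np.prod(self.steps))

    def axis_centers(self, axis: int) -> np.ndarray:
        step = self.steps[axis]
        return self.lower[axis] + step * (np.arange(self.cells_per_dim) + 0.5)


def build_grid(
    coords: np.ndarray, cells_per_dim: int = 15, buffer_fraction: float = 0.05
) -> TraitGrid:
    """Build a grid covering all projected coordinates plus a buffer.

    Per-axis bounds are ``[min - b*range, max + b*range]`` with
    ``b = buffer_fraction``. An axis with zero range cannot be gridded;
    supply a wider coordinate cloud or a manual :class:`TraitGrid`.
    """
    coords = np.atleast_2d(np.asarray(coords, float))
    if coords.size == 0:
        raise ValueError("coords is empty")
    lo = coords.min(axis=0)
    hi = coords.max(axis=0)
    rng = hi - lo
    if np.any(rng <= 0):
        bad = int(np.argmin(rng))
        raise ValueError(
            f"axis {bad} has zero range; widen the input or build a TraitGrid "
            "with explicit bounds (minimum-width override)"
        )
    return TraitGrid(
        lower=tuple(lo - buffer_fraction * rng),
        upper=tuple(hi + buffer_fraction * rng),
        cells_per_dim=cells_per_dim,
    )


@dataclass(frozen=True)
class SpeciesTPD:
    """Discretized, trimmed trait probability distribution of one species."""

    species_id: str
    grid: TraitGrid
    probabilities: np.ndarray  # flat, sums to 1; zeros outside the support

    @property
    def support(self) -> np.ndarray:
        return self.probabilities > 0


@dataclass(frozen=True)
class CommunityTPD:
    """Occurrence-weighted mixture of species TPDs for one site."""

    site_id: str
    grid: TraitGrid
    probabilities: np.ndarray
    species_ids: tuple[str, ...]
    weights: np.ndarray  # renormalized, sums to 1

    @property
    def support(self) -> np.ndarray:
        return self.probabilities > 0


def trim_to_mass(p: np.ndarray, trim_mass: float) -> np.ndarray:
    """Keep the highest-density cells holding >= ``trim_mass`` of the mass.

    Cells are ranked by probability descending (ties broken by cell index);
    the cut falls at the first cell at which the cumulative mass reaches
    ``trim_mass``, so the retained mass is always >= trim_mass. The result
    is renormalized. ``trim_mass >= 1`` is a no-op on the nonzero cells.
    """
    if not 0.5 < trim_mass <= 1.0:
        raise ValueError("trim_mass must lie in (0.5, 1]")
    if trim_mass >= 1.0:
        return p.copy()
    order = np.argsort(-p, kind="stable")
    csum = np.cumsum(p[order])
    cut = int(np.searchsorted(csum, trim_mass)) + 1
    keep = order[:cut]
    out = np.zeros_like(p)
    out[keep] = p[keep]
    return out / out.sum()


def species_tpd(
    species_id: str,
    means: np.ndarray,
    sds: np.ndarray,
    grid: TraitGrid,
    trim_mass: float = 0.99,
) -> SpeciesTPD:
    """Gaussian TPD of one species on the grid, trimmed to its HDR.

    Cell probability is proportional to the product over axes of the
    normal density (mean, SD per axis) at the cell center; the diagonal
    covariance reflects that the ordination axes are uncorrelated at the
    species level. After normalization the lowest-density cells are
    trimmed away until the highest-density region holding ``trim_mass``
    of the mass remains, then renormalized.
    """
    means = np.asarray(means, float)
    sds = np.asarray(sds, float)
    if means.shape != (grid.dims,) or sds.shape != (grid.dims,):
        raise ValueError("means/sds must match the grid dimensionality")
    if np.any(sds <= 0):
        raise ValueError(f"non-positive axis SD for species {species_id!r}")
    dens = np.ones(1)
    for ax in range(grid.dims):
        d = stats.norm.pdf(grid.axis_centers(ax), loc=means[ax], scale=sds[ax])
        dens = np.multiply.outer(dens, d)
    flat = dens.ravel()
    total = flat.sum()
    if total <= 1e-300 or not np.isfinite(total):
        raise ValueError(
            f"species {species_id!r} has essentially no probability mass on "
            "the grid; enlarge the grid bounds"
        )
    p = trim_to_mass(flat / total, trim_mass)
    return SpeciesTPD(species_id=species_id, grid=grid, probabilities=p)


def _check_same_grid(*dists) -> TraitGrid:
    grid = dists[0].grid
    for d in dists[1:]:
        if d.grid != grid:
            raise GridMismatchError("distributions are not on the same grid")
    return grid


def community_tpd(
    site_id: str, tpds: list[SpeciesTPD], weights: np.ndarray
) -> CommunityTPD:
    """Community TPD: weighted mixture of species TPDs.

    ``weights`` are relative occurrence frequencies (any non-negative
    numbers with at least one positive); they are renormalized to sum to 1.
    """
    if not tpds:
        raise ValueError("community has no species TPDs")
    grid = _check_same_grid(*tpds)
    w = np.asarray(weights, float)
    if w.shape != (len(tpds),):
        raise ValueError("one weight per species TPD is required")
    if np.any(w < 0) or w.sum() <= 0:
        raise ValueError("weights must be non-negative with a positive sum")
    w = w / w.sum()
    p = np.zeros(grid.n_cells)
    for wi, t in zip(w, tpds):
        p += wi * t.probabilities
    p /= p.sum()  # corrects trimming round-off
    return CommunityTPD(
        site_id=site_id,
        grid=grid,
        probabilities=p,
        species_ids=tuple(t.species_id for t in tpds),
        weights=w,
    )


def tpd_overlap(p: SpeciesTPD | CommunityTPD, q: SpeciesTPD | CommunityTPD) -> float:
    """Overlap between two distributions: sum of cellwise minima, in [0, 1]."""
    _check_same_grid(p, q)
    return float(np.minimum(p.probabilities, q.probabilities).sum())
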