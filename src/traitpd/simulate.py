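"""Synthetic leaf-litter ant landscapes with known ground truth.

The generator emulates the data structure of a habitat-filtering field
study: 25 sites in four habitat classes (native forest, n = 10; three
plantation classes, n = 5 each), a regional pool of ~80 species, six
sampling points per site yielding occurrence counts 0-6, and
individual-level measurements of eight morphological traits (mm).

Species live in a latent 4-axis niche space. A habitat filters the pool
through a Gaussian kernel around its trait optimum: occupancy probability
of species s at a site of habitat h is

    p = base_occupancy * exp(-||z_s - opt_h||^2 / (2 * omega_h^2)).

In the default "homogenization" scenario the three plantation classes
share one displaced optimum with a narrow filter width (strong filtering,
homogenized composition) while forest keeps a broad filter around the
pool centroid. Niche axes map linearly onto log trait ratios (trait /
Weber's length) plus residual noise, and Weber's length itself covaries
with the first niche axis, so the allometric standardization used by the
analysis pipeline is meaningful. Intraspecific variation is log-normal
around each species' trait means, with per-species spread drawn from a
log-normal distribution; a configurable fraction of the pool is kept
rare (< 6 measured individuals in total) to exercise the SD-imputation
rule downstream.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .traits import SIZE_TRAIT, TRAIT_NAMES

#: Habitat classes of the emulated design with their site counts.
DEFAULT_SITES_PER_HABITAT = {
    "forest": 10,
    "unmanaged_28yr": 5,
    "managed_7yr": 5,
    "managed_28yr": 5,
}

# Baseline log trait ratios (trait / Weber's length) giving realistic
# worker morphology in mm at a ~1.1 mm Weber's length.
_BASE_LOG_RATIO = {
    "head_width": np.log(0.72),
    "scape_length": np.log(0.55),
    "eye_mandible_distance": np.log(0.19),
    "eye_length": np.log(0.15),
    "interocular_distance": np.log(0.46),
    "leg_length": np.log(1.15),
    "petiole_length": np.log(0.18),
}

# Fixed niche-axis -> log-trait-ratio loadings (7 ratio traits x 4 axes).
# Chosen once so every axis is expressed in several traits and species
# ordination recovers a 4-dimensional functional space.
_RATIO_LOADINGS = np.array(
    [
        [0.22, -0.10, 0.05, 0.02],   # head_width
        [0.10, 0.25, -0.08, 0.04],   # scape_length
        [-0.05, 0.08, 0.28, -0.06],  # eye_mandible_distance
        [0.04, -0.20, 0.10, 0.22],   # eye_length
        [0.18, 0.06, -0.15, 0.12],   # interocular_distance
        [0.08, 0.18, 0.12, -0.20],   # leg_length
        [-0.12, 0.05, 0.06, 0.25],   # petiole_length
    ]
)
_WEBER_LOADINGS = np.array([0.45, 0.10, 0.0, 0.0])
_RATIO_NOISE_SD = 0.08  # residual species-level scatter per log ratio


@dataclass
class SimulationConfig:
    """Study-design and effect-size parameters of the generator.

    The defaults define the "homogenization" scenario: plantations share
    one displaced trait optimum with a narrow filter (``omega``), forest
    filters broadly around the pool centroid.
    """

    seed: int = 0
    sites_per_habitat: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_SITES_PER_HABITAT)
    )
    pool_size: int = 80
    n_niche_axes: int = 4
    niche_sds: tuple[float, ...] = (1.0, 0.85, 0.7, 0.6)
    #: habitat -> niche-space optimum (padded/truncated to n_niche_axes)
    habitat_optima: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: {
            "forest": (0.0, 0.0, 0.0, 0.0),
            "unmanaged_28yr": (1.5, 0.0, 0.0, 0.0),
            "managed_7yr": (1.5, 0.0, 0.0, 0.0),
            "managed_28yr": (1.5, 0.0, 0.0, 0.0),
        }
    )
    #: habitat -> Gaussian filter width omega_h
    habitat_omega: dict[str, float] = field(
        default_factory=lambda: {
            "forest": 2.2,
            "unmanaged_28yr": 0.95,
            "managed_7yr": 0.95,
            "managed_28yr": 0.95,
        }
    )
    #: habitat -> occupancy gain. A narrow filter concentrates occupancy on
    #: the few matched species rather than merely thinning the community:
    #: the survivors of a strong filter occur reliably, which is what
    #: homogenizes filtered communities.
    habitat_gain: dict[str, float] = field(
        default_factory=lambda: {
            "forest": 1.0,
            "unmanaged_28yr": 2.6,
            "managed_7yr": 2.6,
            "managed_28yr": 2.6,
        }
    )
    base_occupancy: float = 0.34
    #: SD of the log-normal per-species occupancy propensity; 0 makes all
    #: species equally common, larger values give realistic common/rare
    #: structure (and hence repeatable composition within a habitat).
    occupancy_spread: float = 1.0
    detection: float = 0.5
    sampling_points: int = 6
    #: mean Weber's length (mm) on the log scale and its pool SD
    log_weber_mean: float = float(np.log(1.1))
    log_weber_sd: float = 0.25
    #: log-normal parameters of per-species intraspecific SDs (log scale)
    intraspecific_sd_logmean: float = float(np.log(0.08))
    intraspecific_sd_logsd: float = 0.4
    rare_fraction: float = 0.4
    landscape_extent: float = 2500.0  # m
    clustered_coordinates: bool = False

    def __post_init__(self):
        if self.pool_size < 10:
            raise ValueError("pool_size must be >= 10")
        for p in (self.base_occupancy, self.detection, self.rare_fraction):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        if any(w <= 0 for w in self.habitat_omega.values()):
            raise ValueError("filter widths omega must be positive")
        for mapping in (self.habitat_optima, self.habitat_omega, self.habitat_gain):
            if set(mapping) != set(self.sites_per_habitat):
                raise ValueError(
                    "optima/omega/gain must cover exactly the habitat classes"
                )

    def null_scenario(self) -> "SimulationConfig":
        """Copy with all habitat filters equalized (no habitat effect)."""
        cfg = dataclasses.replace(self)
        cfg.habitat_optima = {h: (0.0,) * self.n_niche_axes for h in self.sites_per_habitat}
        cfg.habitat_omega = {h: 1e6 for h in self.sites_per_habitat}
        cfg.habitat_gain = {h: 1.0 for h in self.sites_per_habitat}
        return cfg


@dataclass
class SpeciesPool:
    """Regional species archetypes: latent niches and true trait values."""

    species_ids: list[str]
    niche: np.ndarray  # pool_size x n_niche_axes
    trait_means: pd.DataFrame  # raw mm scale, pool_size x 8
    log_trait_means: pd.DataFrame  # log mm scale
    intraspecific_sd: pd.DataFrame  # per species x trait, log scale
    rare: np.ndarray  # boolean mask of species kept rare
    occupancy: np.ndarray  # per-species baseline occupancy probability


@dataclass
class SyntheticDataset:
    """A full synthetic landscape plus its generating ground truth."""

    traits: pd.DataFrame  # individual-level trait table
    occurrences: pd.DataFrame  # site x species counts
    sites: pd.DataFrame  # site_id, habitat, x, y
    ground_truth: dict


def generate_species_pool(config: SimulationConfig) -> SpeciesPool:
    """Draw the regional species pool (deterministic given the seed)."""
    rng = np.random.default_rng(config.seed)
    k = config.n_niche_axes
    ids = [f"sp{i + 1:03d}" for i in range(config.pool_size)]
    niche = rng.normal(0.0, np.asarray(config.niche_sds[:k]), size=(config.pool_size, k))

    log_weber = config.log_weber_mean + niche @ _WEBER_LOADINGS[:k] + rng.normal(
        0.0, config.log_weber_sd * 0.4, config.pool_size
    )
    log_means = {}
    ratio_traits = [t for t in TRAIT_NAMES if t != SIZE_TRAIT]
    for r, name in enumerate(ratio_traits):
        log_ratio = (
            _BASE_LOG_RATIO[name]
            + niche @ _RATIO_LOADINGS[r, :k]
            + rng.normal(0.0, _RATIO_NOISE_SD, config.pool_size)
        )
        log_means[name] = log_ratio + log_weber
    log_means[SIZE_TRAIT] = log_weber
    log_df = pd.DataFrame(log_means, index=ids)[list(TRAIT_NAMES)]

    sds = np.exp(
        rng.normal(
            config.intraspecific_sd_logmean,
            config.intraspecific_sd_logsd,
            size=(config.pool_size, len(TRAIT_NAMES)),
        )
    )
    sd_df = pd.DataFrame(sds, index=ids, columns=list(TRAIT_NAMES))
    n_rare = int(round(config.rare_fraction * config.pool_size))
    rare = np.zeros(config.pool_size, dtype=bool)
    rare[rng.choice(config.pool_size, n_rare, replace=False)] = True
    # log-normal occupancy propensity, mean-corrected to base_occupancy
    spread = config.occupancy_spread
    occupancy = np.minimum(
        config.base_occupancy
        * np.exp(rng.normal(0.0, spread, config.pool_size) - spread**2 / 2),
        0.95,
    )
    return SpeciesPool(
        species_ids=ids,
        niche=niche,
        trait_means=np.exp(log_df),
        log_trait_means=log_df,
        intraspecific_sd=sd_df,
        rare=rare,
        occupancy=occupancy,
    )


def _site_table(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    habitats = list(config.sites_per_habitat)
    if config.clustered_coordinates:
        centers = {
            h: rng.uniform(0.2, 0.8, 2) * config.landscape_extent for h in habitats
        }
    i = 0
    for h in habitats:
        for _ in range(config.sites_per_habitat[h]):
            i += 1
            if config.clustered_coordinates:
                xy = centers[h] + rng.normal(0, 0.08 * config.landscape_extent, 2)
            else:
                xy = rng.uniform(0, config.landscape_extent, 2)
            rows.append({"site_id": f"site{i:02d}", "habitat": h, "x": xy[0], "y": xy[1]})
    return pd.DataFrame(rows)


def sample_communities(
    pool: SpeciesPool, config: SimulationConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sample site x species occurrence counts and site coordinates.

    Occupancy follows the Gaussian habitat filter; conditional on
    occupancy, the occurrence count over the site's sampling points is
    Binomial(sampling_points, detection). A site ending up empty is
    resampled once, then raises.
    """
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 1)))
    sites = _site_table(config, rng)
    k = config.n_niche_axes
    counts = np.zeros((len(sites), len(pool.species_ids)), dtype=int)
    for row in sites.itertuples():
        i = sites.index.get_loc(row.Index)
        opt = np.asarray(config.habitat_optima[row.habitat][:k])
        omega = config.habitat_omega[row.habitat]
        gain = config.habitat_gain.get(row.habitat, 1.0)
        d2 = ((pool.niche - opt) ** 2).sum(axis=1)
        p_occ = np.minimum(gain * pool.occupancy * np.exp(-d2 / (2 * omega**2)), 0.95)
        for _attempt in range(2):
            occupied = rng.random(len(p_occ)) < p_occ
            c = np.where(
                occupied,
                rng.binomial(config.sampling_points, config.detection, len(p_occ)),
                0,
            )
            if c.sum() > 0:
                break
        else:
            raise RuntimeError(
                f"site {row.site_id} sampled zero species twice; increase "
                "base_occupancy or detection"
            )
        counts[i] = c
    occ = pd.DataFrame(counts, index=sites["site_id"], columns=pool.species_ids)
    return occ, sites


def measure_individuals(
    pool: SpeciesPool, occurrences: pd.DataFrame, config: SimulationConfig
) -> pd.DataFrame:
    """Simulate individual-level trait measurement of the sampled ants.

    Non-rare species are measured at up to ``sampling_points`` individuals
    per occupied site (a draw scaled by the occurrence count); species in
    the rare set get 1-5 individuals in total, so the six-individual SD
    rule has work to do. Individual log traits are normal around the
    species' log means with its intraspecific SD (hence positive values).
    """
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 2)))
    rows = []
    counter = 0
    rare_by_id = dict(zip(pool.species_ids, pool.rare))
    for sp in pool.species_ids:
        col = occurrences[sp]
        occupied_sites = list(col.index[col > 0])
        if not occupied_sites:
            continue
        if rare_by_id[sp]:
            total = int(rng.integers(1, 6))
            chosen = rng.choice(len(occupied_sites), size=total, replace=True)
            per_site = np.bincount(chosen, minlength=len(occupied_sites))
        else:
            # up to sampling_points individuals per occupied site, scaled
            # by how often the species turned up there
            per_site = np.array(
                [
                    max(1, min(config.sampling_points, int(rng.binomial(2 * col[s], 0.6))))
                    for s in occupied_sites
                ]
            )
        mu = pool.log_trait_means.loc[sp].to_numpy()
        sd = pool.intraspecific_sd.loc[sp].to_numpy()
        for s, n_ind in zip(occupied_sites, per_site):
            for _ in range(int(n_ind)):
                counter += 1
                vals = np.exp(rng.normal(mu, sd))
                row = {
                    "individual_id": f"ind{counter:05d}",
                    "species_id": sp,
                    "site_id": s,
                }
                row.update(dict(zip(TRAIT_NAMES, vals)))
                rows.append(row)
    return pd.DataFrame(rows)


def generate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Generate a complete landscape: pool, communities, measured traits."""
    pool = generate_species_pool(config)
    occurrences, sites = sample_communities(pool, config)
    traits = measure_individuals(pool, occurrences, config)
    ground_truth = {
        "habitat_optima": {h: list(map(float, v)) for h, v in config.habitat_optima.items()},
        "habitat_omega": dict(config.habitat_omega),
        "habitat_gain": dict(config.habitat_gain),
        "species_niche": {
            sp: list(map(float, z)) for sp, z in zip(pool.species_ids, pool.niche)
        },
        "species_trait_means_mm": {
            sp: pool.trait_means.loc[sp].round(6).to_dict() for sp in pool.species_ids
        },
        "species_log_sd": {
            sp: pool.intraspecific_sd.loc[sp].round(6).to_dict()
            for sp in pool.species_ids
        },
        "rare_species": [s for s, r in zip(pool.species_ids, pool.rare) if r],
        "expected_pattern": {
            "forest_fric_highest": True,
            "plantations_homogenized": True,
        }
        if config.habitat_omega.get("forest", 0) > max(
            v for h, v in config.habitat_omega.items() if h != "forest"
        )
        else {"null_scenario": True},
    }
    return SyntheticDataset(
        traits=traits, occurrences=occurrences, sites=sites, ground_truth=ground_truth
    )
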