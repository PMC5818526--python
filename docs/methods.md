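# Methods

`traitpd` implements a trait-based analysis of community structure across
habitat classes, built around trait probability distributions (TPDs). This
note documents the model, the defaults and the numerical choices, and what
the synthetic validation does and does not establish.

## Trait space

Input is an individual-level table of eight morphological lengths (mm):
head width, scape length, eye–mandible distance, eye length, interocular
distance, Weber's length, leg length and petiole length. Weber's length is
the standard ant body-size proxy, so every other trait is divided by it to
remove allometric correlation; all traits (including Weber's length itself,
which is kept as the size axis) are then natural-log-transformed and
z-scored. The z-scoring constants are estimated from **species means** —
the same matrix the ordination consumes — and then applied unchanged to
individuals, so species scores and individual projections share one space.
The log base is immaterial (absorbed by the z-score); natural log is used
by convention.

A PCA is fitted on the species-mean matrix rather than on individuals, so
heavily sampled species do not dominate the axes. The first four axes are
retained by default (on simulated data they carry ~86–92% of the variance);
a cumulative-variance mode (`cumulative_variance=0.85`) is available for
other datasets. Loading signs are fixed (largest-magnitude entry of each
column positive) to make the rotation, and hence every downstream output,
bit-reproducible.

Per-species axis means and standard deviations parameterize the TPDs.
Species with at least **6 measured individuals** use their own sample SDs;
species below the threshold receive, on every axis, the arithmetic mean of
the well-sampled species' SDs (`sd_imputed` flag). This keeps rare species
in the analysis with a plausible spread instead of dropping them or giving
every species the same SD. The imputation never touches the rare species'
own records (verified by a leave-one-out test).

## Trait probability distributions

Each species' TPD is a multivariate Gaussian with diagonal covariance
(axis means, axis SDs) evaluated at the cell centers of a regular grid
over the retained axes, normalized, and trimmed to its high-density region:
cells are ranked by probability (ties broken by cell index) and the
smallest set holding at least `trim_mass` of the mass is kept, then
renormalized. Diagonal covariance is used because the PCA axes are
uncorrelated at the species level and per-species cross-axis covariance is
not estimable for rare species.

Defaults: `cells_per_dim = 15` in 4-D (50,625 cells), `buffer_fraction =
0.05` around the projected individuals, `trim_mass = 0.99` (the 99%
high-density-region convention of the TPD literature). Densities are
evaluated at cell centers rather than integrated over cells; a
grid-refinement test confirms that doubling the resolution moves
overlap-based quantities by well under 2%.

A community's TPD (TPDc) is the mixture of its species' trimmed TPDs
weighted by relative occurrence frequency (occurrences are counts of
sampling points, 0–6, at which the species was recorded; occurrence is
used instead of abundance because ant abundance is inflated by colony
size). The mixture is renormalized to absorb trimming round-off.

## Alpha diversity

- **Richness** — number of species with a positive occurrence count.
- **CWM** — occurrence-weighted mean of each raw trait (mm scale, so the
  values read directly as morphology).
- **FRic** — number of cells where the community TPD is positive times the
  cell volume. Because species TPDs are trimmed once at `trim_mass`, the
  support of the mixture *is* the community's occupied high-density
  region: for a single-species community FRic equals the analytic HDR
  volume (pi·chi²₂(0.99) ≈ 28.94 for an isotropic 2-D unit Gaussian, which
  the tests verify within 5%). A second community-level trim would shave
  the region to ~98% mass and bias the volume ~15% low, so it is not
  applied.
- **FRed** — with M(cell) = number of contributing species whose trimmed
  TPD covers the cell, FRed = Σ TPDc(cell)·M(cell) − 1: the mean depth of
  species overlap under the community distribution, minus one so a
  single-species community scores 0 and n identical species score n − 1.
  The formula identifier is written to the run manifest
  (`mean_overlap_depth_minus_one`) because other redundancy definitions
  exist in the literature.
- **Rao's Q** — Q = Σᵢⱼ wᵢwⱼ dᵢⱼ with dᵢⱼ = 1 − overlap(TPDᵢ, TPDⱼ) and
  overlap the sum of cellwise minima. Q is bounded by 1 − Σwᵢ² (asserted
  as an invariant).

## Beta diversity

Taxonomic dissimilarity between every site pair uses Baselga's
incidence-based partition: total = Sorensen, turnover = Simpson,
nestedness = difference. The degenerate 0/0 case of the Simpson index
(no shared and no unique species on one side) is defined as 0.

Functional dissimilarity applies the same partition to trait space. Two
modes are provided, because normalized probability masses make a naive
Baselga-on-mass partition degenerate (each community's "unique mass"
always equals the other's, forcing zero nestedness):

- **volume** (default): the occupied grid cells of each community TPD play
  the role of species; shared and unique cell counts feed the Baselga
  formulas.
- **overlap**: total = 1 − Σ min(p, q); the nested share is
  total·|P_A − P_B|/(P_A + P_B), where P_X is X's mass outside the other's
  support, and turnover is the remainder.

The mode in use is recorded in the run manifest. Bray–Curtis distances on
raw occurrence counts support the spatial checks.

## Inference

- **Group comparisons** of each alpha index across habitat classes use a
  normality gate: Shapiro–Wilk on the one-way-ANOVA residuals at
  alpha = 0.05 routes to ANOVA + Tukey HSD (normal) or Kruskal–Wallis +
  Dunn's z tests with Holm adjustment (non-normal). Dunn's statistics use
  the standard rank-sum form with tie correction. Pairwise outcomes are
  condensed to a compact letter display via maximal cliques of the
  not-significantly-different graph.
- **PERMANOVA** (one factor): SS_total = Σ_{i<j} d²/N, SS_within summed
  over within-group pairs divided by group size, pseudo-F =
  (SS_among/(g−1))/(SS_within/(N−g)); p by permuting group labels. The
  implementation is cross-checked against scikit-bio to 1e−8 in tests.
- **Moran's I** with inverse-distance weights (w_ij = 1/d_ij, not row
  standardized — the simplest defensible default; duplicate coordinates
  are an error) and a two-sided Monte-Carlo p (doubled smaller tail,
  capped at 1).
- **Mantel**: Pearson r over lower triangles, one-sided (greater) p by
  permuting one matrix's site order.

All permutation engines take 9,999 permutations by default, use
`numpy.random.default_rng(seed)`, report p = (#{null ≥ observed} + 1) /
(n_perm + 1) (never zero, exactly valid under exchangeability), and are
bit-reproducible for a fixed seed.

## Synthetic data generator

The generator emulates the study design the pipeline targets: 25 sites
(10 forest, 5 per plantation class), a pool of 80 species, 6 sampling
points per site, individual-level measurement of the 8 traits. Species
live in a latent 4-axis niche space (SDs 1.0/0.85/0.7/0.6); habitat h
filters the pool via

    p_occ(s, h) = min(gain_h · q_s · exp(−‖z_s − opt_h‖² / (2ω_h²)), 0.95)

where q_s is a log-normal per-species occupancy propensity (spread 1.0,
mean-corrected to `base_occupancy = 0.34`) giving realistic common/rare
structure. Occurrence counts are Binomial(6, 0.5) conditional on
occupancy. In the default *homogenization* scenario the three plantation
classes share one optimum displaced 1.5 niche units from the forest
centroid with ω = 0.95 and gain 2.6, while forest has ω = 2.2 and gain 1;
the gain reflects that the survivors of a strong filter occur reliably,
which is what homogenizes filtered communities and roughly equalizes
occupancy totals. These values were fixed once so that realized
per-habitat richness (~18 forest vs ~10 plantation) and the diversity
ordering resemble a disturbed-landscape field study; they are not tuned
per run. `null_scenario()` equalizes all filters for calibration studies.

Niche axes map linearly onto log trait ratios (fixed 8×4 loading matrix
plus residual scatter), and Weber's length covaries with the first axis so
the ratio standardization is meaningful. Individual log traits are normal
around species log means with per-species SDs drawn log-normally
(median 0.08, i.e. ~8% coefficient of variation); 40% of the pool is kept
rare (1–5 individuals in total) to exercise SD imputation. Coordinates are
uniform over a 2.5 km square by default; a clustered mode exists for
exercising the spatial tests, and is off by default so Moran's I null
checks are clean.

What the generator does **not** emulate: phylogenetic signal in traits,
dispersal limitation or metacommunity dynamics, observation error in the
trait measurements beyond intraspecific variation, and abundance
structure beyond occurrence counts. Passing the recovery tests therefore
shows the pipeline detects Gaussian habitat filtering of the configured
strength in clean data — not that it would detect weaker or structurally
different effects in field data.

## Validation studies and problem sizes

`traitpd.validation` backs the test suite and `scripts/acceptance.py`:

- analytic FRic (2-D isotropic Gaussian, 200 cells/dim) against
  pi·chi²₂(0.99);
- analytic overlap/Rao for two unit Gaussians 2σ apart (1,600 cells)
  against 2Φ(−1);
- a four-point PERMANOVA whose sums of squares are hand-computable
  (F = 1 exactly);
- PERMANOVA type-I error under an exchangeable null (1,000 datasets ×
  999 permutations at N = 12 in the tests);
- the Moran's I permutation null mean against −1/(n−1);
- homogenization recovery over 50 seeded landscapes at 10 cells/dim, and
  null-landscape calibration over 300 replicates at 8 cells/dim. The
  coarser grids are the package's own choice for replicated studies;
  single-run analyses default to 15 cells/dim.

## Known limitations

- FRic is grid-quantized; at the default resolution, volumes are
  comparable between communities on the same grid but carry a
  discretization error of a few percent.
- The functional turnover/nestedness split depends on the chosen mode
  (volume vs overlap); both are reported as such, and neither is claimed
  to be the unique decomposition.
- Moran's I uses unstandardized inverse-distance weights; alternative
  weighting (row standardization, neighbor thresholds) is out of scope.
- Group comparisons assume independent sites; there is no nested or
  multi-factor design support.
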