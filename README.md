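# traitpd

Trait-probability-distribution (TPD) functional diversity analysis for
community ecology, with taxonomic/functional β-diversity partitioning and
permutation-based inference.

## The problem

Comparing communities across habitat classes (e.g. native forest vs
plantation stands) by species richness alone misses how disturbance
reshapes the *functional* structure of a community. `traitpd` works from
individual-level morphological measurements and site × species occurrence
counts to quantify:

- **α diversity per site** — species richness; community-weighted mean
  (CWM) of each trait; functional richness
  `FRic = |{cells : TPDc > 0}| · V_cell` (occupied trait-space volume);
  functional redundancy `FRed = Σ_cells TPDc·M − 1` (mean species-overlap
  depth, with M the number of species covering a cell); and Rao's
  quadratic entropy `Q = Σᵢⱼ wᵢwⱼ dᵢⱼ`, `dᵢⱼ = 1 − Σ min(TPDᵢ, TPDⱼ)`.
- **β diversity between sites** — Baselga's partition
  `β_sor = (b+c)/(2a+b+c)`, `β_sim = min(b,c)/(a+min(b,c))`,
  `β_nes = β_sor − β_sim`, applied to species incidences (taxonomic) and
  to occupied trait-space cells (functional), plus Bray–Curtis distances.
- **Inference** — normality-gated group comparisons (ANOVA + Tukey HSD, or
  Kruskal–Wallis + Dunn with Holm adjustment), one-factor PERMANOVA on the
  β matrices, Moran's I and Mantel tests for spatial autocorrelation; all
  permutation p-values use the +1 rule with a fixed seed.

Species TPDs are multivariate Gaussians over the first four PCA axes of
standardized traits (each trait divided by Weber's length, log-transformed,
z-scored), trimmed to their 99% high-density region. Intraspecific
variation enters through per-species axis SDs; species with fewer than six
measured individuals borrow the mean SD of the well-sampled species.

A synthetic landscape generator (`traitpd.simulate`) with known ground
truth — Gaussian habitat filtering in a latent niche space — supports
end-to-end validation and power/calibration studies.

## Worked example

```python
from traitpd import PipelineConfig, SimulationConfig, analyse, generate_dataset
from traitpd.io import Dataset

sim = generate_dataset(SimulationConfig(seed=42))
dataset = Dataset(traits=sim.traits, occurrences=sim.occurrences,
                  sites=sim.sites.set_index("site_id"))
result = analyse(dataset, PipelineConfig(seed=42, cells_per_dim=12,
                                         n_permutations=499))
print(result.alpha.groupby("habitat")[["richness", "fric", "fred", "rao_q"]]
      .mean().round(3))
```

prints

```
                richness     fric   fred  rao_q
habitat
forest              15.5  705.490  0.793  0.910
managed_28yr         9.4  394.481  0.553  0.853
managed_7yr         10.2  431.593  0.641  0.869
unmanaged_28yr      10.6  443.274  0.472  0.881
```

Forest sites are richer, occupy a much larger trait-space volume (FRic),
and hold functionally more distinct species (higher Rao's Q) than the
filtered plantation classes — the homogenization pattern the generator
encodes. `result.permanova_table` holds the habitat effect on each β
component (for this landscape, taxonomic total: pseudo-F = 1.93,
p = 0.002; functional total: pseudo-F = 3.38, p = 0.001), and
`result.spatial` the Moran's I / Mantel checks (Mantel r = −0.05,
p = 0.72: no spatial artefact).

The `examples/` directory contains one short script per capability
(simulation, trait space, α, β, inference). A thin CLI mirrors the
pipeline:

```bash
traitpd simulate --seed 42 --out data/
traitpd run --traits data/traits.csv --occurrences data/occurrences.csv \
            --sites data/sites.csv --out results/ --seed 42
```

Each run writes machine-readable CSVs plus `manifest.json` recording every
setting needed to reproduce the outputs bit-for-bit.

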