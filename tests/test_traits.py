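"""Trait standardization, ordination and species summaries."""

import numpy as np
import pandas as pd
import pytest

from traitpd.traits import (
    MIN_INDIVIDUALS_FOR_SD,
    TRAIT_NAMES,
    TraitTableError,
    fit_trait_pca,
    project_individuals,
    species_mean_matrix,
    standardize_traits,
    summarize_species,
)


def _one_record(**trait_values):
    row = {"individual_id": "i1", "species_id": "sp1", "site_id": "s1"}
    row.update({t: 1.0 for t in TRAIT_NAMES})
    row.update(trait_values)
    return pd.DataFrame([row])


class TestStandardize:
    def test_log_ratio_values(self, trait_table):
        """Pre-z values are log(trait / Weber's length); Weber is log only."""
        std, const = standardize_traits(trait_table)
        # invert the z-scoring to recover the log-ratio scale
        recovered = std[list(TRAIT_NAMES)].to_numpy() * const.scale + const.center
        weber = trait_table["webers_length"].to_numpy()
        for j, t in enumerate(TRAIT_NAMES):
            raw = trait_table[t].to_numpy()
            expected = np.log(raw) if t == "webers_length" else np.log(raw / weber)
            np.testing.assert_allclose(recovered[:, j], expected, atol=1e-12)

    def test_species_mean_columns_are_z_scored(self, trait_table):
        std, _ = standardize_traits(trait_table)
        means = species_mean_matrix(std)
        np.testing.assert_allclose(means.mean(axis=0), 0, atol=1e-9)
        np.testing.assert_allclose(means.std(axis=0, ddof=1), 1, atol=1e-9)

    def test_stored_constants_reproduce_bitwise(self, trait_table):
        std1, const = standardize_traits(trait_table)
        std2, _ = standardize_traits(trait_table, constants=const)
        assert std1[list(TRAIT_NAMES)].equals(std2[list(TRAIT_NAMES)])

    def test_nonpositive_trait_rejected_with_record_id(self, trait_table):
        bad = trait_table.copy()
        bad.loc[2, "eye_length"] = -0.1
        with pytest.raises(TraitTableError, match=bad.loc[2, "individual_id"]):
            standardize_traits(bad)

    def test_missing_trait_rejected(self, trait_table):
        bad = trait_table.copy()
        bad.loc[0, "head_width"] = np.nan
        with pytest.raises(TraitTableError, match="missing"):
            standardize_traits(bad)


class TestPCA:
    def test_loadings_orthonormal_and_variance_sums_to_one(self, trait_table):
        std, const = standardize_traits(trait_table)
        model = fit_trait_pca(species_mean_matrix(std), const)
        eye = model.loadings.T @ model.loadings
        np.testing.assert_allclose(eye, np.eye(8), atol=1e-9)
        assert abs(model.explained_fraction.sum() - 1) < 1e-9
        assert np.all(np.diff(model.explained_fraction) <= 1e-12)

    def test_collinear_traits_put_all_variance_on_axis_one(self, trait_table):
        # 3 species, two perfectly collinear informative traits, rest constant
        _, const = standardize_traits(trait_table)
        X = np.zeros((3, 8))
        X[:, 0] = [-1.0, 0.0, 1.0]
        X[:, 1] = 2.0 * X[:, 0]
        means = pd.DataFrame(X, columns=list(TRAIT_NAMES), index=["a", "b", "c"])
        model = fit_trait_pca(means, const)
        assert model.explained_fraction[0] == pytest.approx(1.0, abs=1e-12)

    def test_reconstruction_with_all_axes(self, trait_table):
        std, const = standardize_traits(trait_table)
        means = species_mean_matrix(std)
        model = fit_trait_pca(means, const, retained_axes=8)
        X = means.to_numpy()
        scores = X @ model.loadings
        np.testing.assert_allclose(scores @ model.loadings.T, X, atol=1e-8)

    def test_cumulative_variance_mode(self, trait_table):
        std, const = standardize_traits(trait_table)
        means = species_mean_matrix(std)
        model = fit_trait_pca(means, const, cumulative_variance=0.85)
        cum = np.cumsum(model.explained_fraction)
        k = model.retained_axes
        assert cum[k - 1] >= 0.85
        assert k == 1 or cum[k - 2] < 0.85

    def test_degenerate_inputs_raise(self, trait_table):
        _, const = standardize_traits(trait_table)
        one = pd.DataFrame(np.ones((1, 8)), columns=list(TRAIT_NAMES))
        with pytest.raises(ValueError, match="at least 2"):
            fit_trait_pca(one, const)
        flat = pd.DataFrame(np.ones((3, 8)), columns=list(TRAIT_NAMES))
        with pytest.raises(ValueError, match="zero variance"):
            fit_trait_pca(flat, const)


class TestProjection:
    def test_species_mean_projects_to_its_score(self, trait_table):
        std, const = standardize_traits(trait_table)
        means = species_mean_matrix(std)
        model = fit_trait_pca(means, const)
        coords = project_individuals(model, std, const)
        by_species = coords.groupby("species_id")[model.axis_names()].mean()
        np.testing.assert_allclose(
            by_species.loc[model.species_scores.index].to_numpy(),
            model.species_scores.to_numpy(),
            atol=1e-9,
        )

    def test_global_center_maps_to_origin(self, trait_table):
        std, const = standardize_traits(trait_table)
        model = fit_trait_pca(species_mean_matrix(std), const)
        center = _one_record()
        centered = center.copy()
        centered[list(TRAIT_NAMES)] = 0.0  # z = 0 is the global center
        out = project_individuals(model, centered, const)
        np.testing.assert_allclose(out[model.axis_names()].to_numpy(), 0, atol=1e-12)

    def test_matches_explicit_dot_product_oracle(self, trait_table):
        std, const = standardize_traits(trait_table)
        model = fit_trait_pca(species_mean_matrix(std), const)
        rng = np.random.default_rng(1)
        X = rng.normal(size=(10, 8))
        table = pd.DataFrame(X, columns=list(TRAIT_NAMES))
        table.insert(0, "site_id", "s")
        table.insert(0, "species_id", "sp")
        table.insert(0, "individual_id", [f"i{k}" for k in range(10)])
        got = project_individuals(model, table, const)[model.axis_names()].to_numpy()
        expected = np.array(
            [
                [sum(X[i, t] * model.loadings[t, j] for t in range(8)) for j in range(4)]
                for i in range(10)
            ]
        )
        np.testing.assert_allclose(got, expected, atol=1e-9)

    def test_fingerprint_mismatch_raises(self, trait_table):
        std, const = standardize_traits(trait_table)
        model = fit_trait_pca(species_mean_matrix(std), const)
        shifted = trait_table.copy()
        shifted[list(TRAIT_NAMES)] = shifted[list(TRAIT_NAMES)] * 2.0
        std2, const2 = standardize_traits(shifted)
        with pytest.raises(ValueError, match="scaling-constant mismatch"):
            project_individuals(model, std2, const2)


def _coords(counts: dict[str, int], seed=0) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    rows = []
    for sp, n in counts.items():
        mu = rng.normal(size=4)
        for i in range(n):
            row = {"individual_id": f"{sp}-{i}", "species_id": sp, "site_id": "s"}
            row.update(
                {f"axis{j + 1}": mu[j] + rng.normal(0, 0.5) for j in range(4)}
            )
            rows.append(row)
    return pd.DataFrame(rows)


class TestSummaries:
    def test_well_sampled_species_use_own_sd(self):
        coords = _coords({"a": 10, "b": 7, "c": 2})
        out = {s.species_id: s for s in summarize_species(coords)}
        assert not out["a"].sd_imputed and not out["b"].sd_imputed
        own = coords[coords.species_id == "a"][[f"axis{i}" for i in (1, 2, 3, 4)]]
        np.testing.assert_allclose(out["a"].axis_sds, own.std(ddof=1), atol=1e-12)

    def test_rare_species_get_donor_pool_mean_sd(self):
        coords = _coords({"a": 10, "b": 7, "c": 2})
        out = {s.species_id: s for s in summarize_species(coords)}
        assert out["c"].sd_imputed
        donor = np.mean([out["a"].axis_sds, out["b"].axis_sds], axis=0)
        np.testing.assert_allclose(out["c"].axis_sds, donor, atol=1e-12)

    def test_threshold_switches_exactly_at_six(self):
        for n, imputed in ((5, True), (6, False)):
            coords = _coords({"a": 10, "x": n})
            out = {s.species_id: s for s in summarize_species(coords)}
            assert out["x"].sd_imputed is imputed
        assert MIN_INDIVIDUALS_FOR_SD == 6

    def test_imputed_sd_independent_of_own_records(self):
        """Leave-one-out: the imputed SD never uses the rare species' data."""
        coords = _coords({"a": 10, "b": 7, "c": 2})
        out_with = {s.species_id: s for s in summarize_species(coords)}
        dropped = coords[coords.species_id != "c"]
        donor = {s.species_id: s for s in summarize_species(_coords({"a": 10, "b": 7}))}
        # same donor pool either way
        np.testing.assert_allclose(
            out_with["c"].axis_sds,
            np.mean([donor["a"].axis_sds, donor["b"].axis_sds], axis=0),
            atol=1e-12,
        )
        assert len(dropped) == 17

    def test_error_when_no_donor_pool(self):
        coords = _coords({"a": 3, "b": 5})
        with pytest.raises(ValueError, match=">= 6"):
            summarize_species(coords)
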