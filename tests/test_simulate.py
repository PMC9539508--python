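"""The synthetic-data generator: design structure, reproducibility, ground truth."""

import numpy as np
import pandas as pd
import pytest

from revegrowth.simulate import (
    ConfigError,
    SimConfig,
    TruthSet,
    default_truth,
    generate_landscape,
    generate_species_pool,
    simulate_dataset,
    simulate_growth,
)


def tiny_config(**over):
    base = dict(
        n_plantings=12,
        n_subregions=3,
        n_species_per_genus=(8, 10),
        n_other_species=6,
        plots_per_planting_mean=2.5,
        seed=1,
    )
    base.update(over)
    return SimConfig(**base)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "over",
        [
            {"n_plantings": 0},
            {"moisture_range": (0.0, 0.8)},
            {"moisture_range": (0.9, 0.3)},
            {"radiation_moisture_corr": -1.0},
            {"age_min": -2.0},
        ],
    )
    def test_invalid_configs_rejected(self, over):
        with pytest.raises(ConfigError):
            tiny_config(**over).validate()

    def test_negative_variance_rejected(self):
        with pytest.raises(ConfigError):
            TruthSet(beta={}, sigma2_subregion=-0.1, sigma2_planting=0, sigma2_plot=0,
                     sigma2_species=0, sigma2_resid=0.1)


class TestSpeciesPool:
    def test_zero_sd_collapses_to_genus_mean(self):
        cfg = tiny_config()
        for genus in cfg.trait_distributions:
            cfg.trait_distributions[genus]["sla"] = (np.log(5000.0), 0.0)
        pool = generate_species_pool(cfg)
        acacias = pool[pool["genus"] == "Acacia"]
        np.testing.assert_allclose(acacias["sla"], 5000.0)

    def test_reproducible_under_fixed_seed(self):
        p1 = generate_species_pool(tiny_config())
        p2 = generate_species_pool(tiny_config())
        pd.testing.assert_frame_equal(p1, p2)

    def test_large_sample_log_mean_matches_configuration(self):
        cfg = tiny_config(n_species_per_genus=(10000, 10000), n_other_species=0)
        pool = generate_species_pool(cfg)
        mu, sd = cfg.trait_distributions["Acacia"]["sla"]
        logs = np.log(pool.loc[pool["genus"] == "Acacia", "sla"])
        se = sd / np.sqrt(len(logs))
        assert abs(logs.mean() - mu) < 3 * se

    def test_genus_trait_distributions_overlap(self):
        pool = generate_species_pool(tiny_config(n_species_per_genus=(40, 40)))
        a = pool.loc[pool["genus"] == "Acacia", "max_height"]
        e = pool.loc[pool["genus"] == "Eucalyptus", "max_height"]
        assert a.max() > e.min() and e.max() > a.min()

    def test_focal_species_complete(self):
        pool = generate_species_pool(tiny_config())
        focal = pool[pool["genus"].isin(["Acacia", "Eucalyptus"])]
        assert focal[["sla", "wood_density", "max_height"]].notna().all().all()


@pytest.fixture(scope="module")
def landscape():
    return generate_landscape(tiny_config())


class TestLandscape:
    def test_referential_integrity(self, landscape):
        assert landscape.plots["planting_id"].isin(landscape.plantings["planting_id"]).all()
        for col, table in [
            ("plot_id", landscape.plots),
            ("planting_id", landscape.plantings),
        ]:
            assert landscape.plants[col].isin(table[col]).all()
        assert landscape.plants["species"].isin(landscape.species_traits["species"]).all()
        # subregion of each plant matches its planting's subregion
        sub = landscape.plantings.set_index("planting_id")["subregion_id"]
        assert (
            landscape.plants["subregion_id"].to_numpy()
            == sub.loc[landscape.plants["planting_id"]].to_numpy()
        ).all()

    def test_ages_within_stated_range(self, landscape):
        ages = landscape.plantings["age_yr"]
        assert ages.between(4.0, 33.0).all()

    def test_plot_areas_positive_below_400(self, landscape):
        assert (landscape.plots["area_m2"] > 0).all()
        assert (landscape.plots["area_m2"] < 400.0).all()

    def test_every_plot_occupied(self, landscape):
        counts = landscape.plants.groupby("plot_id")["species"].nunique()
        assert counts.reindex(landscape.plots["plot_id"]).ge(1).all()

    def test_moisture_radiation_correlation(self):
        cfg = tiny_config(
            n_plantings=500,
            plots_per_planting_mean=1.0,
            plants_per_plot_mean=12.0,
            plants_per_plot_sd=3.0,
            radiation_moisture_corr=-0.69,
            seed=0,
        )
        land = generate_landscape(cfg)
        r = np.corrcoef(land.plantings["moisture"], land.plantings["radiation"])[0, 1]
        assert -0.75 < r < -0.63

    def test_moisture_quantiles_near_study_values(self):
        land = generate_landscape(tiny_config(n_plantings=400, plots_per_planting_mean=1.0,
                                              plants_per_plot_mean=12.0, plants_per_plot_sd=3.0))
        q10, q90 = np.quantile(land.plantings["moisture"], [0.1, 0.9])
        assert q10 == pytest.approx(0.27, abs=0.03)
        assert q90 == pytest.approx(0.76, abs=0.03)


class TestSimulateGrowth:
    def test_noise_free_limit_equals_linear_predictor(self):
        truth = TruthSet(beta={"intercept": 1.0}, sigma2_subregion=0, sigma2_planting=0,
                         sigma2_plot=0, sigma2_species=0, sigma2_resid=0)
        ds = simulate_growth(generate_landscape(tiny_config()), truth, seed=5)
        rgr = ds.plants["rgr_true"].dropna()
        assert len(rgr) > 100
        np.testing.assert_allclose(rgr, 1.0, atol=1e-12)

    def test_intercept_plus_small_noise_centers_correctly(self):
        truth = TruthSet(beta={"intercept": 1.0}, sigma2_subregion=0.01, sigma2_planting=0.01,
                         sigma2_plot=0.01, sigma2_species=0.01, sigma2_resid=0.01)
        ds = simulate_growth(generate_landscape(tiny_config(n_plantings=40)), truth, seed=6)
        rgr = ds.plants["rgr_true"].dropna()
        se = rgr.std() / np.sqrt(len(rgr))
        # grouped draws inflate the SE of the mean beyond the iid estimate
        assert abs(rgr.mean() - 1.0) < 3 * np.sqrt(se**2 + 4 * 0.01 / 40)

    def test_reproducible_under_fixed_seed(self):
        land = generate_landscape(tiny_config())
        d1 = simulate_growth(land, default_truth(), seed=9)
        d2 = simulate_growth(land, default_truth(), seed=9)
        pd.testing.assert_series_equal(d1.plants["rgr_true"], d2.plants["rgr_true"])

    def test_unknown_truth_term_rejected_by_name(self):
        truth = default_truth()
        truth.beta["not_a_term"] = 1.0
        with pytest.raises(ConfigError, match="not_a_term"):
            simulate_growth(generate_landscape(tiny_config()), truth, seed=1)

    def test_realized_intercepts_match_truth_variances(self):
        truth = default_truth()
        ds = simulate_dataset(SimConfig(n_plantings=150, n_subregions=8, seed=3), truth)
        realized = ds.realized_effects["planting"]
        sd = realized.std()
        target = np.sqrt(truth.sigma2_planting)
        assert sd == pytest.approx(target, rel=0.25)  # chi-distribution MC slack

    def test_pipeline_recovers_simulated_growth_exactly(self, small_dataset, small_frame):
        truth_rgr = small_dataset.plants.set_index("plant_id")["rgr_true"]
        got = pd.Series(
            small_frame.data["rgr"].to_numpy(), index=small_frame.raw["plant_id"]
        )
        diff = (got - truth_rgr.loc[got.index]).abs().max()
        assert diff < 1e-12

    def test_biomass_filter_exercised(self, small_frame):
        assert small_frame.n_excluded_small > 0


class TestDatasetIO:
    def test_round_trip_through_csv(self, tmp_path, small_dataset):
        small_dataset.write(tmp_path)
        back = type(small_dataset).read(tmp_path)
        assert len(back.plants) == len(small_dataset.plants)
        assert back.truth is not None
        assert back.truth.beta == small_dataset.truth.beta
        np.testing.assert_allclose(
            back.plantings["moisture"], small_dataset.plantings["moisture"]
        )
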