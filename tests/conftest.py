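import numpy as np
import pandas as pd
import pytest

from revegrowth import SimConfig, build_model_frame, default_truth, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A small simulated landscape with growth under the default truth."""
    cfg = SimConfig(
        n_plantings=25,
        n_subregions=5,
        n_species_per_genus=(15, 25),
        n_other_species=12,
        plots_per_planting_mean=3.0,
        seed=42,
    )
    return simulate_dataset(cfg, default_truth())


@pytest.fixture(scope="session")
def small_frame(small_dataset):
    return build_model_frame(small_dataset)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def species_pool_frame():
    """A tiny trait table with known missingness for interpolation tests."""
    return pd.DataFrame(
        {
            "species": ["a1", "a2", "a3", "b1", "b2", "c1"],
            "genus": ["Acacia", "Acacia", "Acacia", "Hakea", "Hakea", "Callitris"],
            "sla": [8.0, 12.0, np.nan, 9.0, np.nan, np.nan],
            "wood_density": [0.7, 0.8, 0.75, np.nan, 0.6, 0.5],
            "max_height": [10.0, 20.0, 15.0, 5.0, 4.0, np.nan],
        }
    )
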