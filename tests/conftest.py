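import numpy as np
import pandas as pd
import pytest
from hypothesis import settings as hyp_settings

from islandveg.synthdata import SimulationConfig, simulate_archipelago
from islandveg.vegdata import CommunityMatrix

hyp_settings.register_profile("deterministic", derandomize=True, deadline=None)
hyp_settings.load_profile("deterministic")


@pytest.fixture
def toy_community() -> CommunityMatrix:
    """Four plots, five species, two islands in two regions."""
    cover = pd.DataFrame(
        {
            "sp1": [0.375, 0.025, 0.0, 0.0],
            "sp2": [0.10, 0.205, 0.0, 0.005],
            "sp3": [0.0, 0.025, 0.625, 0.10],
            "sp4": [0.0, 0.0, 0.205, 0.375],
            "sp5": [0.025, 0.0, 0.0, 0.025],
        },
        index=["p1", "p2", "p3", "p4"],
    )
    meta = pd.DataFrame(
        {
            "region": ["A", "A", "B", "B"],
            "island": ["A-1", "A-1", "B-1", "B-2"],
            "habitat": ["grassland"] * 4,
        },
        index=cover.index,
    )
    return CommunityMatrix(cover, meta)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """Reduced archipelago for fast integration tests."""
    return SimulationConfig(
        n_regions=3,
        islands_per_region=5,
        plots_per_habitat=2,
        pools={"rocky_shore": 45, "grassland": 45, "forest": 35},
        n_indicators=5,
    )


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return simulate_archipelago(small_config, seed=11)


def coenocline(
    n_plots: int,
    n_species: int,
    span: float,
    tolerance: float = 1.0,
    noise: float = 0.2,
    margin: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Gaussian-response community along a single gradient (test helper)."""
    rng = np.random.default_rng(seed)
    grad = np.linspace(0.0, span, n_plots)
    opt = rng.uniform(-margin, span + margin, n_species)
    Y = np.exp(-((grad[:, None] - opt[None, :]) ** 2) / (2 * tolerance**2))
    Y *= rng.uniform(0.2, 1.0, n_species)
    if noise > 0:
        Y *= rng.lognormal(0.0, noise, (n_plots, n_species))
    Y[Y < 0.02] = 0.0
    return pd.DataFrame(
        Y,
        index=[f"p{i}" for i in range(n_plots)],
        columns=[f"s{j}" for j in range(n_species)],
    )
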