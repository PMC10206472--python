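import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import eggshell as es

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def three_taxon_tree() -> es.Phylogeny:
    return es.parse_newick("((A:1,B:1):0.5,C:1.5);")


@pytest.fixture
def balanced_oneway():
    """Balanced one-way layout (8 species x 5 eggs), identity covariance."""
    rng = np.random.default_rng(42)
    s, m = 8, 5
    species = np.repeat([f"sp{i}" for i in range(s)], m)
    y = np.repeat(rng.normal(0, 2.0, s), m) + rng.normal(0, 1.0, s * m)
    return pd.DataFrame({"y": y, "species": species}), s, m


@pytest.fixture
def toy_pairing() -> es.PairingSet:
    """Six pairs with hand-computable group contrast (host {1,1,2} vs random {5,5,6})."""
    pairs = pd.DataFrame(
        {
            "parasite_egg": [f"E{i}" for i in range(6)],
            "parasite_species": ["P"] * 6,
            "partner": ["x"] * 6,
            "pair_type": ["host"] * 3 + ["random"] * 3,
            "abs_difference": [1.0, 1.0, 2.0, 5.0, 5.0, 6.0],
        }
    )
    return es.PairingSet(pairs=pairs, trait="sa_nm", rng_seed=0)


@pytest.fixture
def mini_dataset() -> es.SyntheticDataset:
    """Deterministic small synthetic study used across pipeline tests."""
    config = es.SimulationConfig(
        n_species=12,
        n_parasites=4,
        eggs_per_species=4,
        sigma2_p=0.8,
        sigma2_e=0.2,
        trait_mean=1500.0,
        rng_seed=7,
    )
    # rescale to nm so the egg-table range checks are exercised realistically
    config.sigma2_p *= 250_000.0
    config.sigma2_e *= 250_000.0
    return es.simulate_dataset(config)
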