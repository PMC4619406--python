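import warnings

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import dynmod as dm

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")

# the NMF convergence warning is expected on tiny max_iter runs
warnings.filterwarnings("ignore", message="NMF did not reach tolerance")


@pytest.fixture(scope="session")
def small_scenario():
    """A scaled-down standard scenario: 300 genes, 25+15 samples."""
    cfg = dm.script_standard_scenario(
        n_genes=300,
        n_patient_samples_per_timestamp=25,
        n_control_samples=15,
        module_size=30,
        seed=42,
    )
    datasets, truth = dm.simulate_dataset(cfg)
    return cfg, datasets, truth


@pytest.fixture(scope="session")
def small_networks(small_scenario):
    cfg, datasets, _ = small_scenario
    return [
        dm.build_network(datasets[t].patients(), timestamp=t)
        for t in range(cfg.n_timestamps)
    ]


def random_catalog_pair(rng, n_genes=200, n_modules=15, min_size=5, max_size=40):
    """Two random module lists over a shared gene universe."""
    universe = np.array([f"g{i:03d}" for i in range(n_genes)], dtype=object)

    def one(tag, t):
        mods = []
        for j in range(n_modules):
            size = int(rng.integers(min_size, max_size + 1))
            sel = rng.choice(n_genes, size=size, replace=False)
            mods.append(
                dm.GeneModule(f"{tag}{j:02d}", t, frozenset(universe[sel]))
            )
        return mods

    return one("a", 0), one("b", 1)
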