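import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from chipdyn import SimulationParams, simulate_chip_signals, simulate_truth, simulate_universe
from chipdyn.config import PipelineConfig

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_params():
    return SimulationParams(n_genes=60, seed=7)


@pytest.fixture(scope="session")
def small_truth(small_params):
    annotations = simulate_universe(small_params)
    return simulate_truth(small_params, annotations)


@pytest.fixture(scope="session")
def small_signals(small_truth):
    return simulate_chip_signals(small_truth)


@pytest.fixture(scope="session")
def default_config():
    return PipelineConfig()


def noise_only_probes(n_genes: int, seed: int, noise_sd: float = 0.3) -> pd.DataFrame:
    """Signal-free probe table on the standard grid (one sample)."""
    grid = np.arange(-3250, 751, 100)
    rng = np.random.default_rng([seed, 4242])
    return pd.DataFrame(
        {
            "probe_id": [f"g{i:05d}_p{j:02d}" for i in range(n_genes) for j in range(len(grid))],
            "gene_id": np.repeat([f"g{i:05d}" for i in range(n_genes)], len(grid)),
            "offset": np.tile(grid, n_genes),
            "log2_ratio": rng.normal(0.0, noise_sd, n_genes * len(grid)),
        }
    )
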