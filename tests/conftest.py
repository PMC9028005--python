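import numpy as np
import pandas as pd
import pytest

from metareverse.io import ExpressionDataset
from metareverse.simulate import SimulationConfig, simulate_cohorts


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """Desk-scale study conditions shared by several tests."""
    return SimulationConfig(n_genes=400, n_de_genes=40, n_drugs=30,
                            n_planted_anti_drugs=3, seed=11)


@pytest.fixture(scope="session")
def small_cohorts(small_config):
    return simulate_cohorts(small_config)


def make_dataset(dataset_id="d1", n_genes=6, n_ctrl=3, n_case=3, seed=0,
                 shift=0.0):
    """Tiny hand-sized cohort for contract tests."""
    rng = np.random.default_rng(seed)
    genes = [f"g{i}" for i in range(n_genes)]
    samples = [f"{dataset_id}_c{i}" for i in range(n_ctrl)] + \
              [f"{dataset_id}_t{i}" for i in range(n_case)]
    X = rng.normal(7.0, 1.0, (n_genes, n_ctrl + n_case)) + shift
    matrix = pd.DataFrame(X, index=pd.Index(genes, name="gene"), columns=samples)
    manifest = pd.DataFrame({
        "sample_id": samples,
        "group": ["control"] * n_ctrl + ["case"] * n_case,
        "batch": dataset_id,
    })
    return ExpressionDataset(dataset_id=dataset_id, matrix=matrix,
                             manifest=manifest)


@pytest.fixture
def tiny_dataset():
    return make_dataset()
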