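import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from consensnet.synthetic import SimConfig, gen_regulatory_corpus

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    """A small but non-degenerate corpus: 500 genes, 5 nodes, 1 driver."""
    return SimConfig(
        n_genes=500,
        n_nodes=5,
        targets_per_node=25,
        datasets_per_node=(2, 3),
        background_rate=0.2,
        n_up_genes=50,
        n_down_genes=25,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_corpus(small_cfg):
    return gen_regulatory_corpus(small_cfg)


@pytest.fixture()
def toy_peak_table() -> pd.DataFrame:
    """Two datasets for one node; gene Y absent from dataset 2."""
    return pd.DataFrame(
        {
            "dataset_id": ["d1", "d1", "d2"],
            "node": ["Tf1", "Tf1", "Tf1"],
            "gene": ["X", "Y", "X"],
            "strength": [10.0, 12.0, 20.0],
        }
    )


def peak_table_from_strengths(strengths, node="Tf1") -> pd.DataFrame:
    """Single-dataset table with the given mean strengths (genes g0, g1, ...)."""
    genes = [f"g{i}" for i in range(len(strengths))]
    return pd.DataFrame(
        {
            "dataset_id": "d1",
            "node": node,
            "gene": genes,
            "strength": list(map(float, strengths)),
        }
    )
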