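import numpy as np
import pandas as pd
import pytest

from mireomics import simulate as sim


@pytest.fixture(scope="session")
def small_dataset():
    """A small planted microcosm dataset shared by pipeline-level tests."""
    design = sim.SimulationDesign(n_mags=12, days=(0, 7), seed=11)
    return sim.gen_expression_dataset(design)


@pytest.fixture(scope="session")
def methanogen_fixture():
    return sim.gen_methanogen_fixture(seed=0)


@pytest.fixture(scope="session")
def lcms_small():
    return sim.gen_lcms_dataset(
        n_parents=5, n_fragments_per_parent=2, n_independents=12, n_halogen=3, seed=3
    )


@pytest.fixture()
def tiny_counts():
    counts = pd.DataFrame(
        {
            "s1": [10, 0, 4, 50, 7],
            "s2": [20, 5, 0, 100, 14],
        },
        index=pd.Index([f"g{i}" for i in range(5)], name="gene_id"),
    )
    catalog = pd.DataFrame(
        {
            "gene_id": [f"g{i}" for i in range(5)],
            "mag_id": ["A", "A", "A", "B", "B"],
            "length_bp": [1000, 500, 2000, 1000, 700],
            "ko_id": ["K00001", "K00002", None, "K00001", None],
            "cazy_best_hit": [None, "GH13", None, None, None],
            "camper_id": [None] * 5,
        }
    )
    return counts, catalog


def rng(seed: int = 0) -> np.random.Generator:
    return np.random.default_rng(seed)
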