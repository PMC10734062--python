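import numpy as np
import pandas as pd
import pytest

from cernet.io import ExpressionMatrix
from cernet.simulate import SimulationConfig, generate_dataset

#: config of the bundled golden fixture; changing it invalidates the frozen
#: golden hashes in test_acceptance.py.
GOLDEN_CONFIG = {
    "simulate": {"seed": 1234, "n_planted_circuits": 10},
    "circuit_contrasts": ["WT_CM_vs_WT_iPSC"],
    "mrna_filter_set": "HEART_DEVELOPMENT",
}


def small_matrix(values, groups=None, scale="linear"):
    """Helper: matrix from a dict of sample -> value list, default grouping."""
    df = pd.DataFrame(values)
    df.index = [f"f{i}" for i in range(1, len(df) + 1)]
    if groups is None:
        n = df.shape[1]
        groups = pd.DataFrame(
            {
                "genotype": ["WT"] * n,
                "state": ["iPSC"] * n,
                "line_id": [f"W{i}" for i in range(1, n + 1)],
            },
            index=df.columns,
        )
    return ExpressionMatrix(df, groups, scale=scale)


@pytest.fixture(scope="session")
def default_bundle():
    """One seeded bundle at package defaults, shared across tests."""
    return generate_dataset(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def noisefree_bundle():
    """Noise-free world: sigma = 0, no line effects, exact +/-2 log2 effects."""
    return generate_dataset(
        SimulationConfig(
            seed=7, noise_sd=0.0, line_sd=0.0, diff_effect_sd=0.0, n_planted_circuits=5
        )
    )
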