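import numpy as np
import pandas as pd
import pytest

from disturbnet.io import AbundanceTable, PhaseDesign, default_design


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_table():
    data = pd.DataFrame(
        {
            "S1": [0.5, 0.3, 0.2],
            "S2": [0.6, 0.0, 0.4],
            "S3": [0.4, 0.35, 0.25],
            "S4": [0.5, 0.25, 0.25],
        },
        index=["taxA", "taxB", "taxC"],
    )
    return AbundanceTable(data)


@pytest.fixture
def design_12_3_15():
    return default_design()


def random_table(rng, n_taxa=20, n_samples=30, zero_frac=0.15):
    """A random proportions table with scattered exact zeros."""
    vals = rng.gamma(2.0, 1.0, size=(n_taxa, n_samples))
    vals[rng.random(vals.shape) < zero_frac] = 0.0
    # keep every column non-empty
    for k in range(n_samples):
        if vals[:, k].sum() == 0:
            vals[rng.integers(n_taxa), k] = 1.0
    vals = vals / vals.sum(axis=0)
    data = pd.DataFrame(
        vals,
        index=[f"t{i:03d}" for i in range(n_taxa)],
        columns=[f"S{k + 1}" for k in range(n_samples)],
    )
    return AbundanceTable(data)
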