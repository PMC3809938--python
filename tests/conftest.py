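import numpy as np
import pandas as pd
import pytest

from imputebench import GeneratorConfig, MaskedMatrix, generate_dataset


@pytest.fixture(scope="session")
def tiny_config():
    """Small factorial design: 2 sites x 4 pools x 5 replicates, 60 probe sets."""
    return GeneratorConfig(n_probe_sets=60, n_sites=2, seed=1234)


@pytest.fixture(scope="session")
def tiny_dataset(tiny_config):
    return generate_dataset(tiny_config)


@pytest.fixture()
def rank1_matrix():
    """Exact rank-1 positive 50 x 5 matrix."""
    rng = np.random.default_rng(7)
    u = np.exp(rng.normal(5.0, 1.0, 50))
    v = np.exp(rng.normal(0.0, 0.2, 5))
    return pd.DataFrame(np.outer(u, v),
                        index=[f"g{i}" for i in range(50)],
                        columns=[f"s{j}" for j in range(5)])


def mask_cells(values: np.ndarray, cells) -> MaskedMatrix:
    """Build a MaskedMatrix with exactly the given (row, col) cells missing."""
    mask = np.zeros(values.shape, dtype=bool)
    for g, s in cells:
        mask[g, s] = True
    return MaskedMatrix(values=np.where(mask, np.nan, values), mask=mask, truth=values)
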