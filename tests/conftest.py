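import numpy as np
import pandas as pd
import pytest

from fuzzpat import MixedModeTable, generate


@pytest.fixture
def small_mixed_table() -> MixedModeTable:
    """Six samples, one categorical + two continuous attributes."""
    df = pd.DataFrame(
        {
            "G1": ["a", "a", "b", "b", "a", "b"],
            "G2": [0.1, 0.2, 0.9, 1.0, 0.15, 0.8],
            "G3": [5.0, 4.0, 3.0, 2.0, 1.0, 0.0],
        }
    )
    return MixedModeTable.from_dataframe(df)


@pytest.fixture(scope="session")
def synthetic_dataset():
    """One default-condition synthetic dataset, shared across tests."""
    return generate(seed=42)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(7)
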