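import numpy as np
import pandas as pd
import pytest

from capturebias import ScenarioConfig


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_config():
    """A scaled-down scenario that keeps unit tests fast."""
    return ScenarioConfig(population_size=600, sample_size=60, seed=7)


def make_population(genos, infected=None, generation="parent", start_id=0):
    """Hand-built population table for targeted metric/sampling tests."""
    n = len(genos)
    infected = [False] * n if infected is None else infected
    return pd.DataFrame(
        {
            "id": np.arange(start_id, start_id + n, dtype=np.int64),
            "geno": np.asarray(genos, dtype=np.int8),
            "infected": np.asarray(infected, dtype=bool),
            "generation": generation,
            "mother_id": np.full(n, -1, dtype=np.int64),
            "father_id": np.full(n, -1, dtype=np.int64),
        }
    )
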