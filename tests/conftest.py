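import numpy as np
import pandas as pd
import pytest

from glycosecretome.differential_stats import QuantTable
from glycosecretome.synthetic_data import SyntheticConfig, simulate_glycoproteome


def make_quant_table(rows, samples, meta=None):
    """Build a QuantTable from {feature: [intensities]} and sample ids."""
    values = pd.DataFrame.from_dict(rows, orient="index", columns=samples)
    if meta is None:
        meta = pd.DataFrame(index=pd.Index(samples, name="sample_id"))
    return QuantTable(values=values, meta=meta)


@pytest.fixture(scope="session")
def default_config():
    return SyntheticConfig(seed=7)


@pytest.fixture(scope="session")
def glyco_sim(default_config):
    """One simulated glycoproteome shared across tests (read-only)."""
    return simulate_glycoproteome(default_config)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
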