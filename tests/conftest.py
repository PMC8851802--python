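import numpy as np
import pandas as pd
import pytest

from u5dgap.synthetic_data import SimConfig, generate


@pytest.fixture(scope="session")
def desk_dataset():
    """One draw from the default desk-scale scenario plus its truth."""
    records, truth = generate(SimConfig(seed=20240))
    return records, truth


@pytest.fixture()
def toy_children():
    """Tiny hand-written canonical child table: 2 clusters, 1 country."""
    return pd.DataFrame({
        "child_id": [f"k{i}" for i in range(8)],
        "country": ["C00"] * 8,
        "cluster_id": ["cl0"] * 4 + ["cl1"] * 4,
        "sex": ["male", "female"] * 4,
        "died_u5": [1, 0, 0, 0, 1, 1, 0, 0],
        "weight": [1.0, 3.0, 1.0, 1.0, 2.0, 1.0, 1.0, 1.0],
        "maternal_education": ["none", "primary", "none", "secondary+"] * 2,
        "wealth_quintile": ["poorest", "richer", "poorer", "middle"] * 2,
        "media_access": ["no", "yes", "yes", "yes"] * 2,
        "maternal_employment": ["unemployed", "employed"] * 4,
    })


@pytest.fixture()
def rng():
    return np.random.default_rng(99)
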