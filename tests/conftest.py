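import warnings

import numpy as np
import pandas as pd
import pytest

from rhizonet.synthetic import ModuleSpec, SyntheticScenario, generate_counts


@pytest.fixture(scope="session")
def small_tables():
    """A compact planted-structure dataset shared across tests."""
    scenario = SyntheticScenario(
        n_taxa=80,
        n_samples_per_group=6,
        module_spec=(
            ModuleSpec(n_members=5, loading=0.95, focal=True),
            ModuleSpec(n_members=6, loading=0.85),
        ),
        n_positive_pairs=5,
        n_baseline_negative_pairs=2,
        seed=7,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        counts, tax, meta = generate_counts(scenario)
    return scenario, counts, tax, meta


@pytest.fixture
def toy_counts():
    return pd.DataFrame(
        np.array([[5, 10, 0], [5, 0, 4], [0, 0, 4]]),
        index=pd.Index(["t1", "t2", "t3"], name="taxon_id"),
        columns=pd.Index(["s1", "s2", "s3"], name="sample_id"),
    )
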