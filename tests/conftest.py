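import numpy as np
import pandas as pd
import pytest

from xyloherit import PopulationConfig, simulate_population


@pytest.fixture(scope="session")
def default_stand():
    """The 47-tree / 11-spatial-group / 9-clonal-group study layout."""
    return simulate_population(PopulationConfig(seed=42))


@pytest.fixture()
def balanced_toy():
    """Two groups of two observations, {0,2} and {4,6}.

    Closed-form one-way ANOVA: MSW = 2, MSB = 16, n0 = 2, so the REML /
    method-of-moments variance components are sigma2_between = 7 and
    sigma2_within = 2; the total sample variance is 20/3.
    """
    return pd.DataFrame({
        "y": [0.0, 2.0, 4.0, 6.0],
        "tree_id": ["a1", "a2", "b1", "b2"],
        "year": [1, 1, 1, 1],
        "group": ["a", "a", "b", "b"],
    })


@pytest.fixture()
def rng():
    return np.random.default_rng(20201021)
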