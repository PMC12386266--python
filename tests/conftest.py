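import numpy as np
import pandas as pd
import pytest

import sarcomark as sm


@pytest.fixture(scope="session")
def small_dataset():
    """A 300-gene five-group simulated study reused across read-only tests."""
    cfg = sm.SimulationConfig(n_genes=300, seed=1)
    cm, phen, truth = sm.simulate_dataset(cfg)
    return cfg, cm, phen, truth


@pytest.fixture(scope="session")
def small_de(small_dataset):
    """TMM factors, dispersions and the aging + intervention DE tables."""
    _, cm, _, _ = small_dataset
    factors = sm.tmm_factors(cm)
    common, tagwise = sm.estimate_dispersion(cm, factors)
    de_aging = sm.de_test(cm, factors, tagwise, ("Middle", "Mature"))
    de_int = {
        g: sm.de_test(cm, factors, tagwise, (g, "Middle")) for g in ("ALL", "LCOL", "HCOL")
    }
    return factors, common, tagwise, de_aging, de_int


@pytest.fixture()
def toy_counts():
    """3 genes x 5 samples, two groups."""
    counts = pd.DataFrame(
        np.array([[10, 20, 30, 40, 50], [5, 5, 5, 5, 5], [100, 90, 80, 70, 60]]),
        index=["GeneA", "GeneB", "GeneC"],
        columns=[f"s{i}" for i in range(5)],
    )
    groups = pd.Series(["A", "A", "A", "B", "B"], index=counts.columns)
    return sm.CountMatrix(counts, groups)
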