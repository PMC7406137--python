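import numpy as np
import pandas as pd
import pytest

from lignosom.simulate import SimConfig, simulate


@pytest.fixture(scope="session")
def study():
    """One default-scale synthetic study shared across read-only tests."""
    return simulate(SimConfig(seed=123))


@pytest.fixture(scope="session")
def small_study():
    """A fast, small study for end-to-end style unit tests."""
    return simulate(SimConfig(n_genes_per_species=200, n_modules=4,
                              module_size=15, seed=5))


@pytest.fixture
def tiny_counts():
    idx = pd.Index(["g1", "g2", "g3"], name="gene_id")
    return pd.DataFrame(
        [[10, 20, 30, 40], [100, 200, 300, 400], [5, 10, 15, 20]],
        index=idx, columns=["s1", "s2", "s3", "s4"])


@pytest.fixture
def tiny_info():
    rows = [("s1", "sp", "maltose", 1), ("s2", "sp", "maltose", 2),
            ("s3", "sp", "avicel", 1), ("s4", "sp", "avicel", 2)]
    info = pd.DataFrame(rows, columns=["sample_id", "species", "substrate",
                                       "replicate"]).set_index("sample_id")
    info["batch"] = info["species"]
    return info
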