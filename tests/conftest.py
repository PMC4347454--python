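import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from picalink import GenotypeTable, SyntheticConfig, generate_linked_dataset

settings.register_profile("ci", derandomize=True, max_examples=25,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_linked():
    """Modest-size linked cohort shared across tests (read-only)."""
    cfg = SyntheticConfig(seed=11, n_voxels=600, n_snps=300,
                          n_components_fa=5, n_components_snp=4)
    return generate_linked_dataset(cfg)


def make_table(calls, subjects=None) -> GenotypeTable:
    calls = np.asarray(calls, dtype=float)
    n, p = calls.shape
    subjects = subjects or [f"S{i}" for i in range(n)]
    snps = pd.DataFrame({
        "snp": [f"rs{j}" for j in range(p)],
        "chrom": 1,
        "pos": np.arange(1, p + 1),
        "a1": "A",
        "a2": "G",
    })
    return GenotypeTable(subjects=subjects, snps=snps, calls=calls)


@pytest.fixture
def table_factory():
    return make_table
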