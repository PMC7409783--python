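import numpy as np
import pandas as pd
import pytest

from refstab import CqDataset


def make_dataset(cq, samples=None, genes=None, groups=None):
    """Collapsed CqDataset from a 2-D array (samples x genes)."""
    cq = np.asarray(cq, dtype=float)
    n_s, n_g = cq.shape
    samples = samples or [f"s{i + 1}" for i in range(n_s)]
    genes = genes or [f"g{j + 1}" for j in range(n_g)]
    df = pd.DataFrame(cq, index=samples, columns=genes)
    if groups is not None:
        groups = pd.Series(list(groups), index=samples, name="group")
    return CqDataset.from_collapsed(df, groups=groups)


@pytest.fixture
def two_group_panel():
    """4 genes x (2+2 samples), small enough to verify by hand."""
    rng = np.random.default_rng(7)
    base = np.array([20.0, 22.0, 24.0, 26.0])
    cq = base + rng.normal(0, 0.2, size=(4, 4))
    return make_dataset(cq, groups=["a", "a", "b", "b"])


@pytest.fixture
def rng():
    return np.random.default_rng(123)
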