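import numpy as np
import pandas as pd
import pytest

from ecoassembly.tables import OtuTable


@pytest.fixture
def small_table() -> OtuTable:
    """3 samples x 4 taxa with hand-checkable counts."""
    counts = pd.DataFrame(
        [[6, 2, 0, 1], [2, 2, 5, 0], [0, 0, 3, 9]],
        index=["s1", "s2", "s3"],
        columns=["t1", "t2", "t3", "t4"],
    )
    return OtuTable(counts)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_counts(n_samples=8, n_taxa=15, seed=0, depth=200) -> OtuTable:
    rng = np.random.default_rng(seed)
    p = rng.dirichlet(np.ones(n_taxa))
    counts = np.vstack([rng.multinomial(depth, p) for _ in range(n_samples)])
    return OtuTable(
        pd.DataFrame(
            counts,
            index=[f"s{i}" for i in range(n_samples)],
            columns=[f"t{j}" for j in range(n_taxa)],
        )
    )


@pytest.fixture
def random_table() -> OtuTable:
    return random_counts()
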