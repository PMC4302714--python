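import numpy as np
import pandas as pd
import pytest

from wheatsen.model import CountMatrix, full_design


@pytest.fixture(scope="session")
def design36():
    """The full 3x3x4 study design."""
    return full_design(4)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260924)


def make_count_matrix(counts: np.ndarray, design=None) -> CountMatrix:
    """Wrap a loci x 36 integer array in a CountMatrix over the full design."""
    if design is None:
        design = full_design(4)
    counts = np.asarray(counts)
    df = pd.DataFrame(
        counts,
        index=[f"L{i}" for i in range(counts.shape[0])],
        columns=[s.sample_id for s in design],
    )
    return CountMatrix(df, design)
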