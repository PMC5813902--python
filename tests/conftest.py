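import numpy as np
import pandas as pd
import pytest

from glandprot import SpectralCountTable
from glandprot.samples import ATOMIC_SAMPLE_NAMES


def random_count_table(rng: np.random.Generator, n_proteins: int = 30) -> SpectralCountTable:
    """Random valid six-sample table; heavy-tailed counts like real SC data."""
    counts = rng.negative_binomial(1, 0.05, size=(n_proteins, 6))
    df = pd.DataFrame(
        counts,
        index=pd.Index([f"prot|{i:04d}" for i in range(n_proteins)], name="accession"),
        columns=list(ATOMIC_SAMPLE_NAMES),
    )
    df.insert(0, "description", [f"protein {i}" for i in range(n_proteins)])
    return SpectralCountTable(df)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260925)


@pytest.fixture
def six_sample_table() -> SpectralCountTable:
    """Small hand-built six-sample table with known structure."""
    return SpectralCountTable.from_records(
        ["A", "B", "C", "D"],
        {
            "nPcG": [10, 0, 3, 0],
            "fPcG": [20, 0, 4, 0],
            "nTG": [1, 50, 3, 0],
            "fTG": [2, 40, 5, 0],
            "nMG": [0, 0, 4, 2],
            "fMG": [1, 0, 3, 0],
        },
    )
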