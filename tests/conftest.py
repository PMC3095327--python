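import numpy as np
import pandas as pd
import pytest

from vitisugar import Alphabet, ScoringScheme, SequenceRecord, default_library


@pytest.fixture(scope="session")
def library():
    return default_library()


@pytest.fixture(scope="session")
def scheme():
    return ScoringScheme()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def protein(id_: str, residues: str) -> SequenceRecord:
    return SequenceRecord(id=id_, residues=residues, alphabet=Alphabet.protein)


@pytest.fixture(scope="session")
def truth_matrix():
    """A small known expression matrix, everything above detection."""
    rng = np.random.default_rng(99)
    genes = [f"g{i + 1:02d}" for i in range(10)]
    conditions = ["young_leaf", "mature_leaf", "root", "stem"]
    return pd.DataFrame(
        rng.uniform(0.05, 0.6, (len(genes), len(conditions))),
        index=genes,
        columns=conditions,
    )
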