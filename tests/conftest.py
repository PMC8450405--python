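import numpy as np
import pandas as pd
import pytest

from gagmap import ExpressionMatrix, load_kb


@pytest.fixture(scope="session")
def kb():
    return load_kb()


@pytest.fixture
def tiny_matrix():
    """3 genes x 2 tissue-style samples."""
    df = pd.DataFrame(
        {"liver": [5.0, 0.0, 2.0], "lung": [10.0, 3.0, 2.0]},
        index=pd.Index(["XYLT1", "XYLT2", "EXT1"], name="gene"),
    )
    return ExpressionMatrix(df, {"liver": "liver", "lung": "lung"})


@pytest.fixture
def random_full_matrix(kb):
    """All 66 KB genes x 10 samples, uniform random TPM."""
    rng = np.random.default_rng(7)
    genes = kb.genes
    df = pd.DataFrame(
        rng.uniform(0.0, 100.0, size=(len(genes), 10)),
        index=pd.Index(genes, name="gene"),
        columns=[f"s{i}" for i in range(10)],
    )
    return ExpressionMatrix(df, {c: "tissue" for c in df.columns})
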