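import numpy as np
import pandas as pd
import pytest

from sexdim.io_formats import ExpressionMatrix, SampleMetadata


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_matrix(rng):
    """5 genes x 6 samples log2 matrix with annotation."""
    ids = [f"g{i}" for i in range(5)]
    samples = [f"s{j}" for j in range(6)]
    values = pd.DataFrame(rng.uniform(0, 10, size=(5, 6)), index=ids, columns=samples)
    return ExpressionMatrix(
        values,
        scale="log2",
        gene_symbols=pd.Series([f"Sym{i}" for i in range(5)], index=ids),
        gene_chromosome=pd.Series(["1", "2", "X", "Y", "1"], index=ids),
    )


@pytest.fixture
def paired_metadata():
    """6 samples: 3 F + 3 M macrophages in one dataset, ages alternating."""
    rows = []
    for sex in ("F", "M"):
        for rep in (1, 2, 3):
            rows.append(
                {
                    "sample_id": f"s{'012'.index(str(rep - 1)) + (0 if sex == 'F' else 3)}",
                    "sex": sex,
                    "cell_type": "MF",
                    "dataset": "A",
                    "age_group": f"age{rep % 2}",
                    "replicate": rep,
                }
            )
    return SampleMetadata(pd.DataFrame(rows).set_index("sample_id"))
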