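import numpy as np
import pandas as pd
import pytest

from devgrn.containers import ExpressionMatrix, SampleMetadata


@pytest.fixture
def toy_expr():
    """3 genes x 4 samples with simple integer values."""
    data = pd.DataFrame(
        [[1.0, 2.0, 3.0, 4.0],
         [5.0, 5.0, 5.0, 5.0],
         [0.0, 1.0, 0.0, 2.0]],
        index=["g1", "g2", "g3"],
        columns=["s0", "s1", "s2", "s3"],
    )
    return ExpressionMatrix(data, unit_label="RPKM")


@pytest.fixture
def toy_meta():
    return SampleMetadata(pd.DataFrame({
        "sample_id": ["s0", "s1", "s2", "s3"],
        "time_hpf": [0.0, 2.0, 4.0, 6.0],
        "series_id": ["a"] * 4,
        "replicate": [1] * 4,
    }))


def expr_from(values, genes=None, samples=None, unit=""):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples), unit)


def meta_for(samples, times, series="a", replicates=None):
    n = len(samples)
    return SampleMetadata(pd.DataFrame({
        "sample_id": list(samples),
        "time_hpf": list(times),
        "series_id": [series] * n if isinstance(series, str) else list(series),
        "replicate": replicates or [1] * n,
    }))
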