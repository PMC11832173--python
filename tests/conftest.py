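import numpy as np
import pytest

from mechanomics.datasets import ExpressionDataset


@pytest.fixture
def tiny_dataset():
    """3 genes x 4 samples, two groups, already in a normalized state."""
    return ExpressionDataset(
        name="tiny",
        genes=["G1", "G2", "G3"],
        samples=["s1", "s2", "s3", "s4"],
        values=np.array(
            [
                [1.0, 1.0, 3.0, 3.0],
                [3.0, 3.0, 1.0, 1.0],
                [0.5, 1.5, 0.5, 1.5],
            ]
        ),
        sample_groups={"s1": "soft", "s2": "soft", "s3": "stiff", "s4": "stiff"},
        norm_state="log1p",
    )


def make_dataset(values, groups=None, name="ds", norm_state="zscore"):
    """Dataset from a plain array; groups defaults to half/half soft-stiff."""
    values = np.asarray(values, dtype=float)
    g, n = values.shape
    genes = [f"G{i + 1}" for i in range(g)]
    samples = [f"s{j + 1}" for j in range(n)]
    if groups is None:
        groups = ["soft"] * (n // 2) + ["stiff"] * (n - n // 2)
    return ExpressionDataset(
        name=name,
        genes=genes,
        samples=samples,
        values=values,
        sample_groups=dict(zip(samples, groups)),
        norm_state=norm_state,
    )


@pytest.fixture
def make_ds():
    return make_dataset
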