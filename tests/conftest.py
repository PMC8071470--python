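import numpy as np
import pandas as pd
import pytest

from functionome.data_io import ExpressionMatrix, GeneSet, GeneSetCollection


@pytest.fixture
def abc_set() -> GeneSet:
    return GeneSet(set_id="SET_ABC", name="abc", genes=("A", "B", "C"))


@pytest.fixture
def tiny_matrix() -> ExpressionMatrix:
    """3 genes x 5 samples; controls all ordered A<B<C, one reversed case."""
    values = pd.DataFrame(
        {
            "ctrl_0": [1.0, 2.0, 3.0],
            "ctrl_1": [10.0, 20.0, 30.0],
            "ctrl_2": [0.1, 0.2, 0.3],
            "case_same": [5.0, 6.0, 7.0],
            "case_rev": [7.0, 6.0, 5.0],
        },
        index=["A", "B", "C"],
    )
    groups = pd.Series(
        {"ctrl_0": "control", "ctrl_1": "control", "ctrl_2": "control",
         "case_same": "case", "case_rev": "case"}
    )
    return ExpressionMatrix(values=values, groups=groups)


@pytest.fixture
def tiny_collection(abc_set) -> GeneSetCollection:
    return GeneSetCollection(sets=[abc_set])


def random_cohort_frame(rng: np.random.Generator, n_genes: int, n_samples: int,
                        n_controls: int) -> ExpressionMatrix:
    genes = [f"g{i}" for i in range(n_genes)]
    samples = [f"s{i}" for i in range(n_samples)]
    values = pd.DataFrame(rng.normal(size=(n_genes, n_samples)), index=genes, columns=samples)
    groups = pd.Series(
        ["control"] * n_controls + ["case"] * (n_samples - n_controls), index=samples
    )
    return ExpressionMatrix(values=values, groups=groups)
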