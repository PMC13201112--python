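import numpy as np
import pytest

from markermeta import ExpressionDataset, datasets


@pytest.fixture(scope="session")
def plk1_tables():
    return datasets.load_plk1_contingency()


@pytest.fixture(scope="session")
def mycn_tables():
    return datasets.load_mycn_contingency()


@pytest.fixture(scope="session")
def correlation_rows():
    return datasets.load_plk1_mycn_correlations()


def make_dataset(values, group, batch=None, genes=None, dataset_id="ds",
                 log_transformed=False):
    """Small helper to build an ExpressionDataset from plain lists/arrays."""
    values = np.atleast_2d(np.asarray(values, dtype=float))
    n_genes, n_samples = values.shape
    genes = genes or [f"G{i}" for i in range(n_genes)]
    batch = batch if batch is not None else ["b1"] * n_samples
    return ExpressionDataset(
        dataset_id=dataset_id,
        genes=list(genes),
        samples=[f"S{i}" for i in range(n_samples)],
        values=values,
        group=np.asarray(group, dtype=object),
        batch=np.asarray(batch, dtype=object),
        log_transformed=log_transformed,
    )


@pytest.fixture
def dataset_factory():
    return make_dataset
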