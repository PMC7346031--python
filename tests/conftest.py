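import numpy as np
import pandas as pd
import pytest

from glycochol import ExpressionMatrix, SimConfig, generate_cohort, write_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small but complete synthetic cohort shared across test modules."""
    cfg = SimConfig(n_samples=150, n_background_genes=80, seed=7)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_cohort_dir(small_cohort, tmp_path_factory):
    d = tmp_path_factory.mktemp("cohort")
    write_cohort(small_cohort, d)
    return d


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def standardized_matrix(values: np.ndarray, genes=None, samples=None) -> ExpressionMatrix:
    """Wrap a raw array as a standardized-scale matrix (test helper)."""
    n_genes, n_samples = values.shape
    genes = genes or [f"G{i}" for i in range(n_genes)]
    samples = samples or [f"S{j}" for j in range(n_samples)]
    return ExpressionMatrix(
        values=pd.DataFrame(values, index=genes, columns=samples),
        scale_tag="standardized",
    )
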