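import numpy as np
import pandas as pd
import pytest

from senescore import CohortConfig, generate_cohort, normalize, score_all
from senescore.containers import CountMatrix


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced but fully structured cohort shared across read-only tests."""
    return generate_cohort(CohortConfig(n_samples=250, n_genes=300, seed=7))


@pytest.fixture(scope="session")
def small_scores(small_cohort):
    expr = normalize(small_cohort.counts)
    return expr, score_all(expr, small_cohort.gene_sets)


@pytest.fixture
def toy_counts():
    """4 genes x 3 samples, all positive (the frozen-oracle matrix)."""
    values = pd.DataFrame(
        [[10, 20, 15], [100, 180, 120], [5, 12, 8], [50, 90, 60]],
        index=pd.Index(["g1", "g2", "g3", "g4"], name="gene_id"),
        columns=["s1", "s2", "s3"],
    )
    return CountMatrix(values=values)


def random_count_matrix(rng: np.random.Generator, n_genes=10, n_samples=5) -> CountMatrix:
    """Random positive integer counts (every gene positive in every sample)."""
    values = rng.integers(1, 500, size=(n_genes, n_samples))
    df = pd.DataFrame(
        values,
        index=[f"g{i}" for i in range(n_genes)],
        columns=[f"s{j}" for j in range(n_samples)],
    )
    return CountMatrix(values=df)
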