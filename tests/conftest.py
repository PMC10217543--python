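import numpy as np
import pytest

from goafs.synthetic import SyntheticSpec, FeatureTable, generate, make_fixture_suite


@pytest.fixture(scope="session")
def suite():
    """Deterministic catalogue of synthetic tables shared across tests."""
    return make_fixture_suite(seed=0)


@pytest.fixture(scope="session")
def standard_table():
    """The standard selection benchmark: n = 200, D = 20, 5 planted columns."""
    return generate(
        SyntheticSpec(
            n_samples_per_class=100, n_features=20, n_informative=5,
            separation=2.0, seed=0,
        )
    )


@pytest.fixture(scope="session")
def oracle_table():
    """Small-D table for exhaustive 63-mask comparison.

    Moderate class overlap (delta = 1) keeps several subsets within a
    few percent of the optimum, so optimizer-vs-oracle comparisons
    measure convergence rather than exact-hit luck.
    """
    return generate(
        SyntheticSpec(
            n_samples_per_class=100, n_features=6, n_informative=2,
            separation=1.0, seed=7,
        )
    )


@pytest.fixture
def perfect_column_table():
    """One column separates the classes perfectly; the rest is noise."""
    rng = np.random.default_rng(5)
    n, d = 120, 8
    labels = np.repeat([0, 1], n // 2)
    values = rng.normal(size=(n, d))
    values[:, 2] = (labels * 2 - 1) * 2.0 + 0.1 * rng.normal(size=n)
    return FeatureTable(values=values, labels=labels)
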