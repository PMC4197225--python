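import numpy as np
import pytest

from cohortdiversity import ExpressionMatrix, SimulationConfig, simulate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_cohort():
    """A 50-gene x 40-sample homogeneous cohort at the default hyperparameters."""
    return simulate_cohort(SimulationConfig(n_genes=50, n_samples=40, seed=7))


@pytest.fixture
def two_group_cohort():
    return simulate_cohort(
        SimulationConfig(n_genes=50, n_samples=40, group_sizes=(20, 20), seed=11)
    )


def make_expression(values, genes=None, samples=None, **kwargs):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(values, genes, samples, **kwargs)
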