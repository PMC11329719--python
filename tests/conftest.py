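import numpy as np
import pytest

from pdsubtypes import simulate


@pytest.fixture(scope="session")
def small_severity_dataset():
    """Reduced severity-gradient dataset shared across tests."""
    cohorts = simulate.default_cohorts(0.25)
    subtypes = simulate.severity_subtypes()
    table, matrix, truth = simulate.generate_dataset(cohorts, subtypes, seed=11)
    return table, matrix, truth, subtypes


@pytest.fixture(scope="session")
def small_typicality_dataset():
    cohorts = simulate.default_cohorts(0.25)
    subtypes = simulate.typicality_subtypes()
    table, matrix, truth = simulate.generate_dataset(cohorts, subtypes, seed=11)
    return table, matrix, truth, subtypes


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
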