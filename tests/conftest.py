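import numpy as np
import pandas as pd
import pytest

from progsub.simulate import SimulationParams, simulate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_expression():
    """2 genes x 3 samples on the count-plus-one scale."""
    return pd.DataFrame(
        [[2.0, 4.0, 6.0], [10.0, 10.0, 10.0]],
        index=["G1", "G2"],
        columns=["s1", "s2", "s3"],
    )


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort, shared across tests (read-only)."""
    return simulate_cohort(SimulationParams(seed=7))


@pytest.fixture(scope="session")
def unmixed_cohort():
    """Cohort without immune mixing: planted effects hit the bulk directly."""
    return simulate_cohort(SimulationParams(seed=11, n_cell_types=0))
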