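import numpy as np
import pytest

from roirates import SimulationParams, generate_cohort, build_model_input


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture(scope="session")
def small_cohort():
    """Fast cohort: study group sizes, 12 ROIs, known truth."""
    params = SimulationParams(n_roi=12, seed=11)
    return generate_cohort(params)


@pytest.fixture(scope="session")
def small_design(small_cohort):
    return build_model_input(small_cohort)
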