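import warnings

import numpy as np
import pytest

from subgrad import (
    GradientParams,
    SimulationConfig,
    generate_cohort,
)
from subgrad.pipeline import compute_stack

warnings.filterwarnings("ignore", category=UserWarning)


TINY = dict(n_control=4, n_ltle=4, n_rtle=4, a=120, b=600, t=100)


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small cohort with all planted effects, shared across tests."""
    return generate_cohort(SimulationConfig(seed=11, **TINY))


@pytest.fixture(scope="session")
def tiny_stack(tiny_cohort):
    """Aligned + harmonized stack of the tiny cohort (10 components)."""
    stack, sets = compute_stack(tiny_cohort.recordings, GradientParams(n_components=10))
    return stack, sets


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
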