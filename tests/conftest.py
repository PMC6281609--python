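import warnings

import numpy as np
import pytest

from qtgtest import CrossDesign, MediationModel, simulate_f2_intercross, \
    simulate_four_way_cross


@pytest.fixture(autouse=True)
def _quiet_model_warnings():
    """Mixed-model boundary warnings are expected on small fixtures."""
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*boundary.*")
        warnings.filterwarnings("ignore", message=".*Random effects.*")
        yield


@pytest.fixture(scope="session")
def four_way_cohort():
    return simulate_four_way_cross(CrossDesign.four_way(),
                                   MediationModel.null(), seed=101)


@pytest.fixture(scope="session")
def f2_cohort():
    return simulate_f2_intercross(CrossDesign.f2(),
                                  MediationModel.causal(), seed=202)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
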