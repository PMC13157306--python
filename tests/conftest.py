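import numpy as np
import pytest

from clpnet import simulate
from clpnet.estimate import EstimatorConfig

# light estimator settings shared by unit tests (full defaults are exercised
# in the acceptance tests)
FAST = EstimatorConfig(cv_folds=5, n_lambdas=25)


@pytest.fixture(scope="session")
def planted_truth():
    """20 planted cross-lagged effects of latent magnitude 0.15-0.30."""
    return simulate.make_ground_truth(
        n_nonzero_cross=20, effect_range=(0.15, 0.30), seed=101
    )


@pytest.fixture(scope="session")
def planted_panel(planted_truth):
    return simulate.simulate_panel(planted_truth, n=2000, seed=102)


@pytest.fixture(scope="session")
def null_truth():
    """Autoregression only: no cross-lagged structure."""
    return simulate.make_ground_truth(n_nonzero_cross=0, seed=103)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
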