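import numpy as np
import pytest

from hmfc import (
    CriterionFluctuationModel,
    HyperParams,
    simulate_hierarchical_dataset,
)


@pytest.fixture(scope="session")
def reference_simulation():
    """One dataset at the standard validation conditions (reduced to 40
    subjects x 500 trials to keep the suite fast)."""
    eta = HyperParams.reference()
    data, params, trajs = simulate_hierarchical_dataset(eta, 40, 500, 7)
    return eta, data, params, trajs


@pytest.fixture(scope="session")
def reference_fit(reference_simulation):
    """Gibbs fit of the reference dataset, shared across recovery tests."""
    _, data, _, _ = reference_simulation
    model = CriterionFluctuationModel(data)
    return model.fit(iterations=600, burn_in=200, seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
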