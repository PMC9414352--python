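import numpy as np
import pytest

import eegconn as ec

# epoch_ms for an n-sample epoch at 250 Hz
MS = lambda n: n * 4.0


@pytest.fixture(scope="session")
def two_channel_system():
    """Unidirectional 2-channel VAR(1): A(1) = [[0.5, 0], [0.4, 0.5]]."""
    return ec.make_var_system(2, 1, edges=[(0, 1, 0.4)], diag_strength=0.5)


@pytest.fixture(scope="session")
def condition_systems():
    return ec.default_condition_systems()


@pytest.fixture(scope="session")
def long_fit(condition_systems):
    """One 2e4-sample realisation of the dense system and its VAR(5) fit."""
    _, dense = condition_systems
    eps = ec.simulate_epochs(dense, 1, MS(20000), "distracted", seed=3)
    model = ec.fit_mvar(eps.data[0], 5)
    return dense, model


@pytest.fixture(scope="session")
def small_dataset():
    """Tiny two-condition contrast dataset (2 subjects x 2 epochs/class)."""
    return ec.make_condition_dataset(n_subjects=2, epochs_per_class=2, seed=7)
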