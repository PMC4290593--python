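import numpy as np
import pytest

from dcap import SimulationSpec, simulate_mvn_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_weak_dataset():
    """A scaled-down weak-binding dataset shared by fast tests."""
    spec = SimulationSpec(
        n_windows=5000, n_binding=300, n_common=200, n_differential=100,
        binding_mean=4.0, binding_var=2.25, seed=7,
    )
    values, layout, truth = simulate_mvn_dataset(spec)
    return spec, values, layout, truth
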