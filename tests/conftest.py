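import numpy as np
import pytest

import speechtrf as st


@pytest.fixture(scope="session")
def inventory():
    return st.default_inventory()


@pytest.fixture(scope="session")
def montage():
    return st.default_montage()


@pytest.fixture(scope="session")
def stimulus():
    """A 60 s speech-like stimulus with every regressor family."""
    return st.generate_stimulus(60.0, seed=11)


@pytest.fixture(scope="session")
def kernels():
    return st.make_kernels(st.default_kernel_specs(), 64, seed=3)


@pytest.fixture(scope="session")
def recording(stimulus, kernels):
    """Simulated EEG at +20 dB for the default envelope/surprisal kernels."""
    return st.simulate_eeg(stimulus.features, kernels, snr_db=20.0, seed=5)


@pytest.fixture(scope="session")
def small_cohort():
    """Six participants, two conditions, 1.5x envelope kernel in B."""
    base = st.CohortSpec(duration=60.0, n_channels=16, snr_db=20.0)
    return st.make_cohort(
        6, ["A", "B"], {"B": {"kernel_scale": {"env": 1.5}}}, base, seed=21
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
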