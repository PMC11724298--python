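import numpy as np
import pytest

from overstretch.model import ConstructModel, RampProtocol, construct_preset
from overstretch.pipeline import detect_dataset
from overstretch.simulate import simulate_cycles


@pytest.fixture(scope="session")
def unmodified():
    return construct_preset("Unmodified")


@pytest.fixture(scope="session")
def slow_construct():
    """Hopping slow enough that no dwell falls below the sampling interval
    (used for exact detector/simulator closure)."""
    return ConstructModel(
        name="slow", f_tr=63.7, dx_tr=10.8, x_b_ts=6.52, x_s_ts=4.28, k_tr=2.0
    )


@pytest.fixture(scope="session")
def noisy_dataset(unmodified):
    """40 noisy cycles of the reference duplex plus the ground-truth log."""
    protocol = RampProtocol(n_cycles=40, noise_sigma_f=0.2, seed=11)
    trace, truth = simulate_cycles(
        unmodified, protocol, 40, np.random.default_rng(11)
    )
    return trace, truth, protocol


@pytest.fixture(scope="session")
def noisy_detection(noisy_dataset):
    trace, truth, protocol = noisy_dataset
    return detect_dataset(trace), truth, protocol
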