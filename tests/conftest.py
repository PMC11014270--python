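import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import nirquant as nq

settings.register_profile(
    "ci", derandomize=True, max_examples=40, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def micro_axis():
    return nq.build_instrument_grid(nq.MICRO_NIR)


@pytest.fixture(scope="session")
def ft_axis():
    return nq.build_instrument_grid(nq.FT_NIR)


@pytest.fixture(scope="session")
def library():
    return nq.default_library()


@pytest.fixture(scope="session")
def small_dataset():
    """20-spectrum Micro-NIR corn-flour dataset for I/O and plumbing tests."""
    spec = nq.DesignSpec(levels=(1, 5, 10, 20, 50), samples_per_level=2,
                         scans_per_sample=2, instrument=nq.MICRO_NIR,
                         adulterant="corn_flour", seed=7)
    return nq.generate_design(spec)


@pytest.fixture(scope="session")
def full_micro_dataset():
    """The full 450-spectrum Micro-NIR corn-flour design (master seed 42)."""
    return nq.generate_design(nq.DesignSpec(seed=42))


@pytest.fixture(scope="session")
def noisefree_micro_dataset():
    """Noise-free 30-spectrum Micro-NIR design (15 levels x 2 x 1)."""
    spec = nq.DesignSpec(samples_per_level=2, scans_per_sample=1, seed=3)
    return nq.generate_design(spec, noise=nq.NoiseModel.off())


class LinearSurrogate:
    """f(x) = w . x + b — analytic stand-in predictor for oracle tests."""

    def __init__(self, w, b=0.0):
        self.w = np.asarray(w, dtype=float)
        self.b = float(b)

    def predict(self, X):
        return np.asarray(X, dtype=float) @ self.w + self.b


@pytest.fixture
def linear_surrogate():
    return LinearSurrogate
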