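import numpy as np
import pytest

from hmbfit import OptimizerConfig, RateDataset


@pytest.fixture(scope="session")
def fast_config():
    """Reduced-effort optimizer for batch tests."""
    return OptimizerConfig.fast()


@pytest.fixture(scope="session")
def light_config():
    """Single-method optimizer for many-replicate tests."""
    return OptimizerConfig(n_random=0, methods=("nelder-mead",), maxeval=500)


@pytest.fixture()
def log_times():
    return np.geomspace(0.1, 50.0, 60)


@pytest.fixture()
def constant_rate_dataset(log_times):
    """Noiseless constant rate 0.4 across a log-spaced time grid."""
    return RateDataset(time=log_times, rate=np.full_like(log_times, 0.4), name="const")


@pytest.fixture()
def lognormal_dataset():
    """Rates scattered lognormally about 0.3; no time trend."""
    rng = np.random.default_rng(42)
    t = np.geomspace(0.1, 50.0, 40)
    rate = np.exp(rng.normal(np.log(0.3), 0.2, t.size))
    return RateDataset(time=t, rate=rate, name="lognormal")


@pytest.fixture()
def noise_over_time_dataset():
    """Pure time-independent numerator noise divided by time."""
    rng = np.random.default_rng(7)
    t = np.exp(rng.uniform(np.log(0.1), np.log(50.0), 120))
    num = np.abs(rng.normal(0.0, 1.0, t.size))
    return RateDataset(time=t, rate=num / t, numerator=num, name="noise")
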