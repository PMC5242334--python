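import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "vmcmd",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("vmcmd")


@pytest.fixture(scope="session")
def harmonic_bench():
    """Converged V-McMD benchmark on the 6-D harmonic well (shared: the
    flat-histogram, reweighting and ergodicity checks all read it)."""
    from vmcmd.benchmarks import harmonic_flat_benchmark

    return harmonic_flat_benchmark(seed=2024)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
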