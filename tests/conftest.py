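import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from invasionscape.synthgen import (CloneSpec, DoseGrid, generate_benchmark_dataset,
                                    valley_truth)


@pytest.fixture(scope="session")
def low_noise_clone():
    return CloneSpec(sigma_log10=0.15, label="BL")


@pytest.fixture(scope="session")
def high_noise_clone():
    return CloneSpec(sigma_log10=0.30, label="BH")


@pytest.fixture(scope="session")
def valley_benchmark():
    """One seeded/invaded pair thinned under a quadratic-valley truth."""
    spec = CloneSpec(sigma_log10=0.25)
    truth = valley_truth(spec)
    ds = generate_benchmark_dataset(spec, DoseGrid((0.5,)), truth,
                                    n_per_dose=50_000, seed=11)
    return ds
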