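import pytest
from hypothesis import HealthCheck, settings

from ctcf_divergence.pipeline import bundle_features
from ctcf_divergence.synthetic_data import GeneratorConfig, generate

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_bundle():
    """A small but complete synthetic bundle shared across unit tests."""
    return generate(GeneratorConfig(seed=11, n_chrom=3, genes_per_chrom=120))


@pytest.fixture(scope="session")
def small_features(small_bundle):
    return bundle_features(small_bundle)


@pytest.fixture(scope="session")
def default_bundle():
    """The default-size study bundle used by the recovery checks."""
    return generate(GeneratorConfig(seed=101))


@pytest.fixture(scope="session")
def default_features(default_bundle):
    return bundle_features(default_bundle)
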