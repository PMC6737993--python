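import pytest

from quefts import GeneratorConfig, builtin_registry, generate_trials


@pytest.fixture(scope="session")
def registry():
    return builtin_registry("parameterized")


@pytest.fixture(scope="session")
def ngs(registry):
    return registry["NGS"]


@pytest.fixture(scope="session")
def ss(registry):
    return registry["SS"]


@pytest.fixture(scope="session")
def pooled(registry):
    return registry["All"]


@pytest.fixture(scope="session")
def small_trials():
    """A modest noisy NGS trial set shared across read-only tests."""
    return generate_trials(GeneratorConfig(zone="NGS", n_fields=30, seed=11))


@pytest.fixture(scope="session")
def quiet_trials():
    """Noise-free NGS trials (subsistence fields retained)."""
    return generate_trials(GeneratorConfig(zone="NGS", n_fields=30, seed=11).noise_free())
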