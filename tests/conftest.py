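import pytest

from gwhazard import load_registry
from gwhazard.synth import default_config, generate


@pytest.fixture(scope="session")
def registry():
    return load_registry()


@pytest.fixture(scope="session")
def adult(registry):
    return registry.cohort("adult")


@pytest.fixture(scope="session")
def child(registry):
    return registry.cohort("child")


@pytest.fixture(scope="session")
def synthetic40():
    """Default study-condition dataset: 40 samples, fixed seed."""
    return generate(default_config(seed=20240, n_samples=40))
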