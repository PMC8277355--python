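import pytest

from aktloop import GeneratorConfig, default_training_bundle, generate_reference_curves
from aktloop._kinetics import warmup


@pytest.fixture(scope="session", autouse=True)
def _jit_warmup():
    """Compile the numba kernels once per session."""
    warmup()


@pytest.fixture(scope="session")
def default_config():
    return GeneratorConfig()


@pytest.fixture(scope="session")
def reference_curves(default_config):
    return generate_reference_curves(default_config)


@pytest.fixture(scope="session")
def training_bundle(default_config):
    return default_training_bundle(default_config)

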