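import pytest

from stakit import SimConfig, build_toy_reference, simulate_library


@pytest.fixture(scope="session")
def toy_ref():
    return build_toy_reference(0)


@pytest.fixture(scope="session")
def bundle(toy_ref):
    return toy_ref.bundle()


@pytest.fixture(scope="session")
def default_library(toy_ref):
    """A mid-sized library under default chemistry conditions."""
    return simulate_library(toy_ref, SimConfig(seed=11, n_reads=5000))
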