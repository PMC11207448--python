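import numpy as np
import pytest

from phenodiv.simulate import build_default_config, generate


@pytest.fixture(scope="session")
def default_config():
    return build_default_config()


@pytest.fixture(scope="session")
def panel113():
    """Default synthetic panel at the reference size (groups on)."""
    return generate(build_default_config(), seed=7)


@pytest.fixture(scope="session")
def big_panel():
    """Large pure-copula panel (no group offsets) for moment/correlation recovery."""
    return generate(build_default_config(10_000, with_groups=False), seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
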