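import pytest
from hypothesis import settings

from bkmc import make_fixture, parse_config, parse_model

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


def load_fixture(name: str, seed: int = 0, **config_overrides):
    """Parse a named fixture; keyword overrides patch the config."""
    bnd, cfg = make_fixture(name, seed=seed)
    model = parse_model(bnd)
    config = parse_config(cfg, model)
    for key, value in config_overrides.items():
        setattr(config, key, value)
    return model, config


@pytest.fixture
def toy_fast():
    return load_fixture("toy-fast")


@pytest.fixture
def toy_slow():
    return load_fixture("toy-slow")


@pytest.fixture
def p53():
    return load_fixture("p53")


@pytest.fixture
def cellcycle():
    return load_fixture("cellcycle")
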