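import dataclasses

import pytest

from chirace.defaults import default_config


@pytest.fixture(scope="session")
def cfg():
    return default_config()


@pytest.fixture(scope="session")
def enzyme(cfg):
    return cfg.enzyme


@pytest.fixture(scope="session")
def noiseless_enzyme(cfg):
    """Enzyme with deterministic swing delays (cv = 0)."""
    return dataclasses.replace(
        cfg.enzyme, swing=dataclasses.replace(cfg.enzyme.swing, cv=0.0)
    )


@pytest.fixture(scope="session")
def gel(cfg):
    return cfg.gel


@pytest.fixture(scope="session")
def markers(cfg):
    return cfg.markers()
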