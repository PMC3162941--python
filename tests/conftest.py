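from __future__ import annotations

import pytest

from fuzzyvitals import build_engine, default_config


@pytest.fixture(scope="session")
def config():
    return default_config()


@pytest.fixture(scope="session")
def engine(config):
    return build_engine(config)


@pytest.fixture(scope="session")
def mbp_var(engine):
    return engine.variables["MBP"]


@pytest.fixture(scope="session")
def spo2_var(engine):
    return engine.variables["SpO2"]
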