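import pytest

from vamsquant.panel import ThresholdConfig, default_panel


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture(scope="session")
def thresholds():
    return ThresholdConfig()
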