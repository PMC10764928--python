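import numpy as np
import pytest

from isodose.pipeline import PipelineConfig, run_all


DEMO_SEED = 0


@pytest.fixture(scope="session")
def demo_config():
    return PipelineConfig().reseeded(DEMO_SEED)


@pytest.fixture(scope="session")
def demo_reports(demo_config):
    """All three scenarios on the fixed demo seed (shared across tests)."""
    return run_all(demo_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
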