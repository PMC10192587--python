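import numpy as np
import pytest
from hypothesis import settings

from audiosfa import stimuli
from audiosfa.experiments import PipelineConfig

settings.register_profile("ci", derandomize=True, max_examples=25,
                          deadline=None)
settings.load_profile("ci")

RATE = 8000.0


@pytest.fixture(scope="session")
def fast_config():
    """Coarse pipeline for unit tests (2 kHz cochleagram frame rate)."""
    return PipelineConfig.scaled(rate=RATE, downsample=4)


@pytest.fixture(scope="session")
def study_config():
    """The scaled study configuration used for ensemble experiments."""
    return PipelineConfig.scaled(rate=RATE)


@pytest.fixture(scope="session")
def vocal_ensemble():
    return [stimuli.make_vocalization(duration=1.0, seed=s, rate=RATE,
                                      exemplar_id=s) for s in range(10)]


@pytest.fixture(scope="session")
def noise_ensemble():
    return [stimuli.make_white_noise(duration=1.0, rate=RATE, seed=100 + s,
                                     exemplar_id=s) for s in range(10)]


@pytest.fixture(scope="session")
def applause_ensemble():
    return [stimuli.make_applause_like(duration=1.0, rate=RATE, seed=200 + s,
                                       exemplar_id=s) for s in range(10)]


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
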