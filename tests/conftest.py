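import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import vocometric as vm

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def design():
    """The standard 100-item stimulus design."""
    return vm.build_stimulus_list(seed=0)


@pytest.fixture(scope="session")
def speech_like():
    """A synthetic utterance standing in for recorded speech."""
    return vm.synth_utterance("587", rate=16000.0, seed=0)


@pytest.fixture(scope="session")
def control_params():
    """Generating parameters typical of a healthy control listener."""
    return vm.ListenerParams(m=3.14, s=1.08, gamma=0.04, lam=0.0, eta=0.0)
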