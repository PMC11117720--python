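import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")

from myokitchen.config import default_config
from myokitchen.emg_synthesis import GestureScript, SynthParams, synthesize_trace


@pytest.fixture(scope="session")
def config():
    return default_config()


@pytest.fixture(scope="session")
def sustained_flexion_trace():
    """4 s of sustained flexion at 80 µV between 1 s rest pads."""
    script = GestureScript.from_pairs(
        [("rest", 1.0), ("flexion", 4.0, 80.0), ("rest", 1.0)]
    )
    return synthesize_trace(script, SynthParams(seed=7))


@pytest.fixture(scope="session")
def rest_trace():
    script = GestureScript.from_pairs([("rest", 2.0)])
    return synthesize_trace(script, SynthParams(seed=11))
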