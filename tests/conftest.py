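"""Shared fixtures: small synthetic configurations and pre-trained decoders.

Decoder training is the slow step, so strongly-separable MI and P300
decoders are trained once per session and reused across tests.
"""

import numpy as np
import pytest

from fatiguebci import SimulationConfig, gen_mi_session, gen_p300_session
from fatiguebci.pipelines import train_mi, train_p300


@pytest.fixture(scope="session")
def strong_mi_cfg() -> SimulationConfig:
    """Strong planted effect: deep contralateral ERD, low background noise."""
    return SimulationConfig(seed=11, erd_depth=0.8, noise_sd=1.0)


@pytest.fixture(scope="session")
def strong_p300_cfg() -> SimulationConfig:
    """Strong planted evoked response: large deflection, low noise."""
    return SimulationConfig(seed=12, p3_amp=6.0, noise_sd=2.0)


@pytest.fixture(scope="session")
def mi_decoder(strong_mi_cfg):
    rec, events = gen_mi_session(strong_mi_cfg)
    return train_mi(rec, events, feedback_trace=False)


@pytest.fixture(scope="session")
def p300_decoder(strong_p300_cfg):
    rec, events = gen_p300_session(strong_p300_cfg)
    return train_p300(rec, events)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
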