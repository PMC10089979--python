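import numpy as np
import pytest

from tipm.core import NeuronRecord, TrialSet
from tipm.protocols import build_impulse_protocol, build_tonic_protocol
from tipm.simulate import SimConfig, simulate_population, substream


@pytest.fixture(scope="session")
def tonic():
    return build_tonic_protocol()


@pytest.fixture(scope="session")
def impulse():
    return build_impulse_protocol()


@pytest.fixture
def flat_trials(tonic):
    """Three trials pinned at a constant baseline fluorescence of 10."""
    return TrialSet(0, tonic, np.full((3, tonic.n_frames), 10.0), tonic.frame_rate)


@pytest.fixture(scope="session")
def small_population():
    cfg = SimConfig(seed=42, n_fish=2)
    return simulate_population(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_neuron(subtype="nose_up", true_di=0.8, pattern="excitation", impulse_responsive=False):
    return NeuronRecord(
        neuron_id=0,
        fish_id=0,
        hemisphere="left",
        x_rc_um=10.0,
        y_ml_um=10.0,
        z_dv_um=10.0,
        birth_hpf=30.0,
        cohort="early",
        subtype=subtype,
        impulse_responsive=impulse_responsive,
        response_pattern=pattern,
        true_di=true_di,
    )
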