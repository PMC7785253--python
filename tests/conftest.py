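import numpy as np
import pytest

from spikewm import (
    NetworkParams,
    NeuronParams,
    PlasticityParams,
    StimulusParams,
    build_network,
)
from spikewm.engine import SimulationParams, simulate_segment
from spikewm.stimulus import make_background


@pytest.fixture
def neuron():
    return NeuronParams()


@pytest.fixture
def plast():
    return PlasticityParams()


@pytest.fixture
def stim():
    return StimulusParams()


def make_tiny_state(seed=3, n_e=8, n_i=2, c=0.3,
                    neuron=NeuronParams(), plast=PlasticityParams()):
    """A 10-unit network ready to simulate."""
    state = build_network(NetworkParams(c=c, n_e=n_e, n_i=n_i), seed)
    state.V[:] = neuron.e_l
    state.u[:] = plast.u_baseline
    return state


def run_tiny(engine, stdp_mode, t_end=1500.0, seed=3, bg_seed=7, bg_rate=10.0,
             drive_pA=800.0, n_drive=4):
    """Short driven run of the tiny network; returns (state, segment result)."""
    neuron, plast = NeuronParams(), PlasticityParams()
    state = make_tiny_state(seed, neuron=neuron, plast=plast)
    sim = SimulationParams(engine=engine, stdp_mode=stdp_mode,
                           trace_interval_ms=100.0)
    bg = make_background(state.n, bg_rate, t_end, bg_seed)
    I = np.zeros(state.n)
    I[:n_drive] = drive_pA
    seg = simulate_segment(state, neuron, plast, sim, I, bg, t_end,
                           np.zeros(state.n))
    return state, seg
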