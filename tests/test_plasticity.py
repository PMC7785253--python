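import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spikewm.plasticity import (
    PlasticityParams,
    apply_stdp,
    per_spike_amplitude,
    stdp_delta,
    stp_decay,
    stp_on_spike,
    syn_current_step,
)
from tests.conftest import make_tiny_state

PP = PlasticityParams()


# ----------------------------------------------------------------- STP

def test_stp_decay_reaches_baseline():
    u, x = stp_decay(1.0, 1.0, PP, 1000.0)
    assert abs(u - PP.u_baseline) < 1e-4
    assert x == 1.0


def test_stp_resting_state_is_invariant():
    for dt in (0.1, 7.3, 5000.0):
        u, x = stp_decay(PP.u_baseline, 1.0, PP, dt)
        assert u == pytest.approx(PP.u_baseline, abs=1e-15)
        assert x == 1.0


def test_stp_x_recovery_closed_form():
    _, x = stp_decay(PP.u_baseline, 0.04, PP, 900.0)
    assert x == pytest.approx(1.0 - 0.96 * np.exp(-1.0), rel=1e-12)


def test_stp_jump_rules_from_rest():
    u, x, release = stp_on_spike(0.80, 1.0, PP)
    assert u == pytest.approx(0.96, rel=1e-12)
    assert x == pytest.approx(0.04, rel=1e-12)
    assert release == pytest.approx(0.96, rel=1e-12)


def test_stp_transparent_synapse_at_zero_baseline():
    pp = PlasticityParams(u_baseline=0.0)
    u, x, release = stp_on_spike(0.0, 0.7, pp)
    assert u == 0.0
    assert x == 0.7  # fully transparent
    assert release == 0.0


def test_high_rate_spiking_depresses_x():
    u, x = PP.u_baseline, 1.0
    for _ in range(20):  # 100 Hz train
        u, x, _ = stp_on_spike(u, x, PP)
        u, x = stp_decay(u, x, PP, 10.0)
    assert x < 0.2


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.lists(st.tuples(st.booleans(), st.floats(0.01, 500.0)), min_size=1, max_size=60))
def test_stp_variables_stay_in_range(events):
    u, x = PP.u_baseline, 1.0
    for is_spike, dt in events:
        if is_spike:
            u, x, rel = stp_on_spike(u, x, PP)
            assert 0.0 <= rel <= 1.0
        else:
            u, x = stp_decay(u, x, PP, dt)
        assert PP.u_baseline - 1e-12 <= u <= 1.0
        assert 0.0 < x <= 1.0


# ----------------------------------------------------------------- STDP

def test_stdp_soft_bounds():
    assert stdp_delta(1.0, 10.0, PP) == 0.0   # LTP saturates at J = 1
    assert stdp_delta(0.0, -10.0, PP) == 0.0  # LTD vanishes at J = 0


def test_stdp_direct_evaluation():
    dj = stdp_delta(0.5, 20.0, PP)
    assert dj == pytest.approx(5e-5 * 0.5 * np.exp(-1.0), rel=1e-12)


def test_stdp_zero_lag_falls_in_depression_branch():
    assert stdp_delta(0.5, 0.0, PP) < 0.0


def test_stdp_window_shapes():
    pos = np.array([1.0, 5.0, 20.0, 50.0, 120.0])
    ltp = stdp_delta(np.full(5, 0.5), pos, PP)
    assert np.all(np.diff(ltp) < 0)  # LTP magnitude decreases with lag
    ltd = stdp_delta(np.full(5, 0.5), -pos, PP)
    assert np.all(np.diff(-ltd) < 0)  # |LTD| decreases with |lag|


def test_ltd_dominates_ltp_at_equal_lag():
    for lag in (5.0, 10.0, 30.0):
        ratio = -stdp_delta(0.5, -lag, PP) / stdp_delta(0.5, lag, PP)
        assert ratio > 1.0


def test_inhibitory_weights_drift_toward_zero():
    # both branches are non-negative for J < 0 (the documented Dale drift)
    assert stdp_delta(-1.0, 8.0, PP) > 0.0
    assert stdp_delta(-1.0, -8.0, PP) > 0.0


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.floats(0.0, 1.0), st.lists(st.floats(-200.0, 200.0), min_size=1, max_size=100))
def test_multiplicative_rule_keeps_excitatory_weights_bounded(j0, lags):
    j = j0
    for lag in lags:
        j = j + stdp_delta(j, lag, PP)
        assert 0.0 <= j <= 1.0


def test_apply_stdp_two_spike_script():
    state = make_tiny_state(n_e=2, n_i=1, c=0.9)
    state.J[:] = 0.0
    state.C[:] = 0
    state.J[1, 0] = 0.5
    state.C[1, 0] = 1
    dt = 0.1
    # unit 0 spikes at t = 10 ms: partner has no defined spike -> nothing
    state.prev_spike[0] = state.last_spike[0]
    state.last_spike[0] = 10.0
    state.t = 10.0
    apply_stdp(state, [0], PP)
    assert state.J[1, 0] == 0.5
    # unit 1 spikes at t = 30 ms: incoming 0 -> 1 potentiates by the oracle value
    state.prev_spike[1] = state.last_spike[1]
    state.last_spike[1] = 30.0
    state.t = 30.0
    apply_stdp(state, [1], PP)
    assert state.J[1, 0] == pytest.approx(0.5 + stdp_delta(0.5, 20.0, PP), rel=1e-12)
    # outgoing 1 -> 0 had J = 0: depression does nothing and creates nothing
    assert state.J[0, 1] == 0.0
    assert state.C[0, 1] == 0


def test_apply_stdp_creates_connection_on_potentiation():
    state = make_tiny_state(n_e=2, n_i=1, c=0.9)
    state.J[:] = 0.0
    state.C[:] = 0
    state.last_spike[0] = 10.0
    state.last_spike[1] = 30.0
    state.t = 30.0
    apply_stdp(state, [1], PP)
    assert state.C[1, 0] == 1
    assert state.J[1, 0] == pytest.approx(stdp_delta(0.0, 20.0, PP), rel=1e-12)


def test_apply_stdp_no_spikes_is_identity():
    state = make_tiny_state()
    J0, C0 = state.J.copy(), state.C.copy()
    apply_stdp(state, [], PP)
    assert np.array_equal(state.J, J0)
    assert np.array_equal(state.C, C0)


def test_self_pair_uses_penultimate_spike():
    state = make_tiny_state(n_e=2, n_i=1, c=0.9)
    state.J[:] = 0.0
    state.C[:] = 0
    state.prev_spike[0] = 20.0
    state.last_spike[0] = 30.0
    state.t = 30.0
    apply_stdp(state, [0], PP)
    assert state.C[0, 0] == 1  # self-connection created by the 10 ms pairing
    # the self pair is updated in both roles: potentiation as postsynaptic,
    # then depression as presynaptic, each against the penultimate spike
    j = stdp_delta(0.0, 10.0, PP)
    j = j + stdp_delta(j, -10.0, PP)
    assert state.J[0, 0] == pytest.approx(j, rel=1e-12)


def test_allow_self_connections_switch():
    state = make_tiny_state(n_e=2, n_i=1, c=0.9)
    state.J[:] = 0.0
    state.C[:] = 0
    state.prev_spike[0] = 20.0
    state.last_spike[0] = 30.0
    state.t = 30.0
    apply_stdp(state, [0], PP, allow_self_connections=False)
    assert state.C[0, 0] == 0
    assert state.J[0, 0] == 0.0


# ----------------------------------------------------- synaptic currents

def test_syn_current_decay():
    out = syn_current_step(np.array([100.0]), np.zeros(1), tau_syn=5.0, dt=5.0)
    assert out[0] == pytest.approx(100.0 * np.exp(-1.0), rel=1e-12)


def test_syn_current_zero_stays_zero():
    out = syn_current_step(np.zeros(3), np.zeros(3), tau_syn=5.0, dt=0.1)
    assert np.all(out == 0.0)


def test_single_spike_current_integral():
    # integral of G * exp(-t/tau) over time equals G * tau
    dt, tau, G = 0.01, 5.0, 740.0
    I = np.array([G])
    total = I[0] * dt
    for _ in range(int(100.0 / dt)):
        I = syn_current_step(I, np.zeros(1), tau, dt)
        total += I[0] * dt
    assert total == pytest.approx(G * tau, rel=2e-3)


def test_per_spike_amplitude():
    J_col = np.array([0.65, -1.0, 0.4])
    C_col = np.array([1, 1, 0], dtype=np.uint8)
    amps = per_spike_amplitude(J_col, C_col, release=0.8, g_scale=1000.0)
    assert amps[0] == pytest.approx(520.0)
    assert amps[1] == pytest.approx(-800.0)  # hyperpolarizing
    assert amps[2] == 0.0
    assert np.all(per_spike_amplitude(J_col, C_col, 0.0) == 0.0)


def test_param_validation():
    with pytest.raises(ValueError):
        PlasticityParams(u_baseline=1.5)
    with pytest.raises(ValueError):
        PlasticityParams(tau_minus=10.0)  # LTD window must exceed LTP window
    with pytest.raises(ValueError):
        PlasticityParams(alpha=0.5)
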