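"""Time-stepped simulation engines.

Per integration step (``dt`` ms) the loop is:

1. exact exponential relaxation of the STP variables;
2. delivery of presynaptic events — somatic spikes registered in the
   previous step (their release fractions were buffered then) plus the
   frozen background events of this step, each injecting
   ``g_scale * J[:, j] * release`` into connected targets — followed by the
   exponential decay/jump update of the postsynaptic current;
3. forward-Euler membrane/adaptation step, spike detection and reset;
4. STP jumps for this step's spikers (release buffered for the next step);
5. the STDP update (per-spike in ``event`` mode, per-step over all defined
   pairs in ``continuous`` mode);
6. recording (spikes, mean-efficacy trace).

Two implementations share these semantics: a plain-numpy engine whose
continuous-mode plasticity is the brute-force full-matrix per-step update
(readable, the oracle, practical for small networks), and a numba engine that
evaluates the same geometric weight recursions lazily in closed form, pair by
pair, whenever a pair's spike-time difference changes or an observation needs
current weights.  Equivalence of the two is asserted by the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import NetworkState
from .neuron import NeuronParams, membrane_step, NumericalBlowupError
from .plasticity import (
    PlasticityParams,
    apply_stdp,
    continuous_stdp_step,
    per_spike_amplitude,
    stp_decay,
    stp_on_spike,
    syn_current_step,
)
from .stimulus import BackgroundNoise

__all__ = ["SimulationParams", "SegmentResult", "simulate_segment"]

STDP_MODES = ("continuous", "event")
ENGINES = ("auto", "numpy", "numba")


@dataclass(frozen=True)
class SimulationParams:
    dt_ms: float = 0.1
    g_scale: float = 1000.0            # pA of peak current per unit efficacy
    stdp_mode: str = "continuous"
    engine: str = "auto"
    background_drives_stdp: bool = False
    allow_self_connections: bool = True
    trace_interval_ms: float = 500.0   # mean-efficacy sampling period
    max_mean_rate_hz: float = 400.0    # spike-buffer sizing guard

    def __post_init__(self) -> None:
        if self.dt_ms <= 0:
            raise ValueError("dt must be positive")
        if self.stdp_mode not in STDP_MODES:
            raise ValueError(f"stdp_mode must be one of {STDP_MODES}")
        if self.engine not in ENGINES:
            raise ValueError(f"engine must be one of {ENGINES}")
        if self.g_scale <= 0 or self.trace_interval_ms <= 0:
            raise ValueError("g_scale and trace interval must be positive")

    def resolve_engine(self) -> str:
        if self.engine != "auto":
            return self.engine
        try:
            import numba  # noqa: F401
            return "numba"
        except ImportError:  # pragma: no cover
            return "numpy"


@dataclass
class SegmentResult:
    spike_t_ms: np.ndarray
    spike_unit: np.ndarray
    trace_t_ms: np.ndarray
    trace_mean_j: np.ndarray


def _background_events(background: BackgroundNoise | None, t0: float, t1: float,
                       dt: float, step0: int) -> tuple[np.ndarray, np.ndarray]:
    """(step index, unit) pairs for background spikes in [t0, t1), time-sorted."""
    if background is None:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    times, units = [], []
    for j, train in enumerate(background.trains):
        sel = train[(train >= t0) & (train < t1)]
        times.append(sel)
        units.append(np.full(sel.size, j, dtype=np.int64))
    t = np.concatenate(times) if times else np.empty(0)
    u = np.concatenate(units) if units else np.empty(0, np.int64)
    order = np.lexsort((u, t))
    t, u = t[order], u[order]
    steps = step0 + np.floor((t - t0) / dt).astype(np.int64)
    # guard against fp edge cases at segment boundaries
    np.clip(steps, step0, step0 + int(round((t1 - t0) / dt)) - 1, out=steps)
    return steps, u


def simulate_segment(state: NetworkState, neuron: NeuronParams, plast: PlasticityParams,
                     sim: SimulationParams, I_ext_pA: np.ndarray,
                     background: BackgroundNoise | None, t_end_ms: float,
                     pending_release: np.ndarray | None = None) -> SegmentResult:
    """Advance ``state`` to ``t_end_ms`` under a constant external current.

    ``pending_release`` carries the release fractions of spikes from the last
    step of the previous segment (the one-step synaptic delay crosses segment
    boundaries); it is updated in place when given.
    """
    engine = sim.resolve_engine()
    if engine == "numba":
        from ._kernel import simulate_segment_numba
        return simulate_segment_numba(state, neuron, plast, sim, I_ext_pA,
                                      background, t_end_ms, pending_release)
    return _simulate_segment_numpy(state, neuron, plast, sim, I_ext_pA,
                                   background, t_end_ms, pending_release)


def _simulate_segment_numpy(state, neuron, plast, sim, I_ext_pA, background,
                            t_end_ms, pending_release=None):
    dt = sim.dt_ms
    n = state.n
    n_steps = int(round((t_end_ms - state.t) / dt))
    if n_steps < 0:
        raise ValueError("t_end_ms lies before the current clock")

    bg_steps, bg_units = _background_events(background, state.t, t_end_ms, dt, state.step)
    bg_ptr = 0

    pend = pending_release if pending_release is not None else np.zeros(n)
    trace_every = max(int(round(sim.trace_interval_ms / dt)), 1)

    spike_t: list[float] = []
    spike_u: list[int] = []
    trace_t: list[float] = []
    trace_j: list[float] = []

    for _ in range(n_steps):
        k = state.step
        # 1. STP relaxation
        state.u, state.x = stp_decay(state.u, state.x, plast, dt)

        # 2. event delivery -> postsynaptic current
        amps = np.zeros(n)
        pend_idx = np.flatnonzero(pend)
        for j in pend_idx:
            amps += per_spike_amplitude(state.J[:, j], state.C[:, j], pend[j], sim.g_scale)
        pend[:] = 0.0
        while bg_ptr < bg_steps.size and bg_steps[bg_ptr] == k:
            j = int(bg_units[bg_ptr])
            state.u[j], state.x[j], rel = stp_on_spike(state.u[j], state.x[j], plast)
            amps += per_spike_amplitude(state.J[:, j], state.C[:, j], rel, sim.g_scale)
            if sim.background_drives_stdp:
                state.prev_spike[j] = state.last_spike[j]
                state.last_spike[j] = state.t + dt
            bg_ptr += 1
        state.I_syn = syn_current_step(state.I_syn, amps, neuron.tau_syn, dt)

        # 3. membrane step (advances the clock), 4. STP jumps of the spikers
        spikers = membrane_step(state, I_ext_pA, neuron, dt)
        if spikers.size:
            u_new, x_new, rel = stp_on_spike(state.u[spikers], state.x[spikers], plast)
            state.u[spikers] = u_new
            state.x[spikers] = x_new
            pend[spikers] = rel
            spike_t.extend([state.t] * spikers.size)
            spike_u.extend(int(s) for s in spikers)

        # 5. plasticity
        if sim.stdp_mode == "event":
            apply_stdp(state, spikers, plast,
                       allow_self_connections=sim.allow_self_connections)
        else:
            continuous_stdp_step(state, plast,
                                 allow_self_connections=sim.allow_self_connections)

        # 6. trace
        if (state.step % trace_every) == 0:
            present = state.C != 0
            trace_t.append(state.t)
            trace_j.append(float(state.J[present].mean()) if present.any() else 0.0)

    return SegmentResult(
        spike_t_ms=np.asarray(spike_t, dtype=np.float64),
        spike_unit=np.asarray(spike_u, dtype=np.int64),
        trace_t_ms=np.asarray(trace_t, dtype=np.float64),
        trace_mean_j=np.asarray(trace_j, dtype=np.float64),
    )
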