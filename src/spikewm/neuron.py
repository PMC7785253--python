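"""Adaptive exponential integrate-and-fire (aEIF) membrane dynamics.

Two coupled variables per unit: the membrane potential ``V`` (mV) and the
adaptation current ``w`` (pA),

    C_m dV/dt = -g_L (V - E_L) + g_L * Delta_T * exp((V - V_T)/Delta_T)
                - w + I_syn + I_ext
    tau_w dw/dt = a_w (V - E_L) - w

integrated with forward Euler.  A spike is registered when ``V > V_T`` after
the update; the recorded value is the cosmetic ``V_peak``, ``V`` resets to
``E_L`` and ``w`` jumps by ``b_w``.  There is no refractory period.

Internal unit system: mV, ms, pA, nS, pF (pF * mV / ms = pA), so currents
printed in nA are converted (x1000) at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "NeuronParams",
    "membrane_step",
    "subthreshold_steady_state",
    "NoFixedPointError",
    "NumericalBlowupError",
]

#: Clamp on the exponential term's argument; only reachable between threshold
#: crossing and reset within a step, never sub-threshold.
EXP_ARG_MAX = 20.0


class NoFixedPointError(ValueError):
    """The injected current exceeds the rheobase: no subthreshold rest point."""


class NumericalBlowupError(FloatingPointError):
    """Non-finite state after an Euler step; the time step is too large."""


@dataclass(frozen=True)
class NeuronParams:
    c_m: float = 281.0       # membrane capacitance, pF
    g_l: float = 30.0        # leak conductance, nS
    e_l: float = -70.6       # resting (and reset) potential, mV
    v_t: float = -50.4       # threshold, mV
    v_peak: float = 20.0     # recorded spike value, mV
    delta_t: float = 2.0     # spike-initiation slope factor, mV
    tau_w: float = 144.0     # adaptation time constant, ms
    a_w: float = 4.0         # subthreshold adaptation, nS
    b_w_na: float = 0.0805   # spike-triggered adaptation increment, nA
    tau_syn: float = 5.0     # postsynaptic current decay time constant, ms

    def __post_init__(self) -> None:
        for name in ("c_m", "g_l", "delta_t", "tau_w", "tau_syn"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.a_w < 0 or self.b_w_na < 0:
            raise ValueError("adaptation parameters must be non-negative")
        if self.v_peak <= self.v_t:
            raise ValueError("v_peak must exceed v_t")

    @property
    def b_w(self) -> float:
        """Spike-triggered adaptation increment in pA (internal unit system)."""
        return self.b_w_na * 1000.0

    @property
    def v_reset(self) -> float:
        return self.e_l


def exponential_drive(V: np.ndarray, p: NeuronParams) -> np.ndarray:
    """g_L * Delta_T * exp((V - V_T)/Delta_T) with the overflow clamp, pA."""
    arg = np.minimum((V - p.v_t) / p.delta_t, EXP_ARG_MAX)
    return p.g_l * p.delta_t * np.exp(arg)


def membrane_step(state, I_ext: np.ndarray, p: NeuronParams, dt: float) -> np.ndarray:
    """Advance V and w by one forward-Euler step; return spiking unit indices.

    ``I_ext`` is the total external current in pA (one entry per unit); the
    network's own synaptic current ``state.I_syn`` is added internally.
    Spiking units have their spike time (the post-step clock) written to
    ``last_spike`` (the previous value moves to ``prev_spike``), V reset to
    ``E_L`` and w incremented by ``b_w``.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    V, w = state.V, state.w
    with np.errstate(over="ignore"):  # divergence is detected explicitly below
        I_tot = state.I_syn + I_ext
        dV = (-p.g_l * (V - p.e_l) + exponential_drive(V, p) - w + I_tot) * (dt / p.c_m)
        dw = (p.a_w * (V - p.e_l) - w) * (dt / p.tau_w)
        V += dV
        w += dw
    state.step += 1
    state.t = state.step * dt  # clock on the exact step grid
    if not (np.all(np.isfinite(V)) and np.all(np.isfinite(w))):
        bad = int(np.flatnonzero(~(np.isfinite(V) & np.isfinite(w)))[0])
        raise NumericalBlowupError(
            f"non-finite membrane state at t={state.t:.3f} ms (unit {bad}); "
            f"reduce dt (currently {dt} ms)"
        )

    spikers = np.flatnonzero(V > p.v_t)
    if spikers.size:
        state.prev_spike[spikers] = state.last_spike[spikers]
        state.last_spike[spikers] = state.t
        V[spikers] = p.e_l
        w[spikers] += p.b_w
    return spikers


def subthreshold_steady_state(I: float, p: NeuronParams) -> float:
    """Self-consistent rest point of the membrane/adaptation pair at constant I (pA).

    Solves ``0 = -g_L(V-E_L) + g_L*Delta_T*exp((V-V_T)/Delta_T) - a_w(V-E_L) + I``
    for the stable (lower) root.  Raises :class:`NoFixedPointError` when the
    current exceeds the rheobase of the combined V/w nullclines.  Test oracle;
    not used in simulation.
    """

    def h(V: float) -> float:
        return (
            -(p.g_l + p.a_w) * (V - p.e_l)
            + p.g_l * p.delta_t * np.exp((V - p.v_t) / p.delta_t)
            + I
        )

    # h has a single minimum; no root above it can be stable
    v_min = p.v_t + p.delta_t * np.log((p.g_l + p.a_w) / p.g_l)
    if h(v_min) > 0:
        raise NoFixedPointError(
            f"I = {I} pA exceeds the subthreshold rheobase ({-h(v_min) + I:.1f} pA)"
        )
    lo = min(p.e_l, v_min) - max(abs(I) / (p.g_l + p.a_w), 1.0) - 1.0
    return brentq(h, lo, v_min, xtol=1e-10)
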