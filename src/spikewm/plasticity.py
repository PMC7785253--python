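"""Short-term plasticity, spike-timing-dependent plasticity, synaptic currents.

Three interacting mechanisms shape transmission:

* **STP (Tsodyks-Markram)** — per presynaptic unit ``j``, a release
  probability ``u_j`` (facilitation, time constant ``tau_f``) and a
  neurotransmitter availability ``x_j`` (depression recovery ``tau_d``).
  On a presynaptic spike ``u -> u + U(1-u)`` then ``x -> (1-u)x``; between
  spikes both relax exponentially to their resting values ``U`` and 1.
  The fraction transmitted by a spike is ``u' * x`` with the post-jump u and
  the pre-decrement x.  STP variables are per-unit (shared by all efferents).

* **STDP (multiplicative, nearest-neighbour)** — a pair-based rule on the
  signed weight ``J``,

      dJ = +lambda_+ (1-J)^mu exp(-dt/tau_+)      if dt > 0   (LTP)
      dJ = -lambda_- alpha sgn(J)|J|^mu exp(dt/tau_-)  if dt <= 0  (LTD)

  with ``dt = t_post - t_pre`` the difference of the partners' most recent
  spikes.  For excitatory weights in [0, 1] the rule is soft-bounded; for
  negative (inhibitory) weights both branches are non-negative, so inhibitory
  efficacies drift monotonically toward zero and beyond — the documented
  Dale's-law violation, asserted rather than prevented.  Pairs without a
  synapse are still evaluated: a nonzero update creates the connection
  (structural plasticity), starting from J = 0.

* **Current-based transmission** — a spike of presynaptic ``j`` injects
  ``g_scale * J[i, j] * release`` pA into every connected target ``i``; the
  postsynaptic current then decays exponentially with ``tau_syn``.

Two evaluation modes for STDP are provided.  ``event`` applies the rule once
per spike (:func:`apply_stdp`).  ``continuous`` applies the rule at every
integration step to every pair whose spike-time difference is defined
(:func:`continuous_stdp_step`), so a given sign of ``dt`` keeps contributing
for as long as it persists.  The continuous reading is the package default:
it is the only one under which sustained evoked firing potentiates synapses
on the tens-of-seconds timescale of the experiments (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PlasticityParams",
    "stp_decay",
    "stp_on_spike",
    "stdp_delta",
    "apply_stdp",
    "continuous_stdp_step",
    "per_spike_amplitude",
    "syn_current_step",
]


@dataclass(frozen=True)
class PlasticityParams:
    tau_f: float = 100.0          # facilitation time constant, ms
    tau_d: float = 900.0          # depression recovery time constant, ms
    u_baseline: float = 0.80      # baseline release probability U
    tau_plus: float = 20.0        # LTP window time constant, ms
    tau_minus: float = 50.0       # LTD window time constant, ms
    lambda_plus: float = 5e-5     # LTP learning rate (per evaluation)
    lambda_minus: float = 25e-5   # LTD learning rate (per evaluation)
    mu: float = 1.0               # weight-dependence exponent
    alpha: float = 2.0            # LTD/LTP asymmetry

    def __post_init__(self) -> None:
        if not (0.0 <= self.u_baseline <= 1.0):
            raise ValueError("u_baseline must lie in [0, 1]")
        if self.tau_f <= 0 or self.tau_d <= 0:
            raise ValueError("STP time constants must be positive")
        if not (0 < self.lambda_plus < 1 and 0 < self.lambda_minus < 1):
            raise ValueError("learning rates must lie in (0, 1)")
        if self.alpha * self.lambda_minus >= 1:
            raise ValueError("alpha * lambda_minus must stay below 1 "
                             "(one depression step may not overshoot zero)")
        if self.tau_minus <= self.tau_plus:
            raise ValueError("the LTD window must be wider than the LTP window")
        if self.alpha <= 1:
            raise ValueError("alpha must exceed 1 (LTD-favouring asymmetry)")
        if self.mu <= 0:
            raise ValueError("mu must be positive")


# ----------------------------------------------------------------- STP

def stp_decay(u, x, pp: PlasticityParams, dt: float):
    """Exact exponential relaxation of (u, x) toward (U, 1) over ``dt`` ms."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    fu = np.exp(-dt / pp.tau_f)
    fx = np.exp(-dt / pp.tau_d)
    return pp.u_baseline + (u - pp.u_baseline) * fu, 1.0 + (x - 1.0) * fx


def stp_on_spike(u, x, pp: PlasticityParams):
    """Instantaneous STP jumps for a presynaptic spike.

    Returns ``(u', x', release)`` where ``u' = u + U(1-u)``,
    ``x' = (1-u')x`` and ``release = u' * x`` is the transmitted fraction
    (post-jump u, pre-decrement x).
    """
    u_new = u + pp.u_baseline * (1.0 - u)
    release = u_new * x
    x_new = (1.0 - u_new) * x
    return u_new, x_new, release


# ----------------------------------------------------------------- STDP

def _f_plus(J, mu: float):
    return (1.0 - J) ** mu


def _f_minus(J, mu: float, alpha: float):
    # signed power keeps both branches non-negative for J < 0, so inhibitory
    # weights drift toward 0 for any mu (for mu = 1 this is exactly alpha*J)
    return alpha * np.sign(J) * np.abs(J) ** mu


def stdp_delta(J, delta_t, pp: PlasticityParams):
    """Closed-form weight update of the pair rule for one evaluation.

    ``delta_t = t_post - t_pre`` in ms under the nearest-neighbour
    convention; ``delta_t = 0`` falls in the depression branch.  Accepts
    scalars or broadcastable arrays.
    """
    J = np.asarray(J, dtype=float)
    delta_t = np.asarray(delta_t, dtype=float)
    ltp = pp.lambda_plus * _f_plus(J, pp.mu) * np.exp(-delta_t / pp.tau_plus)
    ltd = -pp.lambda_minus * _f_minus(J, pp.mu, pp.alpha) * np.exp(delta_t / pp.tau_minus)
    out = np.where(delta_t > 0, ltp, ltd)
    return out if out.ndim else float(out)


def _pairing_times(state, t_now: float) -> np.ndarray:
    """Most recent spike per unit strictly before ``t_now`` (-inf if none)."""
    return np.where(state.last_spike < t_now, state.last_spike, state.prev_spike)


def apply_stdp(state, spikers, pp: PlasticityParams, *, allow_self_connections: bool = True) -> None:
    """Event-wise STDP for the units that spiked at the current clock time.

    For each spiker ``s`` (spike time ``t_s = state.t``) and every partner
    with a defined pairing time: as postsynaptic, the incoming synapse
    ``p -> s`` receives the ``dt = t_s - t_p > 0`` potentiation branch; as
    presynaptic, every outgoing synapse ``s -> q`` receives the
    ``dt = t_q - t_s <= 0`` depression branch.  Pairing always uses the
    partner's most recent spike strictly before ``t_s`` (hence the
    penultimate spike for self-pairs and simultaneous spikers) — this is
    what lets structural plasticity create self-connections.  A nonzero
    update on an absent synapse creates it (J starts from 0).  Weights are
    clamped to [-1, 1].
    """
    spikers = np.asarray(spikers, dtype=np.intp)
    if spikers.size == 0:
        return
    t_s = state.t
    pair_t = _pairing_times(state, t_s)
    defined = np.isfinite(pair_t)
    if not allow_self_connections:
        absent_self = state.C.diagonal() == 0
    for s in spikers:
        mask = defined.copy()
        if not allow_self_connections and absent_self[s]:
            mask[s] = False
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            continue
        # s as postsynaptic: LTP on incoming synapses
        dj_in = stdp_delta(state.J[s, idx], t_s - pair_t[idx], pp)
        _apply_updates(state, s, idx, dj_in, row=True)
        # s as presynaptic: LTD on outgoing synapses
        dj_out = stdp_delta(state.J[idx, s], pair_t[idx] - t_s, pp)
        _apply_updates(state, s, idx, dj_out, row=False)


def _apply_updates(state, s: int, idx: np.ndarray, dj: np.ndarray, *, row: bool) -> None:
    target = state.J[s, idx] if row else state.J[idx, s]
    new = np.clip(target + dj, -1.0, 1.0)
    created = (dj != 0.0)
    if row:
        state.J[s, idx] = new
        state.C[s, idx] |= created.astype(np.uint8)
    else:
        state.J[idx, s] = new
        state.C[idx, s] |= created.astype(np.uint8)


def continuous_stdp_step(state, pp: PlasticityParams, *, allow_self_connections: bool = True) -> None:
    """One per-timestep evaluation of the pair rule over all defined pairs.

    Brute-force reference used by the numpy engine (and as the oracle for the
    lazily-evaluated fast engine): every ordered pair (i, j) whose spike-time
    difference ``dt = last_i - last_j`` is defined receives one
    :func:`stdp_delta` update per integration step.  Self-pairs use the
    penultimate spike as the presynaptic reference, so ``dt`` is the unit's
    last inter-spike interval.
    """
    last = state.last_spike
    has = np.isfinite(last)
    if not has.any():
        return
    with np.errstate(invalid="ignore"):  # -inf - -inf for never-spiked pairs
        dt_mat = last[:, None] - last[None, :]
        np.fill_diagonal(dt_mat, last - state.prev_spike)
    defined = has[:, None] & has[None, :]
    np.fill_diagonal(defined, has & np.isfinite(state.prev_spike))
    if not allow_self_connections:
        np.fill_diagonal(defined, np.diag(state.C) != 0)
    dj = np.where(defined, stdp_delta(state.J, np.where(defined, dt_mat, 1.0), pp), 0.0)
    new_j = np.clip(state.J + dj, -1.0, 1.0)
    # an update too small to move the weight creates no synapse
    state.C |= (new_j != state.J).astype(np.uint8)
    state.J = new_j


# ----------------------------------------------------- synaptic currents

def per_spike_amplitude(J_column: np.ndarray, C_column: np.ndarray, release: float,
                        g_scale: float = 1000.0) -> np.ndarray:
    """Postsynaptic current amplitudes (pA) for one presynaptic spike.

    ``amplitude_i = g_scale * J[i, j] * release`` for connected targets,
    0 elsewhere.  ``g_scale`` converts dimensionless efficacy to pA
    (default 1000 pA = 1 nA per unit efficacy).
    """
    return np.where(C_column != 0, g_scale * J_column * release, 0.0)


def syn_current_step(I_syn: np.ndarray, incoming: np.ndarray, tau_syn: float, dt: float):
    """Exact exponential decay plus the instantaneous per-spike jumps.

    ``I_syn <- I_syn * exp(-dt/tau_syn) + incoming`` where ``incoming`` is the
    summed amplitude of all spikes delivered in this step (pA).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    return I_syn * np.exp(-dt / tau_syn) + incoming
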