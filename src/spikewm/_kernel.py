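"""Numba implementation of the simulation step loop.

Semantics are defined by the numpy engine in :mod:`spikewm.engine`; this
module reproduces them with two optimisations: the step loop is compiled, and
in ``continuous`` STDP mode the per-step multiplicative weight recursions

    LTP:  1 - J  <-  (1 - J) * (1 - lambda_+ k)       per step
    LTD:      J  <-      J   * (1 - alpha lambda_- k)  per step

(with ``k`` the fixed exponential window factor of the pair's current
spike-time difference) are applied lazily in closed form over the number of
elapsed steps, whenever the pair's spike-time difference changes (either
endpoint spikes) or current weights are observed (event delivery, traces,
segment end).  Pairs are only ever caught up at such endpoint events, so the
last-applied step of pair (i, j) is ``max(row_stamp[i], col_stamp[j])`` with
one stamp pair per unit — no per-pair bookkeeping.  Because spike times sit
on the integration grid, the per-step factor and its logarithm are
precomputed per whole-step time difference; a pair's catch-up over ``n``
steps is then one table lookup and at most one ``exp``.  Differences beyond
38 window time constants are skipped outright — there ``1 - lambda*k``
rounds to 1 in double precision, so the reference recursion is a no-op too.
The closed form requires ``mu = 1``; other exponents fall back to the numpy
engine.  Equivalence with the brute-force per-step reference is covered by
the test suite.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .neuron import NumericalBlowupError

NEVER = -np.inf
_DEFINED = -1e17  # spike-time sentinel threshold
_WINDOW_CUTOFF = 38.0  # in units of the STDP window time constant


class SpikeBufferOverflow(RuntimeError):
    pass


def _window_tables(lam: float, tau: float, dt: float) -> np.ndarray:
    """Interleaved per-step factor ``1 - lam*exp(-d*dt/tau)`` and its log,
    indexed by the whole-step time lag d."""
    n = int(_WINDOW_CUTOFF * tau / dt) + 2
    d = np.arange(n, dtype=np.float64)
    k = np.exp(-(d * dt) / tau)
    tab = np.empty((n, 2), dtype=np.float64)
    tab[:, 0] = 1.0 - lam * k
    with np.errstate(divide="ignore"):
        tab[:, 1] = np.log1p(-lam * k)
    return tab


@njit(cache=True, inline="always")
def _flush_pair(J, C, last_ms, prev_ms, row_stamp, col_stamp, i, j, upto,
                inv_dt, tab_ltp, tab_ltd, allow_self):
    """Catch pair (i, j) up to (but not including) step ``upto``.

    The caller is responsible for advancing ``row_stamp[i]`` / ``col_stamp[j]``
    after completing a whole row/column pass.
    """
    nst = upto - max(row_stamp[i], col_stamp[j])
    if nst <= 0:
        return
    li = last_ms[i]
    lj = prev_ms[j] if i == j else last_ms[j]
    if not (li > _DEFINED and lj > _DEFINED):
        return
    dtp = li - lj
    if dtp > 0.0:
        d = int(dtp * inv_dt + 0.5)
        if d >= tab_ltp.shape[0]:
            return
        fac = tab_ltp[d, 0] if nst == 1 else np.exp(nst * tab_ltp[d, 1])
        jj = J[i, j]
        if jj == 0.0 and fac < 1.0:
            # structural plasticity: a first effective potentiation creates
            # the synapse (a nonzero weight implies a present synapse, so C
            # needs touching only here)
            if i != j or allow_self:
                C[i, j] = 1
            else:
                return
        J[i, j] = 1.0 - (1.0 - jj) * fac
    else:
        jj = J[i, j]
        if jj == 0.0:
            return
        d = int(-dtp * inv_dt + 0.5)
        if d >= tab_ltd.shape[0]:
            return
        fac = tab_ltd[d, 0] if nst == 1 else np.exp(nst * tab_ltd[d, 1])
        J[i, j] = jj * fac


@njit(cache=True)
def _flush_col(J, C, last_ms, prev_ms, row_stamp, col_stamp, j, upto,
               inv_dt, tab_ltp, tab_ltd, allow_self):
    n = J.shape[0]
    lj_all = last_ms[j]
    cs = col_stamp[j]
    if lj_all > _DEFINED:
        n_ltp = tab_ltp.shape[0]
        n_ltd = tab_ltd.shape[0]
        for i in range(n):
            nst = upto - max(row_stamp[i], cs)
            if nst <= 0:
                continue
            li = last_ms[i]
            if not li > _DEFINED:
                continue
            lj = prev_ms[j] if i == j else lj_all
            if not lj > _DEFINED:
                continue
            dtp = li - lj
            if dtp > 0.0:
                d = int(dtp * inv_dt + 0.5)
                if d >= n_ltp:
                    continue
                fac = tab_ltp[d, 0] if nst == 1 else np.exp(nst * tab_ltp[d, 1])
                jj = J[i, j]
                if jj == 0.0 and fac < 1.0:
                    if i != j or allow_self:
                        C[i, j] = 1
                    else:
                        continue
                J[i, j] = 1.0 - (1.0 - jj) * fac
            else:
                jj = J[i, j]
                if jj == 0.0:
                    continue
                d = int(-dtp * inv_dt + 0.5)
                if d >= n_ltd:
                    continue
                fac = tab_ltd[d, 0] if nst == 1 else np.exp(nst * tab_ltd[d, 1])
                J[i, j] = jj * fac
    col_stamp[j] = upto


@njit(cache=True)
def _flush_unit(J, C, last_ms, prev_ms, row_stamp, col_stamp, s, upto,
                inv_dt, tab_ltp, tab_ltd, allow_self):
    n = J.shape[0]
    li = last_ms[s]
    rs = row_stamp[s]
    if li > _DEFINED:
        n_ltp = tab_ltp.shape[0]
        n_ltd = tab_ltd.shape[0]
        for p in range(n):
            nst = upto - max(rs, col_stamp[p])
            if nst <= 0:
                continue
            lj = prev_ms[s] if p == s else last_ms[p]
            if not lj > _DEFINED:
                continue
            dtp = li - lj
            if dtp > 0.0:
                d = int(dtp * inv_dt + 0.5)
                if d >= n_ltp:
                    continue
                fac = tab_ltp[d, 0] if nst == 1 else np.exp(nst * tab_ltp[d, 1])
                jj = J[s, p]
                if jj == 0.0 and fac < 1.0:
                    if s != p or allow_self:
                        C[s, p] = 1
                    else:
                        continue
                J[s, p] = 1.0 - (1.0 - jj) * fac
            else:
                jj = J[s, p]
                if jj == 0.0:
                    continue
                d = int(-dtp * inv_dt + 0.5)
                if d >= n_ltd:
                    continue
                fac = tab_ltd[d, 0] if nst == 1 else np.exp(nst * tab_ltd[d, 1])
                J[s, p] = jj * fac
    # advance the row stamp first so the column pass skips the already
    # flushed self-pair
    row_stamp[s] = upto
    _flush_col(J, C, last_ms, prev_ms, row_stamp, col_stamp, s, upto,
               inv_dt, tab_ltp, tab_ltd, allow_self)


@njit(cache=True)
def _flush_all(J, C, last_ms, prev_ms, row_stamp, col_stamp, upto,
               inv_dt, tab_ltp, tab_ltd, allow_self):
    n = J.shape[0]
    for i in range(n):
        for j in range(n):
            _flush_pair(J, C, last_ms, prev_ms, row_stamp, col_stamp, i, j, upto,
                        inv_dt, tab_ltp, tab_ltd, allow_self)
    for i in range(n):
        row_stamp[i] = upto
        col_stamp[i] = upto


@njit(cache=True)
def _mean_present(J, C):
    n = J.shape[0]
    tot = 0.0
    cnt = 0
    for i in range(n):
        for j in range(n):
            if C[i, j] != 0:
                tot += J[i, j]
                cnt += 1
    return tot / cnt if cnt > 0 else 0.0


@njit(cache=True)
def _run(V, w, u, x, I_syn, J, C, last_ms, prev_ms, row_stamp, col_stamp, pend,
         is_cont, allow_self, bg_stdp,
         dt, c_m, g_l, e_l, v_t, delta_t, tau_w, a_w, b_w, tau_syn,
         tau_f, tau_d, U, tau_p, tau_m, lam_p, lam_m, mu, alpha,
         tab_ltp, tab_ltd,
         g_scale, I_ext, bg_steps, bg_units,
         step0, n_steps, trace_every,
         sp_t, sp_u, tr_t, tr_j):
    n = V.shape[0]
    fu = np.exp(-dt / tau_f)
    fx = np.exp(-dt / tau_d)
    fs = np.exp(-dt / tau_syn)
    inv_dt = 1.0 / dt
    n_sp = 0
    n_tr = 0
    bg_ptr = 0
    spikers = np.empty(n, np.int64)
    amps = np.zeros(n)

    for it in range(n_steps):
        k = step0 + it
        t_next = (k + 1) * dt

        # 1. STP relaxation
        for j in range(n):
            u[j] = U + (u[j] - U) * fu
            x[j] = 1.0 + (x[j] - 1.0) * fx

        # 2. event delivery -> postsynaptic current.  A weight can only be
        # nonzero on a present synapse, so the connectivity mask is implicit.
        for i in range(n):
            amps[i] = 0.0
        for j in range(n):
            if pend[j] != 0.0:
                rel = pend[j]
                if is_cont:
                    _flush_col(J, C, last_ms, prev_ms, row_stamp, col_stamp, j, k,
                               inv_dt, tab_ltp, tab_ltd, allow_self)
                for i in range(n):
                    amps[i] += g_scale * J[i, j] * rel
                pend[j] = 0.0
        while bg_ptr < bg_steps.shape[0] and bg_steps[bg_ptr] == k:
            j = bg_units[bg_ptr]
            un = u[j] + U * (1.0 - u[j])
            rel = un * x[j]
            x[j] = (1.0 - un) * x[j]
            u[j] = un
            if is_cont:
                _flush_col(J, C, last_ms, prev_ms, row_stamp, col_stamp, j, k,
                           inv_dt, tab_ltp, tab_ltd, allow_self)
            for i in range(n):
                amps[i] += g_scale * J[i, j] * rel
            if bg_stdp:
                if is_cont:
                    _flush_unit(J, C, last_ms, prev_ms, row_stamp, col_stamp, j, k,
                                inv_dt, tab_ltp, tab_ltd, allow_self)
                prev_ms[j] = last_ms[j]
                last_ms[j] = t_next
            bg_ptr += 1
        for i in range(n):
            I_syn[i] = I_syn[i] * fs + amps[i]

        # 3. membrane step (spike times land on the post-step clock)
        n_spk = 0
        for i in range(n):
            vv = V[i]
            arg = (vv - v_t) / delta_t
            if arg > 20.0:
                arg = 20.0
            i_tot = I_syn[i] + I_ext[i]
            dv = (-g_l * (vv - e_l) + g_l * delta_t * np.exp(arg) - w[i] + i_tot) * (dt / c_m)
            dw = (a_w * (vv - e_l) - w[i]) * (dt / tau_w)
            vv = vv + dv
            w[i] = w[i] + dw
            if not (np.isfinite(vv) and np.isfinite(w[i])):
                return n_sp, n_tr, 1
            if vv > v_t:
                spikers[n_spk] = i
                n_spk += 1
                vv = e_l
                w[i] = w[i] + b_w
            V[i] = vv

        # 4. STP jumps of the spikers (release buffered for the next step)
        for si in range(n_spk):
            s = spikers[si]
            un = u[s] + U * (1.0 - u[s])
            rel = un * x[s]
            x[s] = (1.0 - un) * x[s]
            u[s] = un
            pend[s] = rel
            if n_sp >= sp_t.shape[0]:
                return n_sp, n_tr, 2
            sp_t[n_sp] = t_next
            sp_u[n_sp] = s
            n_sp += 1

        # 5. STDP (pairing times are the strictly-prior spike times)
        if n_spk > 0:
            if is_cont:
                for si in range(n_spk):
                    _flush_unit(J, C, last_ms, prev_ms, row_stamp, col_stamp,
                                spikers[si], k, inv_dt, tab_ltp, tab_ltd, allow_self)
            else:
                for si in range(n_spk):
                    s = spikers[si]
                    skip_self = (not allow_self) and C[s, s] == 0
                    for p in range(n):
                        pt = last_ms[p]
                        if not pt > _DEFINED:
                            continue
                        if p == s and skip_self:
                            continue
                        # incoming synapse p -> s: potentiation
                        dtp = t_next - pt
                        jj = J[s, p]
                        dj = lam_p * (1.0 - jj) ** mu * np.exp(-dtp / tau_p)
                        jn = jj + dj
                        if jn > 1.0:
                            jn = 1.0
                        J[s, p] = jn
                        if dj != 0.0:
                            C[s, p] = 1
                        # outgoing synapse s -> p: depression
                        jj = J[p, s]
                        sgn = 1.0 if jj > 0.0 else (-1.0 if jj < 0.0 else 0.0)
                        dj = -lam_m * (alpha * sgn * np.abs(jj) ** mu) * np.exp((pt - t_next) / tau_m)
                        jn = jj + dj
                        if jn < -1.0:
                            jn = -1.0
                        J[p, s] = jn
                        if dj != 0.0:
                            C[p, s] = 1
            for si in range(n_spk):
                s = spikers[si]
                prev_ms[s] = last_ms[s]
                last_ms[s] = t_next

        # 6. mean-efficacy trace
        if trace_every > 0 and ((k + 1) % trace_every) == 0:
            if is_cont:
                _flush_all(J, C, last_ms, prev_ms, row_stamp, col_stamp, k + 1,
                           inv_dt, tab_ltp, tab_ltd, allow_self)
            tr_t[n_tr] = t_next
            tr_j[n_tr] = _mean_present(J, C)
            n_tr += 1

    if is_cont:
        _flush_all(J, C, last_ms, prev_ms, row_stamp, col_stamp, step0 + n_steps,
                   inv_dt, tab_ltp, tab_ltd, allow_self)
    return n_sp, n_tr, 0


def simulate_segment_numba(state, neuron, plast, sim, I_ext_pA, background,
                           t_end_ms, pending_release=None):
    """Wrapper marshalling :class:`NetworkState` in and out of the kernel."""
    from .engine import SegmentResult, _background_events

    is_cont = sim.stdp_mode == "continuous"
    if is_cont and plast.mu != 1.0:
        raise NotImplementedError(
            "the numba engine's closed-form continuous STDP requires mu = 1; "
            "use engine='numpy' for other exponents"
        )
    dt = sim.dt_ms
    n_steps = int(round((t_end_ms - state.t) / dt))
    if n_steps < 0:
        raise ValueError("t_end_ms lies before the current clock")
    n = state.n
    bg_steps, bg_units = _background_events(background, state.t, t_end_ms, dt, state.step)

    pend = pending_release if pending_release is not None else np.zeros(n)
    trace_every = max(int(round(sim.trace_interval_ms / dt)), 1)
    cap = int(n * (n_steps * dt / 1000.0) * sim.max_mean_rate_hz) + 1024
    sp_t = np.empty(cap, np.float64)
    sp_u = np.empty(cap, np.int64)
    n_tr_max = n_steps // trace_every + 1
    tr_t = np.empty(n_tr_max, np.float64)
    tr_j = np.empty(n_tr_max, np.float64)

    tab_ltp = _window_tables(plast.lambda_plus, plast.tau_plus, dt)
    tab_ltd = _window_tables(plast.alpha * plast.lambda_minus, plast.tau_minus, dt)

    n_sp, n_tr, status = _run(
        state.V, state.w, state.u, state.x, state.I_syn, state.J, state.C,
        state.last_spike, state.prev_spike, state.row_stamp, state.col_stamp, pend,
        is_cont, sim.allow_self_connections, sim.background_drives_stdp,
        dt, neuron.c_m, neuron.g_l, neuron.e_l, neuron.v_t, neuron.delta_t,
        neuron.tau_w, neuron.a_w, neuron.b_w, neuron.tau_syn,
        plast.tau_f, plast.tau_d, plast.u_baseline, plast.tau_plus, plast.tau_minus,
        plast.lambda_plus, plast.lambda_minus, plast.mu, plast.alpha,
        tab_ltp, tab_ltd,
        sim.g_scale, np.ascontiguousarray(I_ext_pA, dtype=np.float64),
        bg_steps, bg_units,
        state.step, n_steps, trace_every,
        sp_t, sp_u, tr_t, tr_j,
    )
    state.step += n_steps
    state.t = state.step * dt
    if status == 1:
        raise NumericalBlowupError(
            f"non-finite membrane state near t={state.t:.3f} ms; reduce dt ({dt} ms)"
        )
    if status == 2:
        raise SpikeBufferOverflow(
            f"network mean rate exceeded {sim.max_mean_rate_hz} Hz; "
            "likely runaway excitation"
        )
    return SegmentResult(
        spike_t_ms=sp_t[:n_sp].copy(),
        spike_unit=sp_u[:n_sp].copy(),
        trace_t_ms=tr_t[:n_tr].copy(),
        trace_mean_j=tr_j[:n_tr].copy(),
    )
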