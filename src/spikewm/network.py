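"""Network construction and global simulation state.

The network is a population of ``N = N_E + N_I`` adaptive exponential
integrate-and-fire units connected by signed, plastic synapses.  Connectivity
is initialised sparse (a fixed fraction ``c`` of all ordered off-diagonal
pairs) and obeys Dale's law at time zero: efferents of excitatory units carry
the positive initial efficacy, efferents of inhibitory units the negative one.
Structural plasticity later adds synapses (including self-connections) and can
push inhibitory efficacies across zero, so Dale violations are a *reported*
quantity, not an enforced constraint.

Orientation convention: ``J[i, j]`` / ``C[i, j]`` is the synapse from
presynaptic unit ``j`` onto postsynaptic unit ``i``.  Units are indexed
0-based in memory; all external files and reports are 1-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "NetworkParams",
    "NetworkState",
    "ConnectionStats",
    "build_network",
    "connection_stats",
    "initial_connection_count",
]

#: Sentinel for "this unit has never spiked" (ms).
NEVER = -np.inf


class ConfigurationError(ValueError):
    """Raised when a parameter set violates its documented invariants."""


@dataclass(frozen=True)
class NetworkParams:
    """Population sizes and initial synaptic efficacies.

    Efficacies are dimensionless; the conversion to postsynaptic current is
    a simulation-level scale (see :mod:`spikewm.plasticity`).
    """

    c: float = 0.2           # initial probability of synaptic contact
    n_e: int = 400           # number of excitatory units
    n_i: int = 100           # number of inhibitory units
    j_ee: float = 0.65       # initial E -> E efficacy
    j_ie: float = 0.65       # initial E -> I efficacy
    j_ii: float = -1.0       # initial I -> I efficacy
    j_ei: float = -1.0       # initial I -> E efficacy

    def __post_init__(self) -> None:
        if not (isinstance(self.n_e, (int, np.integer)) and self.n_e > 0):
            raise ConfigurationError(f"n_e must be a positive integer, got {self.n_e!r}")
        if not (isinstance(self.n_i, (int, np.integer)) and self.n_i > 0):
            raise ConfigurationError(f"n_i must be a positive integer, got {self.n_i!r}")
        if not (0.0 < self.c <= 1.0):
            raise ConfigurationError(f"c must lie in (0, 1], got {self.c!r}")
        if self.j_ee < 0 or self.j_ie < 0:
            raise ConfigurationError("excitatory efferent efficacies must be >= 0")
        if self.j_ii > 0 or self.j_ei > 0:
            raise ConfigurationError("inhibitory efferent efficacies must be <= 0")

    @property
    def n(self) -> int:
        return self.n_e + self.n_i


@dataclass
class NetworkState:
    """Full mutable simulation state.

    ``last_spike``/``prev_spike`` hold each unit's most recent and
    second-most-recent somatic spike times in ms (``-inf`` if absent); the
    penultimate time is what spike-timing plasticity pairs against when the
    partner spikes in the very same step (and for self-pairs).
    """

    t: float                      # simulation clock, ms
    V: np.ndarray                 # membrane potential, mV
    w: np.ndarray                 # adaptation current, pA
    u: np.ndarray                 # release probability per presynaptic unit
    x: np.ndarray                 # neurotransmitter availability per presynaptic unit
    I_syn: np.ndarray             # postsynaptic current, pA
    J: np.ndarray                 # weight matrix, J[i, j] = synapse j -> i
    C: np.ndarray                 # binary connectivity, same orientation (uint8)
    last_spike: np.ndarray        # most recent spike time per unit, ms
    prev_spike: np.ndarray        # penultimate spike time per unit, ms
    is_excitatory: np.ndarray     # bool flag per unit
    step: int = 0                 # integration step counter (t = step * dt)
    # lazily-applied update bookkeeping of the continuous plasticity engine:
    # pair (i, j) is current up to step max(row_stamp[i], col_stamp[j])
    row_stamp: np.ndarray = field(default=None, repr=False)
    col_stamp: np.ndarray = field(default=None, repr=False)

    @property
    def n(self) -> int:
        return self.V.shape[0]


def initial_connection_count(params: NetworkParams) -> int:
    """Number of initial synapses: round(c * N * (N - 1)), seed-independent."""
    n = params.n
    return int(round(params.c * n * (n - 1)))


def build_network(params: NetworkParams, seed: int) -> NetworkState:
    """Construct the initial network.

    Exactly ``round(c * N * (N-1))`` ordered off-diagonal pairs are sampled
    without replacement (the stated contact probability is treated as a
    population fraction, so the realised density is exact, not Bernoulli).
    E/I identity is a uniform random assignment independent of the two
    stimulus subpopulations.  Identical ``params`` and ``seed`` reproduce the
    state bit for bit.
    """
    n = params.n
    rng = np.random.default_rng(seed)

    is_exc = np.zeros(n, dtype=bool)
    is_exc[rng.permutation(n)[: params.n_e]] = True

    k = initial_connection_count(params)
    # enumerate ordered off-diagonal pairs 0 .. N(N-1)-1 and sample a fixed count
    flat = rng.choice(n * (n - 1), size=k, replace=False)
    i = flat // (n - 1)
    j = flat % (n - 1)
    j = np.where(j >= i, j + 1, j)  # skip the diagonal

    C = np.zeros((n, n), dtype=np.uint8)
    C[i, j] = 1

    # efferent sign/value set by the presynaptic unit's class and the
    # postsynaptic unit's class (columns = presynaptic)
    J = np.zeros((n, n), dtype=np.float64)
    pre_exc = is_exc[j]
    post_exc = is_exc[i]
    vals = np.where(
        pre_exc,
        np.where(post_exc, params.j_ee, params.j_ie),
        np.where(post_exc, params.j_ei, params.j_ii),
    )
    J[i, j] = vals

    return NetworkState(
        t=0.0,
        V=np.full(n, np.nan),   # set to E_L by the caller holding NeuronParams
        w=np.zeros(n),
        u=np.full(n, np.nan),   # set to U by the caller holding PlasticityParams
        x=np.ones(n),
        I_syn=np.zeros(n),
        J=J,
        C=C,
        last_spike=np.full(n, NEVER),
        prev_spike=np.full(n, NEVER),
        is_excitatory=is_exc,
        step=0,
        row_stamp=np.zeros(n, dtype=np.int64),
        col_stamp=np.zeros(n, dtype=np.int64),
    )


@dataclass(frozen=True)
class ConnectionStats:
    density: float
    n_excitatory: int
    n_inhibitory: int
    n_connections: int
    dale_violations: int
    self_connections: int


def connection_stats(state: NetworkState) -> ConnectionStats:
    """Exact connectivity summary (density, Dale violations, self-connections).

    Density is counted over ordered off-diagonal pairs, N*(N-1).  A Dale
    violation is a present synapse whose weight sign contradicts the
    presynaptic unit's class (zero-weight synapses do not count).
    """
    n = state.n
    present = state.C != 0
    n_conn = int(present.sum())
    off_diag = n * (n - 1)
    # denominator is the number of ordered off-diagonal pairs, so a fully
    # connected network with self-connections reads slightly above 1
    density = n_conn / off_diag if off_diag else 0.0
    pre_exc = state.is_excitatory[np.newaxis, :]
    viol = present & ((state.J < 0) & pre_exc | (state.J > 0) & ~pre_exc)
    return ConnectionStats(
        density=density,
        n_excitatory=int(state.is_excitatory.sum()),
        n_inhibitory=int((~state.is_excitatory).sum()),
        n_connections=n_conn,
        dale_violations=int(viol.sum()),
        self_connections=int(np.diag(present).sum()),
    )
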