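"""Network construction and synaptic-weight calibration.

Neurons are indexed globally: excitatory ``0 .. N_exc-1``, inhibitory
``N_exc .. N_exc+N_inh-1``.  The synapse table stores a flat directed edge
list together with CSR views by presynaptic (out-edges) and postsynaptic
(in-edges) neuron, which is the layout the simulation kernel consumes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import (ConfigError, NetworkConfig, NeuronParams, RingConfig,
                     WeightDist)

__all__ = [
    "SynapseTable",
    "build_network",
    "build_ring",
    "calibrate_weights",
    "calibrate_conductance_scale",
    "peak_depolarization",
    "min_spikes_to_threshold",
    "CalibrationError",
]

CLASS_CODES = {"EE": 0, "EI": 1, "IE": 2, "II": 3}
CLASS_NAMES = {v: k for k, v in CLASS_CODES.items()}


class CalibrationError(RuntimeError):
    """Raised when the requested depolarization target is unreachable."""


@dataclass
class SynapseTable:
    """Directed edge list with CSR views.

    ``pre``/``post`` are global neuron ids, ``weight`` the synaptic weights,
    ``cls`` the class code (0=EE, 1=EI, 2=IE, 3=II; first letter = target
    population).  ``u`` holds per-excitatory-neuron synaptic efficacies
    (short-term resources) shared by all EE out-edges of that neuron.
    """

    N_exc: int
    N_inh: int
    pre: np.ndarray
    post: np.ndarray
    weight: np.ndarray
    cls: np.ndarray

    def __post_init__(self) -> None:
        self.pre = np.asarray(self.pre, dtype=np.int64)
        self.post = np.asarray(self.post, dtype=np.int64)
        self.weight = np.asarray(self.weight, dtype=np.float64)
        self.cls = np.asarray(self.cls, dtype=np.int8)
        if np.any(self.pre == self.post):
            raise ConfigError("self-edges are not allowed")
        if np.any(self.weight < 0):
            raise ConfigError("weights must be non-negative")
        self._build_csr()

    def _build_csr(self) -> None:
        N = self.N
        order = np.argsort(self.pre, kind="stable")
        self.out_edges = order.astype(np.int64)
        self.out_indptr = np.zeros(N + 1, dtype=np.int64)
        np.add.at(self.out_indptr[1:], self.pre, 1)
        np.cumsum(self.out_indptr, out=self.out_indptr)
        order_in = np.argsort(self.post, kind="stable")
        self.in_edges = order_in.astype(np.int64)
        self.in_indptr = np.zeros(N + 1, dtype=np.int64)
        np.add.at(self.in_indptr[1:], self.post, 1)
        np.cumsum(self.in_indptr, out=self.in_indptr)

    @property
    def N(self) -> int:
        return self.N_exc + self.N_inh

    @property
    def n_edges(self) -> int:
        return self.pre.size

    def mean_weight(self, cls: str) -> float:
        mask = self.cls == CLASS_CODES[cls]
        return float(self.weight[mask].mean()) if mask.any() else 0.0

    def in_degree(self, post_pop: str, pre_pop: str) -> np.ndarray:
        """Per-neuron in-degree of class (post_pop <- pre_pop)."""
        code = CLASS_CODES[post_pop + pre_pop]
        counts = np.zeros(self.N, dtype=np.int64)
        mask = self.cls == code
        np.add.at(counts, self.post[mask], 1)
        sl = (slice(0, self.N_exc) if post_pop == "E"
              else slice(self.N_exc, self.N))
        return counts[sl]


def _sample_in_edges(rng, post_ids, source_lo, source_hi, k):
    """Choose k distinct presynaptic partners per postsynaptic neuron."""
    n_src = source_hi - source_lo
    pres = np.empty((post_ids.size, k), dtype=np.int64)
    for row, pid in enumerate(post_ids):
        exclude_self = source_lo <= pid < source_hi
        choice = rng.choice(n_src - (1 if exclude_self else 0), size=k,
                            replace=False)
        if exclude_self:
            local = pid - source_lo
            choice = np.where(choice >= local, choice + 1, choice)
        pres[row] = choice + source_lo
    return pres


def build_network(config: NetworkConfig) -> SynapseTable:
    """Build the sparse random network with exact per-class in-degrees.

    Every excitatory neuron receives exactly ``k_EE`` excitatory and ``k_EI``
    inhibitory in-edges, every inhibitory neuron ``k_IE`` and ``k_II``.
    Weights are log-normal, clipped to ``(0, w_max]`` of their class.
    Deterministic for a fixed ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    NE, NI = config.N_exc, config.N_inh
    exc = np.arange(NE)
    inh = np.arange(NE, NE + NI)
    blocks = []  # (pre, post, cls)
    plan = [
        ("EE", exc, 0, NE, config.k_EE),
        ("EI", exc, NE, NE + NI, config.k_EI),
        ("IE", inh, 0, NE, config.k_IE),
        ("II", inh, NE, NE + NI, config.k_II),
    ]
    pre_l, post_l, w_l, c_l = [], [], [], []
    for cls, posts, lo, hi, k in plan:
        if k == 0 or posts.size == 0:
            continue
        pres = _sample_in_edges(rng, posts, lo, hi, k)
        n = pres.size
        w = config.weights[cls].sample(n, rng)
        np.clip(w, np.finfo(float).tiny, config.w_max(cls), out=w)
        pre_l.append(pres.ravel())
        post_l.append(np.repeat(posts, k))
        w_l.append(w)
        c_l.append(np.full(n, CLASS_CODES[cls], dtype=np.int8))
    if not pre_l:
        empty = np.empty(0)
        return SynapseTable(NE, NI, empty.astype(np.int64),
                            empty.astype(np.int64), empty,
                            empty.astype(np.int8))
    return SynapseTable(NE, NI, np.concatenate(pre_l),
                        np.concatenate(post_l), np.concatenate(w_l),
                        np.concatenate(c_l))


def build_ring(config: RingConfig) -> SynapseTable:
    """Ring of E-I populations with distance-decaying excitatory coupling.

    Intra-population wiring follows :func:`build_network` per population.
    Each excitatory neuron additionally receives ``k_cross`` excitatory
    in-edges from every other population, with weight
    ``coupling * exp(-d/decay) * mean_w_EE`` where ``d`` is the ring
    distance.  With a single population this reduces exactly to
    :func:`build_network`.
    """
    P = config.n_populations
    pop = config.population
    NE, NI = pop.N_exc, pop.N_inh
    npp = NE + NI  # neurons per population
    pre_l, post_l, w_l, c_l = [], [], [], []
    for p in range(P):
        sub = build_network(
            NetworkConfig(**{**pop.__dict__,
                             "seed": pop.seed + 1000003 * p}))
        # remap local ids: local exc [0,NE) -> global, inh likewise
        off_e = p * NE
        off_i = P * NE + p * NI
        def remap(ids):
            return np.where(ids < NE, ids + off_e, ids - NE + off_i)
        pre_l.append(remap(sub.pre))
        post_l.append(remap(sub.post))
        w_l.append(sub.weight)
        c_l.append(sub.cls)
    if P > 1 and config.coupling > 0 and config.k_cross > 0:
        rng = np.random.default_rng(config.seed + 7)
        w_mean = pop.weights["EE"].mean
        for p in range(P):
            for qp in range(P):
                if qp == p:
                    continue
                d = min(abs(p - qp), P - abs(p - qp))
                w = config.coupling * np.exp(-d / config.decay) * w_mean
                posts = np.arange(p * NE, (p + 1) * NE)
                pres = rng.integers(qp * NE, (qp + 1) * NE,
                                    size=(NE, config.k_cross))
                pre_l.append(pres.ravel())
                post_l.append(np.repeat(posts, config.k_cross))
                w_l.append(np.full(NE * config.k_cross, w))
                c_l.append(np.full(NE * config.k_cross, CLASS_CODES["EE"],
                                   dtype=np.int8))
    return SynapseTable(P * NE, P * NI, np.concatenate(pre_l),
                        np.concatenate(post_l), np.concatenate(w_l),
                        np.concatenate(c_l))


def peak_depolarization(n_spikes: int, w: float, params: NeuronParams,
                        dt: float = 0.005, T: float = 120.0) -> float:
    """Peak membrane voltage after n synchronous excitatory spikes at rest.

    Integrates the single-neuron conductance equation from ``v_rest`` with
    ``g_exc(t) = n * w * g0_exc * exp(-t/tau_syn_exc)`` (fine fixed-step
    integration; exact exponential decay of the conductance).
    """
    G0 = n_spikes * w * params.g0_exc
    steps = int(T / dt)
    t = dt * np.arange(steps)
    g = G0 * np.exp(-t / params.tau_syn_exc)
    v = params.v_rest
    vmax = v
    inv_tm = dt / params.tau_m
    vL, VRe = params.v_leak, params.V_R_exc
    for gi in g:
        v += inv_tm * ((vL - v) + gi * (VRe - v))
        if v > vmax:
            vmax = v
    return float(vmax)


def min_spikes_to_threshold(w: float, params: NeuronParams,
                            n_max: int = 1000, **kw) -> int:
    """Minimal number of synchronous spikes of weight w reaching v_th."""
    for n in range(1, n_max + 1):
        if peak_depolarization(n, w, params, **kw) >= params.v_th:
            return n
    raise CalibrationError(
        f"threshold not reached with {n_max} synchronous spikes")


def calibrate_weights(config: NetworkConfig, params: NeuronParams,
                      n_target: int = 14, cv: float = 0.2) -> WeightDist:
    """Excitatory weight law such that ``n_target`` synchronous mean-weight
    spikes just depolarize a resting neuron to threshold.

    Bisects the mean weight; the returned law keeps the configured
    coefficient of variation.  Raises :class:`CalibrationError` when the
    threshold is unreachable (e.g. reverse potential below threshold).
    """
    if not 1 <= n_target <= max(config.k_EE, 1):
        raise ConfigError("require 1 <= n_target <= k_EE")
    if params.V_R_exc <= params.v_th:
        raise CalibrationError("excitatory reverse potential below threshold")
    lo, hi = 1e-8, 1.0
    while peak_depolarization(n_target, hi, params) < params.v_th:
        hi *= 2.0
        if hi > 1e6:
            raise CalibrationError("threshold unreachable")
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if peak_depolarization(n_target, mid, params) < params.v_th:
            lo = mid
        else:
            hi = mid
    return WeightDist(mean=hi, cv=cv)  # upper end: n_target surely reaches


def calibrate_conductance_scale(params: NeuronParams, w_mean: float = 0.54,
                                n_target: int = 14) -> float:
    """Conductance increment g0 such that ``n_target`` synchronous spikes of
    weight ``w_mean`` reach threshold from rest.

    This fixes the weight unit so that printed weight tables (W_EE = 0.54
    etc.) and the synchronous-spike calibration rule are mutually
    consistent.
    """
    lo, hi = 1e-6, 1.0
    def peak(g0):
        p = NeuronParams(**{**params.__dict__, "g0_exc": g0})
        return peak_depolarization(n_target, w_mean, p)
    while peak(hi) < params.v_th:
        hi *= 2.0
        if hi > 1e6:
            raise CalibrationError("threshold unreachable")
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if peak(mid) < params.v_th:
            lo = mid
        else:
            hi = mid
    return hi
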