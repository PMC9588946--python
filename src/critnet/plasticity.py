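"""Pair-based STDP, Tsodyks-Markram short-term depression, and the averaged
weight-evolution ODEs used by the mean-field analysis.

The online simulator applies the same trace-based rule inside its compiled
kernel; the functions here are the reference, operation-level implementations
(plus the offline replay used to validate the kernel against exhaustive
all-pairs summation).

Conventions: ``dt = t_post - t_pre >= 0`` (including coincident spikes) takes
the potentiation branch ``+A_plus exp(-dt/tau_plus)``; ``dt < 0`` the
depression branch ``-A_minus exp(dt/tau_minus)``.  The kernel class is set by
the presynaptic population: E-type for EE and IE synapses, I-type for EI and
II.  Rates entering the averaged ODEs are in Hz, times in ms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import SynapseTable
from .params import STDPKernel, STPParams

__all__ = [
    "stdp_delta", "TraceState", "stdp_on_spike", "replay_stdp",
    "stp_on_pre_spike", "stp_decay", "stationary_efficacy",
    "effective_weight", "CorrelationKernel", "mean_weight_ode_rhs",
    "stationary_ratio_from_kernels", "StabilityError",
]


class StabilityError(ValueError):
    """Kernel-integral signs violate the balance/stability conditions."""


def stdp_delta(dt: float, kernel: STDPKernel) -> float:
    """Weight change for a single pre/post pair, dt = t_post - t_pre."""
    if dt >= 0:
        return kernel.A_plus * np.exp(-dt / kernel.tau_plus)
    return -kernel.A_minus * np.exp(dt / kernel.tau_minus)


@dataclass
class TraceState:
    """Exponential spike traces realizing all-to-all STDP pairing.

    ``trace_plus[j]`` sums ``exp(-(t - t_spike)/tau_plus)`` over past spikes
    of neuron j (used when j is presynaptic), ``trace_minus`` likewise with
    ``tau_minus`` (used when j is postsynaptic).
    """

    trace_plus: np.ndarray
    trace_minus: np.ndarray
    t: float = 0.0

    @classmethod
    def zeros(cls, n: int) -> "TraceState":
        return cls(np.zeros(n), np.zeros(n))

    def advance(self, t: float, tau_plus: float, tau_minus: float) -> None:
        if t < self.t:
            raise ValueError("traces cannot run backwards")
        self.trace_plus *= np.exp(-(t - self.t) / tau_plus)
        self.trace_minus *= np.exp(-(t - self.t) / tau_minus)
        self.t = t

    def on_spike_pre(self, i: int) -> None:
        self.trace_plus[i] += 1.0

    def on_spike_post(self, i: int) -> None:
        self.trace_minus[i] += 1.0


def stdp_on_spike(traces: TraceState, synapses: SynapseTable, kernels: dict,
                  neuron: int, role: str) -> np.ndarray:
    """Weight deltas caused by one spike of ``neuron`` in the given role.

    role='post': every in-edge is potentiated by ``A_plus * trace_plus[pre]``;
    role='pre': every out-edge is depressed by ``A_minus * trace_minus[post]``.
    Returns an array of per-edge deltas aligned with ``synapses.weight``
    (deltas are *not* applied; callers clip to [0, w_max] when applying).
    """
    for k in ("E", "I"):
        if k not in kernels:
            raise KeyError(f"missing kernel for class {k!r}")
    NE = synapses.N_exc
    delta = np.zeros(synapses.n_edges)
    if role == "post":
        lo, hi = synapses.in_indptr[neuron], synapses.in_indptr[neuron + 1]
        for e in synapses.in_edges[lo:hi]:
            pre = synapses.pre[e]
            ker = kernels["E" if pre < NE else "I"]
            delta[e] = ker.A_plus * traces.trace_plus[pre]
    elif role == "pre":
        ker = kernels["E" if neuron < NE else "I"]
        lo, hi = synapses.out_indptr[neuron], synapses.out_indptr[neuron + 1]
        for e in synapses.out_edges[lo:hi]:
            delta[e] = -ker.A_minus * traces.trace_minus[synapses.post[e]]
    else:
        raise ValueError("role must be 'pre' or 'post'")
    return delta


def replay_stdp(times: np.ndarray, ids: np.ndarray, synapses: SynapseTable,
                kernels: dict, w_max: float = np.inf,
                clip: bool = True) -> np.ndarray:
    """Total per-edge STDP weight change from replaying a spike record.

    Events are processed in time order through the trace algorithm; spikes
    with identical times pair on the potentiation branch.  Returns the final
    weights (starting from ``synapses.weight``, clipped to [0, w_max];
    ``clip=False`` disables the bounds for oracle comparisons).
    """
    w_lo = 0.0 if clip else -np.inf
    order = np.argsort(times, kind="stable")
    times, ids = np.asarray(times)[order], np.asarray(ids)[order]
    tr = TraceState.zeros(synapses.N)
    tp = kernels["E"].tau_plus
    tm = kernels["E"].tau_minus
    w = synapses.weight.copy()
    i = 0
    n = times.size
    while i < n:
        j = i
        while j < n and times[j] == times[i]:
            j += 1
        tr.advance(times[i], tp, tm)
        batch = ids[i:j]
        for nid in batch:
            tr.on_spike_pre(nid)
        for nid in batch:
            d = stdp_on_spike(tr, synapses, kernels, nid, "post")
            np.clip(w + d, w_lo, w_max, out=w)
        for nid in batch:
            d = stdp_on_spike(tr, synapses, kernels, nid, "pre")
            np.clip(w + d, w_lo, w_max, out=w)
        for nid in batch:
            tr.on_spike_post(nid)
        i = j
    return w


def stp_on_pre_spike(u: float, q: float) -> float:
    """Resource depletion at a presynaptic spike: u -> u(1-q)."""
    return u * (1.0 - q)


def stp_decay(u, dt: float, tau_STP: float):
    """Exact relaxation of the resource variable toward 1 over dt ms."""
    if dt < 0:
        raise ValueError("dt must be >= 0")
    return 1.0 + (u - 1.0) * np.exp(-dt / tau_STP)


def stationary_efficacy(rho_hz: float, stp: STPParams) -> float:
    """Mean efficacy under Poisson presynaptic firing at rate rho (Hz):
    <u> = 1 / (1 + tau_STP * q * rho)."""
    return 1.0 / (1.0 + stp.tau_STP * stp.q * rho_hz * 1e-3)


def effective_weight(w, u):
    """Depressed EE synaptic weight u*w."""
    return u * w


@dataclass(frozen=True)
class CorrelationKernel:
    """Causal pre-before-post spike correlation kernel.

    Exponential with decay ``tau_gamma`` and total integral ``gamma_bar``
    (ms); zero for negative lags.  Encodes the excess probability that a
    presynaptic spike precedes a postsynaptic one by lag delta.
    """

    gamma_bar: float = 1.0
    tau_gamma: float = 5.0

    def __post_init__(self):
        if self.gamma_bar < 0 or self.tau_gamma <= 0:
            raise ValueError("gamma_bar >= 0 and tau_gamma > 0 required")

    def __call__(self, delta):
        delta = np.asarray(delta, dtype=float)
        out = np.where(delta >= 0,
                       (self.gamma_bar / self.tau_gamma)
                       * np.exp(-np.clip(delta, 0, None) / self.tau_gamma),
                       0.0)
        return out

    def k_plus_integral(self, kernel: STDPKernel) -> float:
        """Closed-form int_0^inf K_+(d) gamma(d) dd."""
        return (kernel.A_plus * self.gamma_bar * kernel.tau_plus
                / (kernel.tau_plus + self.tau_gamma))


def mean_weight_ode_rhs(rates, weights, kernels, gammas, potentials,
                        neuron=None):
    """Averaged evolution of the four class-mean weights (per ms).

    Parameters
    ----------
    rates : (rho_E, rho_I) in Hz
    weights : (w_EE, w_EI, w_IE, w_II)
    kernels : {"E": STDPKernel, "I": STDPKernel}
    gammas : {"E": CorrelationKernel, "I": CorrelationKernel}
    potentials : (<V_E>, <V_I>) in mV; reverse potentials are taken from
        ``neuron`` (defaults 0 / -80 mV).

    Each class combines a rate-product drift proportional to the signed
    kernel integral with a causal-correlation term proportional to the
    weight and the synaptic driving force.
    """
    from .params import NeuronParams
    neuron = neuron or NeuronParams()
    rE, rI = (r * 1e-3 for r in rates)  # 1/ms
    wEE, wEI, wIE, wII = weights
    VE, VI = potentials
    kE, kI = kernels["E"], kernels["I"]
    KhatE, KhatI = kE.integral, kI.integral
    KgE = gammas["E"].k_plus_integral(kE)
    KgI = gammas["I"].k_plus_integral(kI)
    VRe, VRi = neuron.V_R_exc, neuron.V_R_inh
    dwEE = rE * rE * KhatE + rE * wEE * (VRe - VE) * KgE
    dwEI = rE * rI * KhatI - rI * wEI * (VE - VRi) * KgI
    dwIE = rE * rI * KhatE + rE * wIE * (VRe - VI) * KgE
    dwII = rI * rI * KhatI - rI * wII * (VI - VRi) * KgI
    return np.array([dwEE, dwEI, dwIE, dwII])


def stationary_ratio_from_kernels(kernels, gammas) -> float:
    """Common stationary value of c_EI/c_EE and c_II/c_IE:
    (Khat_I * int K_+^E gamma^E) / (Khat_E * int K_+^I gamma^I).

    Requires the balance sign conditions Khat_E < 0 and Khat_I > 0 (the
    ratio is then negative, matching the signs of the coupling
    coefficients: c_EI < 0 < c_EE).
    """
    kE, kI = kernels["E"], kernels["I"]
    if kE.integral >= 0:
        raise StabilityError("E-type kernel integral must be negative")
    if kI.integral <= 0:
        raise StabilityError("I-type kernel integral must be positive")
    KgE = gammas["E"].k_plus_integral(kE)
    KgI = gammas["I"].k_plus_integral(kI)
    return (kI.integral * KgE) / (kE.integral * KgI)
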