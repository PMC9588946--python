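"""Parameter containers for the spiking E-I network and its plasticity rules.

All voltages are in mV, times in ms, rates in Hz.  Conductances are expressed
in units of the leak conductance (``g_leak`` is normalized to 1 by default, so
the membrane capacitance is ``C = tau_m * g_leak``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = [
    "NeuronParams",
    "WeightDist",
    "NetworkConfig",
    "DriveParams",
    "RingConfig",
    "STDPKernel",
    "STPParams",
    "ConfigError",
    "DEFAULT_G0",
]

# Conductance increment per unit synaptic weight, chosen so that 14
# synchronous excitatory spikes of weight 0.54 depolarize a resting neuron
# exactly to threshold (the 10-20 synchronous-spike convention that fixes the
# weight unit shared by all parameter tables).  Recomputable with
# ``network.calibrate_conductance_scale``.
DEFAULT_G0 = 0.22771478843441


class ConfigError(ValueError):
    """Raised when a configuration violates a structural invariant."""


@dataclass(frozen=True)
class NeuronParams:
    """Conductance-based leaky integrate-and-fire neuron parameters.

    The membrane obeys ``C dv/dt = g_leak (v_leak - v) + g_exc (V_R_exc - v)
    + g_inh (V_R_inh - v)``; each presynaptic spike of weight ``w`` increments
    the matching conductance by ``w * g0`` which then decays exponentially
    with ``tau_syn``.  A spike is emitted at ``v >= v_th`` with an immediate
    reset to ``v_rest`` and no refractory period.
    """

    v_th: float = -50.0
    v_rest: float = -65.0
    v_leak: float = -65.0
    V_R_exc: float = 0.0
    V_R_inh: float = -80.0
    g_leak: float = 1.0
    tau_m: float = 20.0
    tau_syn_exc: float = 5.0
    tau_syn_inh: float = 5.0
    g0_exc: float = DEFAULT_G0
    g0_inh: float = DEFAULT_G0

    @property
    def C(self) -> float:
        """Membrane capacitance, fixed by tau_m = C / g_leak."""
        return self.tau_m * self.g_leak

    def __post_init__(self) -> None:
        if not self.v_leak < self.v_th:
            raise ConfigError("require v_leak < v_th")
        if not (self.V_R_inh <= self.v_leak < self.v_th <= self.V_R_exc):
            raise ConfigError("require V_R_inh <= v_leak < v_th <= V_R_exc")
        for name in ("g_leak", "tau_m", "tau_syn_exc", "tau_syn_inh",
                     "g0_exc", "g0_inh"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be strictly positive")


@dataclass(frozen=True)
class WeightDist:
    """Log-normal synaptic weight law (natural-scale mean and CV)."""

    mean: float
    cv: float = 0.2

    def __post_init__(self) -> None:
        if self.mean <= 0 or self.cv < 0:
            raise ConfigError("weight mean must be > 0 and cv >= 0")

    @property
    def sigma_log(self) -> float:
        return float(np.sqrt(np.log1p(self.cv ** 2)))

    @property
    def mu_log(self) -> float:
        return float(np.log(self.mean) - 0.5 * self.sigma_log ** 2)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.cv == 0.0:
            return np.full(n, self.mean)
        return rng.lognormal(self.mu_log, self.sigma_log, size=n)


def _default_weights() -> dict:
    return {
        "EE": WeightDist(0.54),
        "EI": WeightDist(1.5),
        "IE": WeightDist(0.75),
        "II": WeightDist(2.0),
    }


@dataclass(frozen=True)
class NetworkConfig:
    """Static wiring of the sparse random E-I network.

    ``k_xy`` is the in-degree of every neuron of population ``x`` from
    population ``y`` (x, y in {E, I}).  Weights per synapse class are drawn
    log-normal and clipped to ``(0, w_max]``.
    """

    N_exc: int = 2000
    N_inh: int = 500
    k_EE: int = 20
    k_EI: int = 5
    k_IE: int = 20
    k_II: int = 5
    weights: dict = field(default_factory=_default_weights)
    w_max_E: float = 0.54 * 4
    w_max_I: float = 2.0 * 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.N_exc < 0 or self.N_inh < 0:
            raise ConfigError("population sizes must be non-negative")
        if self.k_EE > self.N_exc or self.k_IE > self.N_exc:
            raise ConfigError("excitatory in-degree exceeds N_exc")
        if self.k_EI > self.N_inh or self.k_II > self.N_inh:
            raise ConfigError("inhibitory in-degree exceeds N_inh")
        for k in ("k_EE", "k_EI", "k_IE", "k_II"):
            if getattr(self, k) < 0:
                raise ConfigError(f"{k} must be non-negative")
        for cls in ("EE", "EI", "IE", "II"):
            if cls not in self.weights:
                raise ConfigError(f"missing weight law for class {cls}")

    @property
    def N(self) -> int:
        return self.N_exc + self.N_inh

    def w_max(self, cls: str) -> float:
        return self.w_max_E if cls in ("EE", "IE") else self.w_max_I

    def with_weights(self, **means: float) -> "NetworkConfig":
        """Return a copy with the mean of selected weight classes replaced."""
        new = dict(self.weights)
        for cls, m in means.items():
            if cls not in new:
                raise ConfigError(f"unknown synapse class {cls}")
            new[cls] = replace(new[cls], mean=m)
        return replace(self, weights=new)


@dataclass(frozen=True)
class DriveParams:
    """Independent homogeneous Poisson external drive per neuron (Hz)."""

    rho_ext_E: float = 230.0
    rho_ext_I: float = 150.0
    w_ext: float = 0.54

    def __post_init__(self) -> None:
        if self.rho_ext_E < 0 or self.rho_ext_I < 0:
            raise ConfigError("drive rates must be non-negative")
        if self.w_ext < 0:
            raise ConfigError("w_ext must be non-negative")


@dataclass(frozen=True)
class RingConfig:
    """Ring of weakly coupled E-I populations.

    Cross-population excitatory weights are scaled by
    ``coupling * exp(-ring_distance / decay)`` relative to the
    intra-population mean EE weight.
    """

    n_populations: int = 20
    population: NetworkConfig = field(default_factory=NetworkConfig)
    coupling: float = 0.1
    decay: float = 2.0
    k_cross: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_populations < 1:
            raise ConfigError("n_populations must be >= 1")
        if self.coupling < 0:
            raise ConfigError("coupling amplitude must be >= 0")
        if self.decay <= 0:
            raise ConfigError("decay constant must be > 0")


@dataclass(frozen=True)
class STDPKernel:
    """Exponential pair-based STDP kernel.

    ``K(dt) = A_plus * exp(-dt/tau_plus)`` for post-after-pre (``dt >= 0``)
    potentiation and ``-A_minus * exp(dt/tau_minus)`` for the reverse order.
    The kernel integral ``A_plus*tau_plus - A_minus*tau_minus`` must be
    negative for the E-type kernel (EE and IE synapses, excitatory
    presynaptic) and positive for the I-type kernel (EI and II synapses).
    """

    A_plus: float
    A_minus: float
    tau_plus: float = 20.0
    tau_minus: float = 20.0
    kind: str = "E"  # "E" (pre excitatory) or "I" (pre inhibitory)

    def __post_init__(self) -> None:
        if min(self.A_plus, self.A_minus, self.tau_plus, self.tau_minus) <= 0:
            raise ConfigError("kernel amplitudes/time constants must be > 0")
        if self.kind not in ("E", "I"):
            raise ConfigError("kernel kind must be 'E' or 'I'")
        integ = self.integral
        if self.kind == "E" and integ >= 0:
            raise ConfigError("E-type kernel integral must be negative")
        if self.kind == "I" and integ <= 0:
            raise ConfigError("I-type kernel integral must be positive")

    @property
    def integral(self) -> float:
        """Signed kernel integral A+tau+ - A-tau-."""
        return self.A_plus * self.tau_plus - self.A_minus * self.tau_minus


def default_kernels(scale: float = 1.0) -> dict:
    """Default E-type / I-type kernel pair.

    Only the signs of the kernel integrals are constrained by the theory;
    the magnitudes set the plasticity speed and can be scaled jointly
    (``scale`` > 1 accelerates convergence at small network scale).
    """
    a = 1e-3 * scale
    return {
        "E": STDPKernel(A_plus=a, A_minus=1.05 * a, kind="E"),
        "I": STDPKernel(A_plus=a, A_minus=0.95 * a, kind="I"),
    }


@dataclass(frozen=True)
class STPParams:
    """Tsodyks-Markram short-term depression of E->E synapses.

    Each presynaptic spike multiplies the available resource fraction ``u``
    by ``(1 - q)``; ``u`` recovers toward 1 with time constant ``tau_STP``.
    """

    q: float = 0.3
    tau_STP: float = 50.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.q < 1.0:
            raise ConfigError("q must be in [0, 1)")
        if self.tau_STP <= 0:
            raise ConfigError("tau_STP must be > 0")
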