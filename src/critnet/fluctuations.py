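"""Finite-size fluctuations: two-state Markov population model and the
system-size-expansion (linear-noise) stationary variances.

Each of the ``N_E`` excitatory and ``N_I`` inhibitory units is either active
or inactive.  Active units deactivate at rate ``alpha`` (per ms); inactive
units activate at a rate set by the population state, so the total
activation flux of population X is ``N_X * f_X(eps, iota)`` with
``eps = n_E/N_E`` and ``iota = n_I/N_I`` the intensive active fractions.
The deterministic (N -> infinity) limit is then exactly the rate ODE
``d eps/dt = f_E(eps, iota) - alpha*eps``.

Around a stable fixed point the linear-noise approximation gives Gaussian
stationary fluctuations whose (intensive) covariance solves the Lyapunov
system; closed-form solution below.  ``Var(n_E/N_E) = Var(eps)/N_E``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence, Tuple, Union

import numpy as np
from numba import njit

__all__ = ["MarkovConfig", "LNAResult", "gillespie", "lna_variances",
           "variance_vs_criticality", "NearCriticalityError"]


class NearCriticalityError(ArithmeticError):
    """Lyapunov system is singular: fixed point at/beyond stability loss."""


AffineRates = Tuple[float, float, float]  # f = a + b*eps + c*iota


@dataclass
class MarkovConfig:
    """Two-population active/inactive Markov model.

    ``f_E``/``f_I`` map the intensive state (eps, iota) to per-unit
    activation rates (1/ms): either callables or affine coefficient triples
    ``(a, b, c)`` meaning ``a + b*eps + c*iota`` (the affine form runs in
    the compiled kernel).  ``alpha`` is the deactivation rate (1/ms).
    """

    N_E: int
    N_I: int
    alpha: float
    f_E: Union[Callable, AffineRates]
    f_I: Union[Callable, AffineRates]

    def __post_init__(self):
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if self.N_E < 1 or self.N_I < 0:
            raise ValueError("population sizes invalid")

    @property
    def affine(self) -> bool:
        return not callable(self.f_E)


@njit(cache=True)
def _gillespie_affine(NE, NI, alpha, aE, bE, cE, aI, bI, cI,
                      n0E, n0I, T, sample_dt, seed, out_E, out_I):
    np.random.seed(seed)
    t = 0.0
    nE = n0E
    nI = n0I
    k = 0
    nsamp = out_E.size
    while k < nsamp:
        eps = nE / NE
        iota = nI / NI if NI > 0 else 0.0
        rE = NE * max(aE + bE * eps + cE * iota, 0.0)
        rI = NI * max(aI + bI * eps + cI * iota, 0.0)
        dE = alpha * nE
        dI = alpha * nI
        tot = rE + rI + dE + dI
        if tot <= 0.0:
            # absorbing: fill remaining samples and stop
            while k < nsamp:
                out_E[k] = nE
                out_I[k] = nI
                k += 1
            return
        dt = -np.log(np.random.random()) / tot
        tn = t + dt
        while k < nsamp and (k + 1) * sample_dt <= tn:
            out_E[k] = nE
            out_I[k] = nI
            k += 1
        t = tn
        x = np.random.random() * tot
        if x < rE:
            nE += 1
        elif x < rE + rI:
            nI += 1
        elif x < rE + rI + dE:
            nE -= 1
        else:
            nI -= 1


def gillespie(config: MarkovConfig, T: float, seed: int = 0,
              sample_dt: float = 1.0, init: Optional[Tuple[int, int]] = None):
    """Statistically exact trajectory of (active E, active I) counts.

    Returns a dict with sample times (ms) and the two count arrays, sampled
    on a regular grid (value = state just before each grid time).
    Reproducible per seed."""
    nsamp = int(T / sample_dt)
    out_E = np.empty(nsamp, dtype=np.int64)
    out_I = np.empty(nsamp, dtype=np.int64)
    n0E, n0I = init if init is not None else (0, 0)
    if config.affine:
        aE, bE, cE = config.f_E
        aI, bI, cI = config.f_I
        _gillespie_affine(config.N_E, config.N_I, config.alpha,
                          aE, bE, cE, aI, bI, cI, n0E, n0I,
                          float(T), float(sample_dt), seed % (2**31 - 1),
                          out_E, out_I)
    else:
        rng = np.random.default_rng(seed)
        t, nE, nI, k = 0.0, n0E, n0I, 0
        while k < nsamp:
            eps = nE / config.N_E
            iota = nI / config.N_I if config.N_I else 0.0
            rE = config.N_E * max(config.f_E(eps, iota), 0.0)
            rI = config.N_I * max(config.f_I(eps, iota), 0.0)
            dE, dI = config.alpha * nE, config.alpha * nI
            tot = rE + rI + dE + dI
            if tot <= 0:
                out_E[k:] = nE
                out_I[k:] = nI
                break
            tn = t + rng.exponential(1.0 / tot)
            while k < nsamp and (k + 1) * sample_dt <= tn:
                out_E[k], out_I[k] = nE, nI
                k += 1
            t = tn
            x = rng.random() * tot
            if x < rE:
                nE += 1
            elif x < rE + rI:
                nI += 1
            elif x < rE + rI + dE:
                nE -= 1
            else:
                nI -= 1
    return {"t_ms": (np.arange(1, nsamp + 1)) * sample_dt,
            "n_E": out_E, "n_I": out_I}


@dataclass
class LNAResult:
    """Stationary linear-noise covariances (intensive variables)."""

    var_eps: float
    var_iota: float
    cov: float
    A: np.ndarray
    c_lna: float

    def var_extensive(self, N_E: int, N_I: int):
        """Variances of the active fractions n/N at system sizes N."""
        return self.var_eps / N_E, self.var_iota / N_I


def lna_variances(jacobian, alpha: float, rates) -> LNAResult:
    """Closed-form stationary covariance of the linear-noise approximation.

    ``jacobian`` is the 2x2 Jacobian A of the intensive deterministic flow
    at a stable fixed point with stationary levels ``rates = (rho_E,
    rho_I)`` (same intensive units as eps, iota).  Solves the Lyapunov
    system

        A Sigma + Sigma A^T + 2 alpha diag(rho_E, rho_I) = 0

    whose row-reduced form is the 3x3 system with right-hand side
    ``-alpha (rho_E, rho_I, 0)``.  Closed form:

        Var(eps) = c ((det A + A22^2) rho_E + A12^2 rho_I)
        Var(iota) = c ((det A + A11^2) rho_I + A21^2 rho_E)
        Cov      = -c (A11 A12 rho_I + A21 A22 rho_E)

    with ``c = -alpha / ((A11+A22)(A11 A22 - A12 A21))``.  The noise matrix
    uses that the stationary birth and death fluxes are both
    ``alpha * rho``, making the decoupled limit exactly Poisson
    (Var(eps) = rho_E for A12 = A21 = 0, A11 = -alpha).
    """
    A = np.asarray(jacobian, dtype=float)
    rE, rI = rates
    tr = A[0, 0] + A[1, 1]
    det = A[0, 0] * A[1, 1] - A[0, 1] * A[1, 0]
    if tr >= -1e-12 or det <= 1e-12:
        raise NearCriticalityError(
            f"fixed point not strictly stable (trace={tr:.3g}, det={det:.3g})")
    c = -alpha / (tr * det)
    var_eps = c * ((det + A[1, 1] ** 2) * rE + A[0, 1] ** 2 * rI)
    var_iota = c * ((det + A[0, 0] ** 2) * rI + A[1, 0] ** 2 * rE)
    cov = -c * (A[0, 0] * A[0, 1] * rI + A[1, 0] * A[1, 1] * rE)
    return LNAResult(float(var_eps), float(var_iota), float(cov), A, float(c))


def variance_vs_criticality(jacobians: Sequence, alpha: float,
                            rates) -> np.ndarray:
    """Var(eps) along a parameter path approaching the bifurcation.

    Stops (with the values so far) at the first point that is no longer
    strictly stable.  The variance grows like 1/|trace| near the Hopf line
    and 1/det near the saddle-node line."""
    out = []
    for A in jacobians:
        try:
            out.append(lna_variances(A, alpha, rates).var_eps)
        except NearCriticalityError:
            break
    return np.array(out)
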