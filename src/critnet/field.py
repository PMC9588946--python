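"""Continuum layer: reaction-diffusion linear stability, the
directed-percolation (DP) Langevin equation for the excitatory rate field,
and the depression-coupled field model.

The excitatory field obeys

    dE/dt = gamma E + D lap(E) - u E^2 + psi,
    <psi psi'> = (2 sigma^2 / N_local) E delta(x-x') delta(t-t'),

with ``u > 0`` the saturating quadratic feedback (the DP convention: net
negative quadratic drift).  Rescaling ``E = lam S`` with
``lam = sigma / sqrt(u N_local)`` turns the noise variance into
``2 u' S`` with ``u' = u lam``, the standard Langevin form of directed
percolation; ``gamma = 0`` maps to the DP critical point ``gamma' = 0``.

The depression-coupled variant replaces ``gamma`` by ``(-alpha + Omega)``
where the synaptic-efficacy field Omega relaxes to ``Omega0`` with time
constant ``tau_STP`` and is consumed at rate ``q Omega E``; its homogeneous
stationary state self-organizes ``-alpha + Omega_st`` toward zero.

Integration on a periodic lattice (1D ring by default) uses operator
splitting: the linear drift plus square-root multiplicative noise are
propagated EXACTLY through their known transition density (a
Poisson-mixture of Gamma distributions), which preserves the absorbing
state and avoids the systematic upward bias of clip-at-zero truncation
near extinction; the diffusion, saturation and drive terms follow by an
Euler step (rare negative excursions of that deterministic part are
truncated and counted).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dfield
from typing import Optional

import numpy as np
from numba import njit

__all__ = [
    "FieldConfig", "DPParams", "STPFieldParams", "FieldState",
    "dispersion_relation", "dp_step", "dp_run", "rescale_to_dp",
    "stp_field_step", "stp_field_run", "stationary_intersection",
    "dp_avalanche_sizes", "FieldStabilityError",
]


class FieldStabilityError(RuntimeError):
    """Field magnitude exploded; reduce dt or check coefficients."""


@dataclass(frozen=True)
class FieldConfig:
    """Lattice and coefficients of the excitatory Langevin field."""

    n_sites: int = 256
    dx: float = 1.0
    dt: float = 0.2           # ms; must satisfy dt <= dx^2/(4D)
    D: float = 0.5
    gamma: float = 0.0        # linear coefficient (1/ms)
    u_quad: float = 0.01      # quadratic saturation (> 0)
    sigma2: float = 1.0       # noise scale
    N_local: int = 1000       # local population size entering noise variance
    drive: float = 0.0        # homogeneous additive drive
    ndim: int = 1

    def __post_init__(self):
        if self.u_quad <= 0:
            raise ValueError("u_quad must be > 0")
        if self.N_local < 1:
            raise ValueError("N_local must be >= 1")
        if self.D > 0 and self.dt > self.dx ** 2 / (4.0 * self.D):
            raise ValueError("dt too large for diffusive stability "
                             "(need dt <= dx^2/(4D))")
        if self.ndim not in (1, 2):
            raise ValueError("only 1D ring and 2D periodic lattices")


@dataclass(frozen=True)
class DPParams:
    """Coefficients of the rescaled directed-percolation field."""

    gamma_prime: float
    D_prime: float
    u_prime: float
    scale: float  # E = scale * S

    def __post_init__(self):
        if self.u_prime <= 0:
            raise ValueError("u_prime must be > 0")


@dataclass(frozen=True)
class STPFieldParams:
    """Efficacy-field coupling of the depression-stabilized model."""

    Omega0: float = 0.06
    alpha_decay: float = 0.05
    q: float = 0.3
    tau_STP: float = 50.0
    tau_m: float = 20.0

    def __post_init__(self):
        if min(self.Omega0, self.alpha_decay, self.q, self.tau_STP,
               self.tau_m) <= 0:
            raise ValueError("all STP-field parameters must be positive")


@dataclass
class FieldState:
    E: np.ndarray
    Omega: Optional[np.ndarray] = None
    t: float = 0.0
    truncations: int = 0


def _exact_linear_noise(E, gamma, s, dt, rng):
    """Exact update of dE = gamma*E dt + sqrt(2 s E) dW per site.

    Transition density: E' = Gamma(Poisson(lam * E * exp(gamma dt))) / lam
    with lam = gamma / (s (exp(gamma dt) - 1)) (limit 1/(s dt) at gamma=0).
    Zero stays exactly zero."""
    gd = gamma * dt
    if s == 0.0:  # deterministic linear part
        return E * np.exp(gd)
    lam = np.where(np.abs(gd) < 1e-12, 1.0 / (s * dt),
                   gamma / (s * np.expm1(np.where(np.abs(gd) < 1e-12, 1.0,
                                                  gd))))
    mu = lam * E * np.exp(gd)
    k = rng.poisson(np.maximum(mu, 0.0))
    out = np.zeros_like(E, dtype=float)
    nz = k > 0
    if np.any(nz):
        lam_nz = np.broadcast_to(lam, E.shape)[nz]
        out[nz] = rng.gamma(k[nz]) / lam_nz
    return out


def _laplacian(E, dx, ndim):
    if ndim == 1:
        return (np.roll(E, 1) + np.roll(E, -1) - 2 * E) / dx ** 2
    return (np.roll(E, 1, 0) + np.roll(E, -1, 0)
            + np.roll(E, 1, 1) + np.roll(E, -1, 1) - 4 * E) / dx ** 2


def dispersion_relation(jacobian, D, k_grid):
    """Eigenvalues of (L - k^2 D) over a wavenumber grid.

    Returns (lambda(k) array of shape (len(k), 2) sorted by real part
    descending, hopf_at_k0 flag, turing flag).  Hopf at k=0 requires
    trace(L) ~ 0 with det(L) > 0; a Turing instability is any k > 0 whose
    leading real part exceeds both 0 and the k=0 value."""
    L = np.asarray(jacobian, dtype=float)
    D = np.asarray(D, dtype=float)
    if D.ndim == 0:
        D = D * np.eye(2)
    lams = np.empty((len(k_grid), 2), dtype=complex)
    for i, k in enumerate(k_grid):
        ev = np.linalg.eigvals(L - (k ** 2) * D)
        lams[i] = ev[np.argsort(-ev.real)]
    tr = np.trace(L)
    det = np.linalg.det(L)
    hopf_k0 = bool(abs(tr) < 1e-8 and det > 0)
    re0 = lams[np.argmin(np.abs(np.asarray(k_grid)))].real.max() \
        if len(k_grid) else -np.inf
    turing = bool(np.any((lams.real.max(axis=1) > max(re0, 0.0) + 1e-12)
                         & (np.asarray(k_grid) > 0)))
    return lams, hopf_k0, turing


def dp_step(state: FieldState, config: FieldConfig,
            rng: np.random.Generator) -> FieldState:
    """One Euler-Maruyama step of the DP Langevin field (in place).

    Noise amplitude per site: sqrt(2 sigma^2 E dt / (N_local dx^ndim)),
    computed from the pre-step non-negative field; negative excursions are
    truncated at zero and counted.  The zero field with zero drive is
    exactly invariant (absorbing state)."""
    E = state.E
    c = config
    s = c.sigma2 / (c.N_local * c.dx ** c.ndim)
    En = _exact_linear_noise(E, np.float64(c.gamma), s, c.dt, rng)
    drift = -c.u_quad * En * En + c.drive
    if c.D > 0:
        drift = drift + c.D * _laplacian(En, c.dx, c.ndim)
    En = En + c.dt * drift
    neg = En < 0.0
    state.truncations += int(np.count_nonzero(neg))
    En[neg] = 0.0
    if not np.all(np.isfinite(En)) or En.max(initial=0.0) > 1e12:
        raise FieldStabilityError("field diverged; reduce dt")
    state.E = En
    state.t += c.dt
    return state


def dp_run(config: FieldConfig, n_steps: int, seed: int = 0,
           init: Optional[np.ndarray] = None, record_every: int = 10):
    """Run the DP field; returns (state, times, spatial-mean trajectory)."""
    rng = np.random.default_rng(seed)
    shape = ((config.n_sites,) if config.ndim == 1
             else (config.n_sites, config.n_sites))
    E0 = np.zeros(shape) if init is None else np.array(init, dtype=float)
    state = FieldState(E0)
    ts, means = [], []
    for i in range(n_steps):
        dp_step(state, config, rng)
        if (i + 1) % record_every == 0:
            ts.append(state.t)
            means.append(float(state.E.mean()))
    return state, np.array(ts), np.array(means)


def rescale_to_dp(config: FieldConfig) -> DPParams:
    """Map the excitatory field to standard DP variables.

    With ``E = lam S`` and ``lam = sigma/sqrt(u_quad N_local)`` the noise
    correlator becomes ``2 u' S`` with ``u' = u_quad * lam``; gamma and D
    are unchanged, so criticality (gamma = 0) is preserved."""
    lam = math.sqrt(config.sigma2 / (config.u_quad * config.N_local))
    return DPParams(gamma_prime=config.gamma, D_prime=config.D,
                    u_prime=config.u_quad * lam, scale=lam)


def dp_config_from_params(p: DPParams, base: FieldConfig) -> FieldConfig:
    """FieldConfig whose dynamics are the rescaled S-field of ``p``."""
    # noise 2 u' S corresponds to sigma2/N_local = u'
    return FieldConfig(n_sites=base.n_sites, dx=base.dx, dt=base.dt,
                       D=p.D_prime, gamma=p.gamma_prime, u_quad=p.u_prime,
                       sigma2=p.u_prime, N_local=1, drive=0.0,
                       ndim=base.ndim)


def stp_field_step(state: FieldState, config: FieldConfig,
                   stp: STPFieldParams,
                   rng: np.random.Generator) -> FieldState:
    """Joint update of rate field E and efficacy field Omega (in place).

    tau_m dE/dt = (-alpha + Omega) E + D lap(E) - u E^2 + psi
    dOmega/dt   = (Omega0 - Omega)/tau_STP - q Omega E
    """
    E, Om = state.E, state.Omega
    if Om is None:
        Om = np.full_like(E, stp.Omega0)
    c = config
    # per-site linear coefficient and noise scale of the tau_m-normalized
    # equation dE = [(-alpha+Omega)E + D lap - u E^2]/tau_m + psi/tau_m
    gam = (-stp.alpha_decay + Om) / stp.tau_m
    s = c.sigma2 / (c.N_local * c.dx ** c.ndim * stp.tau_m ** 2)
    En = _exact_linear_noise(E, gam, s, c.dt, rng)
    drift = -c.u_quad * En * En + c.drive
    if c.D > 0:
        drift = drift + c.D * _laplacian(En, c.dx, c.ndim)
    En = En + (c.dt / stp.tau_m) * drift
    dOm = (stp.Omega0 - Om) / stp.tau_STP - stp.q * Om * E
    Omn = Om + c.dt * dOm
    neg = En < 0.0
    state.truncations += int(np.count_nonzero(neg))
    En[neg] = 0.0
    np.clip(Omn, 1e-12, stp.Omega0, out=Omn)
    if not np.all(np.isfinite(En)) or En.max(initial=0.0) > 1e12:
        raise FieldStabilityError("field diverged; reduce dt")
    state.E, state.Omega = En, Omn
    state.t += c.dt
    return state


def stp_field_run(config: FieldConfig, stp: STPFieldParams, n_steps: int,
                  seed: int = 0, init_E: Optional[np.ndarray] = None,
                  record_every: int = 10):
    """Run the depression-coupled field; returns (state, t, mean E, mean Omega)."""
    rng = np.random.default_rng(seed)
    shape = ((config.n_sites,) if config.ndim == 1
             else (config.n_sites, config.n_sites))
    E0 = np.zeros(shape) if init_E is None else np.array(init_E, dtype=float)
    state = FieldState(E0, np.full(shape, stp.Omega0))
    ts, mE, mO = [], [], []
    for i in range(n_steps):
        stp_field_step(state, config, stp, rng)
        if (i + 1) % record_every == 0:
            ts.append(state.t)
            mE.append(float(state.E.mean()))
            mO.append(float(state.Omega.mean()))
    return state, np.array(ts), np.array(mE), np.array(mO)


def stationary_intersection(stp: STPFieldParams, u_quad: float):
    """Homogeneous stationary (E_st, Omega_st) of the coupled field.

    Solves Omega = Omega0/(1 + q tau_STP E) simultaneously with the
    active-phase balance E = (Omega - alpha)/u_quad.  Returns the absorbing
    solution (0, Omega0) when Omega0 <= alpha.  With Omega0 close to alpha
    the intersection satisfies -alpha + Omega_st ~ 0: self-organized
    proximity to the critical line."""
    if stp.Omega0 <= stp.alpha_decay:
        return 0.0, stp.Omega0

    def res(E):
        Om = stp.Omega0 / (1.0 + stp.q * stp.tau_STP * E)
        return u_quad * E - (Om - stp.alpha_decay)

    from scipy.optimize import brentq
    E_hi = (stp.Omega0 - stp.alpha_decay) / u_quad
    E_st = brentq(res, 0.0, E_hi + 1e-12, xtol=1e-14)
    Om_st = stp.Omega0 / (1.0 + stp.q * stp.tau_STP * E_st)
    return float(E_st), float(Om_st)


@njit(cache=True)
def _dp_avalanche_kernel(n_sites, dt, dx, D, gamma, u, s, seed_amp,
                         eps_field, max_steps, n_trials, seed, sizes):
    np.random.seed(seed)
    if abs(gamma * dt) < 1e-12:
        lam = 1.0 / (s * dt)
    else:
        lam = gamma / (s * (math.exp(gamma * dt) - 1.0))
    egd = math.exp(gamma * dt)
    for trial in range(n_trials):
        E = np.zeros(n_sites)
        E[n_sites // 2] = seed_amp
        size = 0.0
        for _ in range(max_steps):
            tot = 0.0
            for i in range(n_sites):
                tot += E[i]
            if tot * dx < eps_field:
                break
            size += tot * dx * dt
            # exact linear+noise propagation per site
            Emid = np.empty(n_sites)
            for i in range(n_sites):
                if E[i] <= 0.0:
                    Emid[i] = 0.0
                else:
                    k = np.random.poisson(lam * E[i] * egd)
                    Emid[i] = np.random.gamma(k, 1.0) / lam if k > 0 else 0.0
            # Euler on diffusion + saturation
            Enew = np.empty(n_sites)
            for i in range(n_sites):
                lap = (Emid[(i + 1) % n_sites] + Emid[(i - 1) % n_sites]
                       - 2.0 * Emid[i]) / (dx * dx)
                x = Emid[i] + dt * (D * lap - u * Emid[i] * Emid[i])
                Enew[i] = x if x > 0.0 else 0.0
            E = Enew
        sizes[trial] = size


def dp_avalanche_sizes(config: FieldConfig, n_trials: int, seed: int = 0,
                       seed_amp: float = 1.0, eps_field: float = 1e-6,
                       max_steps: int = 200_000) -> np.ndarray:
    """Avalanche sizes of the seeded DP field at (or near) criticality.

    Each trial seeds a point perturbation on the empty lattice and
    integrates until the lattice-summed activity returns below
    ``eps_field``; the size is the space-time integral of activity.  At
    ``gamma = 0`` the size distribution follows the mean-field DP power law
    with exponent 3/2."""
    sizes = np.empty(n_trials)
    s = config.sigma2 / (config.N_local * config.dx ** config.ndim)
    _dp_avalanche_kernel(config.n_sites, config.dt, config.dx, config.D,
                         config.gamma, config.u_quad, s, seed_amp,
                         eps_field, max_steps, n_trials, seed % (2**31 - 1),
                         sizes)
    return sizes
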