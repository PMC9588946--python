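"""Two-population rate model of the E-I network.

The stationary rates solve ``rho_x = phi(z_x) - z0`` where the net input is
``z_E = c_EE rho_E + c_EI rho_I + d rho_Ext^E`` (likewise for I) with
coupling coefficients ``c_xy = c_scale * k_xy * w_xy * (V_R_y - <V_x>)``.
The mean potential ``<V_x>`` is the conductance-weighted average of the leak
and reverse potentials at the given rates, so the coefficients inherit a
self-consistent rate dependence.

The gain ``phi`` is a smooth threshold-linear function with soft saturation:
zero below threshold, slope-``s`` linear mid-section, saturating at
``rho_max``.  Its three calibration constants (threshold, width, slope) and
the overall coupling scale are free parameters of the reduction, fixed once
against reference spiking simulations and then held.

A Bogdanov-Takens (double-zero eigenvalue) point is located where the
linearized nullcline slopes and intercepts match:
``c_EE c_II = c_EI c_IE`` and ``rho_Ext^E = (c_EE/c_IE)(rho_Ext^I - d) + d``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy import optimize

from .params import DriveParams, NeuronParams, STPParams

__all__ = [
    "GainParams", "MeanFieldParams", "FixedPoint", "BTResiduals",
    "average_potential", "coupling_coefficients", "find_fixed_points",
    "nullclines", "bt_residuals", "rate_ode_rhs", "slow_fast_rhs",
    "up_down_conditions", "scan_bifurcation", "locate_bt",
]


@dataclass(frozen=True)
class GainParams:
    """Smooth threshold-linear gain with soft saturation.

    ``phi(z) = rho_max * (1 - exp(-slope * softplus_beta(z - z_th)/rho_max))``
    where ``softplus_beta(y) = beta*log(1+exp(y/beta))`` rounds the threshold
    over a width ``beta``.  ``z0 = phi(0)`` shifts the curve so that zero net
    input maps to exactly zero rate.
    """

    rho_max: float = 500.0
    z_th: float = 80.0
    beta: float = 6.0
    slope: float = 10.0

    def __post_init__(self):
        if min(self.rho_max, self.beta, self.slope) <= 0:
            raise ValueError("rho_max, beta, slope must be > 0")

    def phi(self, z):
        y = (np.asarray(z, dtype=float) - self.z_th) / self.beta
        sp = self.beta * np.logaddexp(0.0, y)
        return self.rho_max * (-np.expm1(-self.slope * sp / self.rho_max))

    @property
    def z0(self) -> float:
        return float(self.phi(0.0))

    def __call__(self, z):
        """Rectified gain phi(z) - z0 (non-negative, non-decreasing)."""
        return np.maximum(self.phi(z) - self.z0, 0.0)


def _default_k():
    return {"EE": 200, "EI": 50, "IE": 200, "II": 50}


def _default_w():
    return {"EE": 0.54, "EI": 1.5, "IE": 0.75, "II": 2.0}


def _default_gain_E():
    return GainParams(rho_max=500.0, z_th=80.0, beta=10.0, slope=10.0)


def _default_gain_I():
    return GainParams(rho_max=500.0, z_th=43.0, beta=6.0, slope=10.0)


@dataclass(frozen=True)
class MeanFieldParams:
    """Rate-model coefficients (defaults: full-scale reference network).

    The two populations carry separate gain functions; their threshold /
    width constants are calibration parameters of the reduction, fixed once
    so that the low-rate fixed point at the avalanche-regime reference
    parameter set (drive 230/150 Hz, depressed EE efficacy ~0.81) matches
    the reference spiking simulation's (rho_E, rho_I) ~ (13, 35) Hz, and
    held fixed thereafter."""

    k: dict = field(default_factory=_default_k)
    w: dict = field(default_factory=_default_w)
    neuron: NeuronParams = field(default_factory=NeuronParams)
    drive: DriveParams = field(default_factory=DriveParams)
    gain_E: GainParams = field(default_factory=_default_gain_E)
    gain_I: GainParams = field(default_factory=_default_gain_I)
    c_scale: Optional[float] = None  # default: tau_syn*g0/(1000*(v_th-v_rest))
    u_eff: float = 1.0               # STP efficacy multiplying w_EE

    @property
    def gain(self) -> GainParams:
        """Excitatory gain (the control-parameter plane of the scans)."""
        return self.gain_E

    def __post_init__(self):
        if self.c_scale is None:
            n = self.neuron
            object.__setattr__(
                self, "c_scale",
                n.tau_syn_exc * n.g0_exc / (1000.0 * (n.v_th - n.v_rest)))

    @property
    def d(self) -> float:
        """Drive coefficient g_L (v_rest - v_th) / (tau g0_exc (v_th - V_R_exc))."""
        n = self.neuron
        return (n.g_leak * (n.v_rest - n.v_th)
                / (n.tau_syn_exc * n.g0_exc * (n.v_th - n.V_R_exc)))

    def w_effective(self, cls: str) -> float:
        return self.w[cls] * (self.u_eff if cls == "EE" else 1.0)

    @classmethod
    def from_network(cls, config, drive, neuron=None, **kw):
        """Build from a spiking NetworkConfig (degrees + mean weights)."""
        k = {c: getattr(config, "k_" + c) for c in ("EE", "EI", "IE", "II")}
        w = {c: config.weights[c].mean for c in ("EE", "EI", "IE", "II")}
        return cls(k=k, w=w, neuron=neuron or NeuronParams(), drive=drive,
                   **kw)


def average_potential(rho_E: float, rho_I: float, params: MeanFieldParams,
                      population: str = "E") -> float:
    """Conductance-weighted mean membrane potential of one population (mV).

    Equals the steady state of the voltage equation under the time-averaged
    synaptic conductances at rates (rho_E, rho_I)."""
    n = params.neuron
    x = population
    tau = n.tau_syn_exc
    aE = (params.k[x + "E"] * params.w_effective(x + "E") * n.g0_exc
          * rho_E * 1e-3 * tau)
    aI = (params.k[x + "I"] * params.w[x + "I"] * n.g0_inh
          * rho_I * 1e-3 * n.tau_syn_inh)
    v = ((n.g_leak * n.v_leak + aE * n.V_R_exc + aI * n.V_R_inh)
         / (n.g_leak + aE + aI))
    # the spiking neuron resets at threshold, so its time-averaged potential
    # cannot exceed v_th; the conductance-average is clamped accordingly
    return min(v, n.v_th)


def coupling_coefficients(params: MeanFieldParams, rho_E: float = 0.0,
                          rho_I: float = 0.0) -> dict:
    """Linearized-nullcline coupling coefficients at the given rates.

    ``c_xy = c_scale * k_xy * w_xy * (V_R_y - <V_x>)``; excitatory columns
    are positive, inhibitory negative.  The rate dependence enters through
    the mean potentials."""
    VE = average_potential(rho_E, rho_I, params, "E")
    VI = average_potential(rho_E, rho_I, params, "I")
    n = params.neuron
    VR = {"E": n.V_R_exc, "I": n.V_R_inh}
    V = {"E": VE, "I": VI}
    return {x + y: params.c_scale * params.k[x + y]
            * params.w_effective(x + y) * (VR[y] - V[x])
            for x in "EI" for y in "EI"}


def _net_input(rho, params):
    c = coupling_coefficients(params, rho[0], rho[1])
    zE = c["EE"] * rho[0] + c["EI"] * rho[1] + params.d * params.drive.rho_ext_E
    zI = c["IE"] * rho[0] + c["II"] * rho[1] + params.d * params.drive.rho_ext_I
    return zE, zI


def rate_ode_rhs(rho, params: MeanFieldParams):
    """d(rho)/dt = -(rho - gain(z(rho))) / tau_m, rates in Hz, t in ms."""
    zE, zI = _net_input(rho, params)
    return np.array([-(rho[0] - params.gain_E(zE)),
                     -(rho[1] - params.gain_I(zI))]) / params.neuron.tau_m


def _jacobian(rho, params, eps=1e-4):
    J = np.empty((2, 2))
    f0 = rate_ode_rhs(rho, params)
    for j in range(2):
        dr = np.array(rho, dtype=float)
        h = eps * max(1.0, abs(rho[j]))
        dr[j] += h
        J[:, j] = (rate_ode_rhs(dr, params) - f0) / h
    return J


@dataclass
class FixedPoint:
    rho_E: float
    rho_I: float
    jacobian: np.ndarray
    trace: float
    det: float
    classification: str
    regime: str

    def __repr__(self):
        return (f"FixedPoint(rho_E={self.rho_E:.3f}, rho_I={self.rho_I:.3f}, "
                f"{self.classification}, regime={self.regime})")


def _classify(tr, det):
    if det < 0:
        return "saddle"
    disc = tr * tr - 4 * det
    kind = "node" if disc >= 0 else "focus"
    return ("stable " if tr < 0 else "unstable ") + kind


def _regime(rho_E, zE, gain):
    if rho_E < 1e-3 * gain.rho_max:
        return "Q"
    if zE < gain.z_th - 2 * gain.beta:
        return "L"
    if zE <= gain.z_th + 2 * gain.beta:
        return "M"
    return "H"


def find_fixed_points(params: MeanFieldParams, grid_n: int = 200,
                      tol: float = 1e-9, merge_tol: float = 1e-3) -> list:
    """All fixed points of the rate model in [0, 1.2*rho_max]^2.

    Dense-grid bracketing of the residual followed by local Newton
    refinement; duplicates within ``merge_tol`` Hz are merged.  Each root is
    returned with its Jacobian classification and gain-regime label."""
    rmax = 1.2 * max(params.gain_E.rho_max, params.gain_I.rho_max)
    # log-ish grid: dense near zero where the interesting roots live
    g1 = np.linspace(0.0, rmax, grid_n)
    g2 = np.geomspace(1e-3, rmax, grid_n // 2)
    grid = np.unique(np.concatenate([g1, g2, [0.0]]))
    sols = []
    fun = lambda r: rate_ode_rhs(r, params)
    # residual of the E-equation along the I-nullcline and vice versa is
    # expensive; use 2D seeding on a coarse product grid instead
    coarse = grid[::4]
    seeds = [(a, b) for a in coarse for b in coarse]
    seeds.append((0.0, 0.0))
    resid = np.array([np.linalg.norm(fun(np.array(s))) for s in seeds])
    order = np.argsort(resid)
    for idx in order[:120]:
        s = np.array(seeds[idx], dtype=float)
        sol = optimize.root(fun, s, method="hybr", tol=tol)
        r = sol.x
        if not sol.success or np.any(r < -1e-6) or np.any(r > rmax + 1):
            continue
        r = np.clip(r, 0.0, None)
        if np.linalg.norm(fun(r)) > 1e-6:
            continue
        if any(abs(r[0] - p.rho_E) < merge_tol
               and abs(r[1] - p.rho_I) < merge_tol for p in sols):
            continue
        J = _jacobian(r, params)
        tr, det = float(np.trace(J)), float(np.linalg.det(J))
        zE, _ = _net_input(r, params)
        sols.append(FixedPoint(float(r[0]), float(r[1]), J, tr, det,
                               _classify(tr, det),
                               _regime(r[0], zE, params.gain_E)))
    sols.sort(key=lambda p: p.rho_E)
    return sols


def nullclines(params: MeanFieldParams, rho_grid: np.ndarray):
    """Solution branches of each scalar stationary equation plus the
    linearized slope ratios (c_EI/c_EE for E, c_II/c_IE for I).

    Returns ``(curve_E, curve_I, ratios)`` where each curve is an array of
    (rho_E, rho_I) points satisfying its equation to high accuracy.  The
    E-curve is parameterized by rho_E (solving for rho_I) and vice versa."""
    rho_grid = np.asarray(rho_grid, dtype=float)
    if np.any(rho_grid < 0):
        raise ValueError("rate grid must be non-negative")
    rmax = 1.2 * max(params.gain_E.rho_max, params.gain_I.rho_max)

    def branch(which):
        pts = []
        idx = 0 if which == "E" else 1
        for r_fix in rho_grid:
            def res(r_other):
                rho = (r_fix, r_other) if which == "E" else (r_other, r_fix)
                return rate_ode_rhs(rho, params)[idx] * params.neuron.tau_m
            scan = np.linspace(0.0, rmax, 400)
            vals = np.array([res(s) for s in scan])
            sgn = np.sign(vals)
            for i in np.nonzero(sgn[:-1] * sgn[1:] < 0)[0]:
                root = optimize.brentq(res, scan[i], scan[i + 1], xtol=1e-10)
                pt = (r_fix, root) if which == "E" else (root, r_fix)
                pts.append(pt)
            if np.any(vals == 0.0):
                for s in scan[vals == 0.0]:
                    pt = (r_fix, s) if which == "E" else (s, r_fix)
                    pts.append(pt)
        return np.array(pts) if pts else np.empty((0, 2))

    c = coupling_coefficients(params, float(rho_grid.mean()),
                              float(rho_grid.mean()))
    ratios = {"E": c["EI"] / c["EE"] if c["EE"] else np.nan,
              "I": c["II"] / c["IE"] if c["IE"] else np.nan}
    return branch("E"), branch("I"), ratios


@dataclass
class BTResiduals:
    """Distance from the double-zero (BT) matching conditions."""

    slope: float       # c_EE*c_II - c_EI*c_IE
    intercept: float   # rho_Ext^E - [(c_EE/c_IE)(rho_Ext^I - d) + d]
    deltaW: float      # u*w_EE*w_II - w_EI*w_IE


def bt_residuals(params: MeanFieldParams, rho_E: float = 0.0,
                 rho_I: float = 0.0) -> BTResiduals:
    """Slope/intercept matching residuals of the linearized nullclines.

    Both residuals near zero place the system in the Bogdanov-Takens
    neighborhood.  ``deltaW`` is the weight-level balance index
    ``w_EE^eff * w_II - w_EI * w_IE``."""
    c = coupling_coefficients(params, rho_E, rho_I)
    slope = c["EE"] * c["II"] - c["EI"] * c["IE"]
    d = params.d
    if c["IE"] == 0.0:
        intercept = np.nan  # intercept condition undefined without E->I
    else:
        intercept = params.drive.rho_ext_E - (
            (c["EE"] / c["IE"]) * (params.drive.rho_ext_I - d) + d)
    dW = (params.w_effective("EE") * params.w["II"]
          - params.w["EI"] * params.w["IE"])
    return BTResiduals(float(slope), float(intercept), float(dW))


def slow_fast_rhs(rho, w_EE: float, params: MeanFieldParams,
                  stp: STPParams):
    """Fast rate dynamics + slow EE-weight depression, in fast time t/tau_m.

    Returns (drho_E, drho_I, dw_EE) with
    ``dw_EE = mu (w0 - w_EE) - q tau_m w_EE rho_E`` where
    ``mu = tau_m / tau_STP`` and w0 is the baseline EE weight."""
    p = replace(params, w={**params.w, "EE": w_EE}, u_eff=1.0)
    drho = rate_ode_rhs(rho, p) * params.neuron.tau_m  # per fast time unit
    mu = params.neuron.tau_m / stp.tau_STP
    w0 = params.w["EE"]
    dw = mu * (w0 - w_EE) - stp.q * params.neuron.tau_m * w_EE * rho[0] * 1e-3
    return np.array([drho[0], drho[1], dw])


def up_down_conditions(params: MeanFieldParams, stp: STPParams,
                       rho_H: float):
    """Necessary conditions for up->down switching by short-term depression.

    (i) ``k_EE w0 > k_EI w_EI`` -- a stable high-rate state exists;
    (ii) ``k_EE w0/(1 + tau_STP q rho_H) < k_EI w_EI`` -- the depressed
    stationary weight at the high-state rate destabilizes it."""
    lhs = params.k["EE"] * params.w["EE"]
    rhs = params.k["EI"] * params.w["EI"]
    depressed = lhs / (1.0 + stp.tau_STP * stp.q * rho_H * 1e-3)
    return bool(lhs > rhs), bool(depressed < rhs)


def scan_bifurcation(params: MeanFieldParams, w_EE_range, rho_ext_range,
                     grid_n: int = 60):
    """Regime-label grid over (w_EE, rho_Ext^E).

    Each cell is labeled by the sorted tuple of fixed-point regime labels
    (subsets of Q/L/M/H) found there."""
    labels = np.empty((len(w_EE_range), len(rho_ext_range)), dtype=object)
    for i, wEE in enumerate(w_EE_range):
        for j, rext in enumerate(rho_ext_range):
            p = replace(params, w={**params.w, "EE": float(wEE)},
                        drive=replace(params.drive, rho_ext_E=float(rext)))
            fps = find_fixed_points(p, grid_n=grid_n)
            labels[i, j] = tuple(sorted(fp.regime for fp in fps))
    return labels


def locate_bt(params: MeanFieldParams, w_EE0: float, rho_ext0: float,
              rho_E: float = 0.0, rho_I: float = 0.0):
    """Minimize the summed squared slope/intercept residuals over
    (w_EE, rho_Ext^E) starting from the given guess."""
    r0 = bt_residuals(params, rho_E, rho_I)
    s_scale = max(abs(r0.slope), 1e-6)
    i_scale = max(abs(r0.intercept), 1e-3)

    def cost(x):
        p = replace(params, w={**params.w, "EE": float(x[0])},
                    drive=replace(params.drive, rho_ext_E=float(x[1])))
        r = bt_residuals(p, rho_E, rho_I)
        return (r.slope / s_scale) ** 2 + (r.intercept / i_scale) ** 2
    res = optimize.minimize(cost, [w_EE0, rho_ext0], method="Nelder-Mead",
                            options={"xatol": 1e-6, "fatol": 1e-10})
    return res.x, res.fun
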