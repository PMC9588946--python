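"""Spiking simulation of the conductance-based LIF E-I network.

Integration is exponential-Euler throughout: synaptic conductances decay
exactly by ``exp(-dt/tau_syn)`` each step, and the membrane relaxes exactly
toward its instantaneous conductance-weighted equilibrium (stable at
arbitrarily large synaptic conductance, where a forward-Euler voltage step
would oscillate numerically).  Threshold crossing is checked after the
voltage update; the reset to
``v_rest`` happens in the same step and postsynaptic conductance jumps are
applied at the start of the next step (zero axonal delay, no refractory
period).

Optionally the kernel applies online pair-based STDP (all-to-all pairing via
exponential traces) to all four synapse classes and Tsodyks-Markram
short-term depression to E->E synapses (one resource variable per excitatory
neuron, shared by its out-edges).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from numba import njit

from .network import SynapseTable
from .params import DriveParams, NeuronParams, STDPKernel, STPParams

__all__ = ["SpikeRecord", "SimResult", "simulate", "population_series"]


class NumericError(RuntimeError):
    """Raised when the network state becomes non-finite."""


@dataclass
class SpikeRecord:
    """Time-sorted spike events with simulation metadata."""

    t_ms: np.ndarray
    neuron_id: np.ndarray
    N_exc: int
    N: int
    duration: float
    dt: float
    seed: int

    @property
    def population(self) -> np.ndarray:
        """Per-event population label ('E' or 'I')."""
        return np.where(self.neuron_id < self.N_exc, "E", "I")

    @property
    def n_spikes(self) -> int:
        return self.t_ms.size

    def to_tsv(self, path) -> None:
        pd.DataFrame({"t_ms": self.t_ms, "neuron_id": self.neuron_id,
                      "population": self.population}).to_csv(
            path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, N_exc, N, duration=np.nan, dt=np.nan, seed=-1):
        df = pd.read_csv(path, sep="\t")
        return cls(df["t_ms"].to_numpy(float),
                   df["neuron_id"].to_numpy(np.int64),
                   N_exc, N, duration, dt, seed)


@dataclass
class SimResult:
    spikes: SpikeRecord
    series: pd.DataFrame            # t_ms, rate_E_hz, rate_I_hz, vmean_E_mv, vmean_I_mv
    state: dict                     # final v, gE, gI, u, traces
    weights: pd.DataFrame           # epoch snapshots (empty if no plasticity)


@njit(cache=True)
def _run(n_steps, step0, dt, seed,
         # state
         v, gE, gI, dgE, dgI, u, trace_p, trace_m,
         # wiring
         weight, cls, pre, post, out_indptr, out_eidx, in_indptr, in_eidx,
         # neuron constants
         NE, N, vL, vth, vrest, VRe, VRi, tau_m, decE, decI, g0E, g0I,
         # drive
         lamE, lamI, w_ext,
         # plasticity
         stp_on, q, decSTP, stdp_on, Ap, Am, dec_p, dec_m, wmax,
         # recording
         rec_stride, rec_rateE, rec_rateI, rec_vE, rec_vI, rec_u,
         rec_count0, spike_t, spike_id, record_spikes):
    """Advance the network ``n_steps``; returns (spikes written, steps done,
    status).  status 1 = spike buffer full, 2 = non-finite state."""
    np.random.seed(seed)
    ns = 0
    cntE = rec_count0[0]
    cntI = rec_count0[1]
    inv_tm = dt / tau_m
    gjE = w_ext * g0E
    for it in range(n_steps):
        step = step0 + it
        # conductance decay + pending recurrent jumps
        for i in range(N):
            gE[i] = gE[i] * decE + dgE[i]
            gI[i] = gI[i] * decI + dgI[i]
            dgE[i] = 0.0
            dgI[i] = 0.0
        # external Poisson drive (merged-process thinning)
        kE = np.random.poisson(lamE)
        for _ in range(kE):
            gE[np.random.randint(0, NE)] += gjE
        kI = np.random.poisson(lamI)
        for _ in range(kI):
            gE[NE + np.random.randint(0, N - NE)] += gjE
        # membrane update + threshold (exponential-Euler: exact relaxation
        # toward the instantaneous conductance-weighted equilibrium;
        # unconditionally stable at large synaptic conductances)
        nspk = 0
        for i in range(N):
            gtot = 1.0 + gE[i] + gI[i]
            vinf = (vL + gE[i] * VRe + gI[i] * VRi) / gtot
            x = gtot * inv_tm
            if x < 0.02:
                # 1 - exp(-x) to O(x^4): avoids the exp call on the common
                # low-conductance path (error < 2e-9 relative)
                em = x * (1.0 - 0.5 * x + x * x / 6.0)
            else:
                em = -math.expm1(-x)
            vi = v[i] + (vinf - v[i]) * em
            if vi >= vth:
                spike_t[ns + nspk] = (step + 1) * dt
                spike_id[ns + nspk] = i
                nspk += 1
                vi = vrest
            v[i] = vi
        first = ns
        ns += nspk
        if stdp_on:
            for i in range(N):
                trace_p[i] *= dec_p
                trace_m[i] *= dec_m
            # pre-trace increments first so that same-step pairs take the
            # potentiation branch (dt = 0)
            for s in range(first, ns):
                trace_p[spike_id[s]] += 1.0
            for s in range(first, ns):
                i = spike_id[s]
                # potentiation of in-edges on postsynaptic spike
                for p in range(in_indptr[i], in_indptr[i + 1]):
                    e = in_eidx[p]
                    j = pre[e]
                    kind = 0 if j < NE else 1  # kernel by presynaptic class
                    w = weight[e] + Ap[kind] * trace_p[j]
                    wm = wmax[cls[e]]
                    if w > wm:
                        w = wm
                    weight[e] = w
                # depression of out-edges on presynaptic spike
                for p in range(out_indptr[i], out_indptr[i + 1]):
                    e = out_eidx[p]
                    kind = 0 if i < NE else 1
                    w = weight[e] - Am[kind] * trace_m[post[e]]
                    if w < 0.0:
                        w = 0.0
                    weight[e] = w
            for s in range(first, ns):
                trace_m[spike_id[s]] += 1.0
        # propagate spikes (jumps effective next step)
        for s in range(first, ns):
            i = spike_id[s]
            if i < NE:
                ui = u[i]
                for p in range(out_indptr[i], out_indptr[i + 1]):
                    e = out_eidx[p]
                    w = weight[e]
                    if cls[e] == 0:      # EE: scaled by efficacy
                        w *= ui
                    dgE[post[e]] += w * g0E
                if stp_on:
                    u[i] = ui * (1.0 - q)
                cntE += 1
            else:
                for p in range(out_indptr[i], out_indptr[i + 1]):
                    e = out_eidx[p]
                    dgI[post[e]] += weight[e] * g0I
                cntI += 1
        if stp_on:
            for i in range(NE):
                u[i] = 1.0 + (u[i] - 1.0) * decSTP
        # recording
        if (step + 1) % rec_stride == 0:
            r = (step + 1) // rec_stride - 1
            if r < rec_rateE.size:
                wnd = rec_stride * dt * 0.001  # s
                rec_rateE[r] = cntE / (wnd * NE)
                rec_rateI[r] = cntI / (wnd * (N - NE)) if N > NE else 0.0
                sE = 0.0
                sI = 0.0
                for i in range(NE):
                    sE += v[i]
                for i in range(NE, N):
                    sI += v[i]
                rec_vE[r] = sE / NE
                rec_vI[r] = sI / (N - NE) if N > NE else 0.0
                su = 0.0
                for i in range(NE):
                    su += u[i]
                rec_u[r] = su / NE if NE > 0 else 1.0
            cntE = 0
            cntI = 0
        if not (math.isfinite(v[0]) and math.isfinite(gE[0])):
            rec_count0[0] = cntE
            rec_count0[1] = cntI
            return ns, it + 1, 2
        if ns + N > spike_t.size:
            rec_count0[0] = cntE
            rec_count0[1] = cntI
            return ns, it + 1, 1
    rec_count0[0] = cntE
    rec_count0[1] = cntI
    return ns, n_steps, 0


def simulate(synapses: SynapseTable, drive: DriveParams, duration: float,
             dt: float = 0.1, seed: int = 0,
             neuron: Optional[NeuronParams] = None,
             stp: Optional[STPParams] = None,
             stdp: Optional[dict] = None,
             record_every: float = 1.0,
             snapshot_every: Optional[float] = None,
             init_state: Optional[dict] = None,
             record_spikes: bool = True,
             spike_buffer: int = 2_000_000) -> SimResult:
    """Simulate the network for ``duration`` ms.

    Parameters
    ----------
    stp : STPParams, optional
        Enables short-term depression of EE synapses.
    stdp : dict, optional
        ``{"E": STDPKernel, "I": STDPKernel}`` enables online STDP on all
        four synapse classes (kernel chosen by presynaptic population).
    record_every : float
        Sampling interval (ms) of the population rate / mean-potential
        series.
    snapshot_every : float, optional
        Interval (ms) at which mean weights per class are snapshotted
        (defaults to duration/50 when plasticity is on).

    Bitwise reproducible for fixed (seed, dt).  Weights in ``synapses`` are
    modified in place when STDP is enabled.
    """
    neuron = neuron or NeuronParams()
    N, NE = synapses.N, synapses.N_exc
    n_steps = int(round(duration / dt))
    if dt <= 0:
        raise ValueError("dt must be > 0")

    v = np.full(N, neuron.v_rest)
    gE = np.zeros(N)
    gI = np.zeros(N)
    dgE = np.zeros(N)
    dgI = np.zeros(N)
    u = np.ones(NE)
    trace_p = np.zeros(N)
    trace_m = np.zeros(N)
    if init_state:
        for k, arr in (("v", v), ("gE", gE), ("gI", gI), ("u", u)):
            if k in init_state:
                arr[:] = init_state[k]

    stdp_on = stdp is not None
    if stdp_on:
        kE, kI = stdp["E"], stdp["I"]
        Ap = np.array([kE.A_plus, kI.A_plus])
        Am = np.array([kE.A_minus, kI.A_minus])
        dec_p = math.exp(-dt / kE.tau_plus)
        dec_m = math.exp(-dt / kE.tau_minus)
        if abs(kE.tau_plus - kI.tau_plus) > 1e-12 or \
           abs(kE.tau_minus - kI.tau_minus) > 1e-12:
            raise NotImplementedError(
                "online kernel time constants must match across classes")
    else:
        Ap = np.zeros(2)
        Am = np.zeros(2)
        dec_p = dec_m = 1.0
    # per-class saturation: EE/IE share w_max_E scale via table construction;
    # bounds are taken from current weights if not provided
    wmax = np.empty(4)
    for c in range(4):
        mask = synapses.cls == c
        wmax[c] = 4.0 * synapses.weight[mask].mean() if mask.any() else np.inf
    if "wmax" in (stdp or {}):
        wmax = np.asarray(stdp["wmax"], dtype=float)

    stp_on = stp is not None
    q = stp.q if stp_on else 0.0
    decSTP = math.exp(-dt / stp.tau_STP) if stp_on else 1.0

    rec_stride = max(1, int(round(record_every / dt)))
    n_rec = n_steps // rec_stride
    rec_rateE = np.zeros(n_rec)
    rec_rateI = np.zeros(n_rec)
    rec_vE = np.zeros(n_rec)
    rec_vI = np.zeros(n_rec)
    rec_u = np.ones(n_rec)
    rec_count0 = np.zeros(2, dtype=np.int64)

    plastic = stdp_on or stp_on
    if snapshot_every is None:
        snapshot_every = duration / 50 if plastic else duration
    snap_steps = max(1, int(round(snapshot_every / dt)))

    cap = spike_buffer
    spike_t = np.empty(cap)
    spike_id = np.empty(cap, dtype=np.int64)
    all_t = []
    all_id = []
    snaps = []

    decE = math.exp(-dt / neuron.tau_syn_exc)
    decI = math.exp(-dt / neuron.tau_syn_inh)
    lamE = NE * drive.rho_ext_E * dt * 1e-3
    lamI = (N - NE) * drive.rho_ext_I * dt * 1e-3

    def snapshot(t):
        row = {"t_ms": t}
        for cname in ("EE", "EI", "IE", "II"):
            row["w" + cname] = synapses.mean_weight(cname)
        row["u_mean"] = float(u.mean()) if NE else 1.0
        row["deltaW"] = (row["u_mean"] * row["wEE"] * row["wII"]
                         - row["wEI"] * row["wIE"])
        snaps.append(row)

    if plastic:
        snapshot(0.0)

    step = 0
    chunk = 0
    while step < n_steps:
        todo = min(n_steps - step, snap_steps if plastic else n_steps)
        done = 0
        while done < todo:
            ns, d, status = _run(
                todo - done, step + done, dt,
                (seed + 12345 * chunk) % (2**31 - 1),
                v, gE, gI, dgE, dgI, u, trace_p, trace_m,
                synapses.weight, synapses.cls, synapses.pre, synapses.post,
                synapses.out_indptr, synapses.out_edges,
                synapses.in_indptr, synapses.in_edges,
                NE, N, neuron.v_leak, neuron.v_th, neuron.v_rest,
                neuron.V_R_exc, neuron.V_R_inh, neuron.tau_m,
                decE, decI, neuron.g0_exc, neuron.g0_inh,
                lamE, lamI, drive.w_ext,
                stp_on, q, decSTP, stdp_on, Ap, Am, dec_p, dec_m, wmax,
                rec_stride, rec_rateE, rec_rateI, rec_vE, rec_vI, rec_u,
                rec_count0, spike_t, spike_id, record_spikes)
            chunk += 1
            if status == 2:
                raise NumericError(
                    f"non-finite state at t={(step + done + d) * dt:.3f} ms")
            if record_spikes and ns:
                all_t.append(spike_t[:ns].copy())
                all_id.append(spike_id[:ns].copy())
            done += d
        step += todo
        if plastic:
            snapshot(step * dt)

    t_arr = np.concatenate(all_t) if all_t else np.empty(0)
    id_arr = np.concatenate(all_id) if all_id else np.empty(0, dtype=np.int64)
    spikes = SpikeRecord(t_arr, id_arr, NE, N, duration, dt, seed)
    series = pd.DataFrame({
        "t_ms": (np.arange(1, n_rec + 1)) * rec_stride * dt,
        "rate_E_hz": rec_rateE, "rate_I_hz": rec_rateI,
        "vmean_E_mv": rec_vE, "vmean_I_mv": rec_vI,
        "u_mean": rec_u,
    })
    state = {"v": v, "gE": gE, "gI": gI, "u": u,
             "trace_p": trace_p, "trace_m": trace_m}
    weights = pd.DataFrame(snaps)
    return SimResult(spikes, series, state, weights)


def population_series(spikes: SpikeRecord, bin: float) -> pd.DataFrame:
    """Per-population firing rate (Hz per neuron) in fixed time bins.

    The summed counts satisfy ``sum(rate * bin/1000 * N_pop) == n_spikes``.
    """
    if bin <= 0:
        raise ValueError("bin must be > 0")
    if spikes.n_spikes == 0:
        return pd.DataFrame(columns=["t_ms", "rate_E_hz", "rate_I_hz"])
    t_end = max(spikes.duration if np.isfinite(spikes.duration) else 0.0,
                float(spikes.t_ms.max()))
    edges = np.arange(0.0, t_end + bin, bin)
    isE = spikes.neuron_id < spikes.N_exc
    cE, _ = np.histogram(spikes.t_ms[isE], bins=edges)
    cI, _ = np.histogram(spikes.t_ms[~isE], bins=edges)
    NI = spikes.N - spikes.N_exc
    return pd.DataFrame({
        "t_ms": edges[:-1],
        "rate_E_hz": cE / (spikes.N_exc * bin * 1e-3),
        "rate_I_hz": cI / (NI * bin * 1e-3) if NI else np.zeros(cE.size),
    })
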