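"""Avalanche detection and criticality statistics.

An avalanche is a maximal run of consecutive non-empty time bins of the
merged spike train, separated by at least one empty bin; its size is the
spike count of the run, its duration the run length in bins.  The default
bin width is the population mean inter-event interval.

Two power-law fitters are provided: linear regression on the log-log
complementary cumulative size distribution (exponent = slope + 1), and the
discrete maximum-likelihood estimator with Kolmogorov-Smirnov selection of
the lower cutoff.  Criticality diagnostics include the branching ratio (two
estimators), interspike-interval variability, avalanche shape collapse, and
the mean size vs. duration scaling exponent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .simulate import SpikeRecord

__all__ = [
    "AvalancheCatalog", "PowerLawFit", "BranchingEstimate",
    "detect_avalanches", "fit_power_law", "branching_ratio", "isi_cv",
    "shape_collapse", "size_duration_scaling",
]


@dataclass
class AvalancheCatalog:
    """Detected avalanches, time-ordered and disjoint."""

    start_bin: np.ndarray
    duration: np.ndarray       # bins
    size: np.ndarray           # spikes
    profiles: list             # per-avalanche per-bin spike counts
    bin_ms: float
    n_spikes_total: int

    @property
    def n(self) -> int:
        return self.size.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "start_ms": self.start_bin * self.bin_ms,
            "duration_bins": self.duration,
            "size": self.size,
        })

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def detect_avalanches(spikes: SpikeRecord, bin="auto") -> AvalancheCatalog:
    """Bin the merged spike train and extract non-empty runs.

    bin='auto' uses the mean inter-event interval of the merged train.
    Every spike belongs to exactly one avalanche (sizes sum to the total
    spike count)."""
    t = np.sort(np.asarray(spikes.t_ms, dtype=float))
    if t.size == 0:
        z = np.empty(0, dtype=np.int64)
        return AvalancheCatalog(z, z, z, [], float(bin) if bin != "auto"
                                else np.nan, 0)
    if bin == "auto":
        if t.size < 2:
            bin_ms = 1.0
        else:
            bin_ms = float(np.diff(t).mean())
            if bin_ms <= 0:
                bin_ms = 1.0
        # never bin finer than the simulation time step: spikes emitted in
        # the same step are simultaneous by construction
        if np.isfinite(spikes.dt) and spikes.dt > 0:
            bin_ms = max(bin_ms, spikes.dt)
    else:
        bin_ms = float(bin)
        if bin_ms <= 0:
            raise ValueError("bin must be > 0")
    idx = np.floor(t / bin_ms).astype(np.int64)  # absolute bin grid
    # run-length encode occupied bins
    bins, counts = np.unique(idx, return_counts=True)
    brk = np.nonzero(np.diff(bins) > 1)[0] + 1
    seg_starts = np.concatenate([[0], brk])
    seg_ends = np.concatenate([brk, [bins.size]])
    starts = bins[seg_starts]
    durations = bins[seg_ends - 1] - starts + 1
    sizes = np.add.reduceat(counts, seg_starts)
    profiles = []
    for s, e, st, d in zip(seg_starts, seg_ends, starts, durations):
        prof = np.zeros(d, dtype=np.int64)
        prof[bins[s:e] - st] = counts[s:e]
        profiles.append(prof)
    return AvalancheCatalog(starts, durations.astype(np.int64),
                            sizes.astype(np.int64), profiles, bin_ms,
                            int(t.size))


@dataclass
class PowerLawFit:
    exponent: float
    method: str                # "ccdf" or "mle"
    x_min: int
    stderr: float
    ks: float

    def __repr__(self):
        return (f"PowerLawFit({self.method}: exponent="
                f"{self.exponent:.3f}+-{self.stderr:.3f}, "
                f"x_min={self.x_min}, KS={self.ks:.3f})")


def _zeta(a, x_min):
    return special.zeta(a, x_min)


def _mle_at(x, x_min):
    xs = x[x >= x_min].astype(float)
    n = xs.size
    slog = np.log(xs).sum()

    def nll(a):
        return n * np.log(_zeta(a, x_min)) + a * slog

    res = optimize.minimize_scalar(nll, bounds=(1.01, 6.0), method="bounded",
                                   options={"xatol": 1e-7})
    a = float(res.x)
    # observed Fisher information via numeric second derivative
    h = 1e-4
    d2 = (nll(a + h) - 2 * nll(a) + nll(a - h)) / h ** 2
    se = 1.0 / np.sqrt(d2) if d2 > 0 else np.nan
    # KS distance of the fitted discrete law
    xmax = int(min(xs.max(), 10_000_000))
    ks = _ks_discrete(xs, a, x_min, xmax)
    return a, se, ks, n


def _ks_discrete(xs, a, x_min, xmax):
    vals = np.unique(xs)
    z = _zeta(a, x_min)
    # model CCDF at each observed value: zeta(a, v)/zeta(a, x_min)
    model_ccdf = np.array([_zeta(a, v) / z for v in vals])
    emp_sorted = np.sort(xs)
    # empirical P(X >= v)
    emp_ccdf = 1.0 - np.searchsorted(emp_sorted, vals, side="left") / xs.size
    return float(np.max(np.abs(emp_ccdf - model_ccdf)))


def fit_power_law(sizes: Sequence, method: str = "mle",
                  x_min: Optional[int] = None,
                  n_bootstrap: int = 20, seed: int = 0) -> PowerLawFit:
    """Fit a power-law exponent to avalanche sizes (or durations).

    method='ccdf': linear regression of log CCDF against log size over
    [x_min, 99th percentile]; the size-distribution exponent is
    slope + 1 (standard error by resampling bootstrap).
    method='mle': discrete maximum likelihood (Hurwitz-zeta normalization)
    with x_min chosen by KS-distance minimization unless given.
    """
    x = np.asarray(sizes)
    x = x[np.isfinite(x) & (x >= 1)].astype(np.int64)
    if method == "ccdf":
        if x.size < 100:
            raise ValueError("CCDF regression needs >= 100 samples")
    elif x.size < 50:
        raise ValueError("MLE needs >= 50 samples")
    if np.unique(x).size < 2:
        raise ValueError("degenerate sample: all values equal")

    if method == "mle":
        if x_min is not None:
            a, se, ks, _ = _mle_at(x, x_min)
            return PowerLawFit(a, "mle", int(x_min), se, ks)
        best = None
        cand = np.unique(x)
        cand = cand[cand <= np.quantile(x, 0.9)][:40]
        for xm in cand:
            if np.count_nonzero(x >= xm) < 50:
                break
            a, se, ks, _ = _mle_at(x, int(xm))
            if best is None or ks < best[2]:
                best = (a, se, ks, int(xm))
        a, se, ks, xm = best
        return PowerLawFit(a, "mle", xm, se, ks)

    if method != "ccdf":
        raise ValueError("method must be 'ccdf' or 'mle'")
    xm = 1 if x_min is None else int(x_min)

    def slope_of(sample):
        vals = np.unique(sample)
        hi = np.quantile(sample, 0.99)
        vals = vals[(vals >= xm) & (vals <= max(hi, xm + 1))]
        if vals.size < 3:
            vals = np.unique(sample)[:max(3, 1)]
        srt = np.sort(sample)
        ccdf = 1.0 - np.searchsorted(srt, vals, side="left") / sample.size
        keep = ccdf > 0
        lx, ly = np.log(vals[keep]), np.log(ccdf[keep])
        sl = stats.linregress(lx, ly).slope
        return -sl

    s0 = slope_of(x)
    rng = np.random.default_rng(seed)
    boots = [slope_of(rng.choice(x, x.size, replace=True))
             for _ in range(n_bootstrap)]
    se = float(np.std(boots, ddof=1)) if n_bootstrap > 1 else np.nan
    exponent = s0 + 1.0
    # KS against the pure power law implied by the regression exponent
    ks = _ks_discrete(x[x >= xm].astype(float), max(exponent, 1.01), xm,
                      int(x.max()))
    return PowerLawFit(float(exponent), "ccdf", xm, se, ks)


@dataclass
class BranchingEstimate:
    estimator: str             # "bin-ratio" or "causal-descendant"
    value: float
    stderr: float


def branching_ratio(spikes: SpikeRecord, synapses=None, bin="auto",
                    estimator: str = "bin-ratio",
                    window_ms: float = 5.0) -> BranchingEstimate:
    """Branching ratio: expected spikes triggered per spike.

    'bin-ratio': mean over within-avalanche consecutive bin pairs of
    n(t+1)/n(t).  'causal-descendant': for each presynaptic spike, the
    weight-fractional count of postsynaptic spikes within ``window_ms``
    attributable to it (requires the wiring)."""
    if spikes.n_spikes == 0:
        raise ValueError("empty spike record")
    if estimator == "bin-ratio":
        cat = detect_avalanches(spikes, bin)
        ratios = []
        for prof in cat.profiles:
            if prof.size >= 2:
                ratios.extend(prof[1:] / prof[:-1])
            # terminating transition n -> 0: required for unbiasedness
            # (conditioning on non-empty successor bins inflates the mean)
            ratios.append(0.0)
        if not ratios:
            return BranchingEstimate("bin-ratio", np.nan, np.nan)
        r = np.asarray(ratios, dtype=float)
        return BranchingEstimate("bin-ratio", float(r.mean()),
                                 float(r.std(ddof=1) / np.sqrt(r.size))
                                 if r.size > 1 else np.nan)
    if estimator != "causal-descendant":
        raise ValueError("unknown estimator")
    if synapses is None:
        raise ValueError("causal-descendant estimator requires the wiring")
    order = np.argsort(spikes.t_ms, kind="stable")
    t = spikes.t_ms[order]
    ids = spikes.neuron_id[order]
    n = t.size
    # per postsynaptic spike, distribute one unit of attribution among the
    # presynaptic spikes within the preceding window, weighted by synaptic
    # weight; accumulate per presynaptic spike, then average.
    credit = np.zeros(n)
    # weight lookup: dict of (pre, post) -> w would be large; use in-edge CSR
    w_of = {}
    for e in range(synapses.n_edges):
        w_of[(synapses.pre[e], synapses.post[e])] = synapses.weight[e]
    lo = 0
    for s in range(n):
        while t[lo] < t[s] - window_ms:
            lo += 1
        cand = []
        for p in range(lo, s):
            w = w_of.get((ids[p], ids[s]))
            if w is not None:
                cand.append((p, w))
        if cand:
            tot = sum(w for _, w in cand)
            for p, w in cand:
                credit[p] += w / tot
    # exclude spikes whose window extends past the end of the record
    t_end = t[-1]
    valid = t <= t_end - window_ms
    if not np.any(valid):
        valid[:] = True
    vals = credit[valid]
    return BranchingEstimate("causal-descendant", float(vals.mean()),
                             float(vals.std(ddof=1) / np.sqrt(vals.size))
                             if vals.size > 1 else np.nan)


def isi_cv(spikes: SpikeRecord, min_spikes: int = 3) -> pd.DataFrame:
    """Per-neuron coefficient of variation of inter-spike intervals.

    CV = 1 marks Poisson-like firing; 0 a perfectly periodic train.
    Neurons with fewer than ``min_spikes`` spikes are omitted."""
    df = pd.DataFrame({"id": spikes.neuron_id, "t": spikes.t_ms})
    rows = []
    for nid, grp in df.groupby("id"):
        tt = np.sort(grp["t"].to_numpy())
        if tt.size < min_spikes:
            continue
        isi = np.diff(tt)
        m = isi.mean()
        rows.append({"neuron_id": int(nid), "n_spikes": int(tt.size),
                     "cv": float(isi.std(ddof=1) / m) if m > 0 else np.nan})
    return pd.DataFrame(rows)


def shape_collapse(catalog: AvalancheCatalog, min_per_duration: int = 20,
                   min_duration: int = 4, n_interp: int = 50):
    """Avalanche shape-collapse exponent.

    Mean temporal profiles per duration T are rescaled to t/T on a common
    grid and multiplied by T^(1-g); the returned ``g`` (= sigma nu z in the
    scaling form <s(t,T)> = T^(g-1) F(t/T)) minimizes the mean squared
    deviation between rescaled profiles.  Returns (g, residual)."""
    if np.any(np.diff(catalog.start_bin) < 0):
        raise ValueError("catalog must be time-ordered")
    durs, counts = np.unique(catalog.duration, return_counts=True)
    keep = durs[(durs >= min_duration) & (counts >= min_per_duration)]
    if keep.size < 2:
        raise ValueError("insufficient statistics for shape collapse "
                         f"(need >= 2 durations with >= {min_per_duration} "
                         "avalanches)")
    grid = np.linspace(0.0, 1.0, n_interp)
    profs = {}
    for T in keep:
        sel = [p for p, d in zip(catalog.profiles, catalog.duration)
               if d == T]
        mean_prof = np.mean(np.stack(sel), axis=0)
        x = (np.arange(T) + 0.5) / T
        profs[T] = np.interp(grid, x, mean_prof)

    def residual(g):
        scaled = np.stack([profs[T] * T ** (1.0 - g) for T in keep])
        m = scaled.mean(axis=0)
        denom = np.mean(m ** 2)
        return float(np.mean((scaled - m) ** 2) / denom) if denom > 0 else np.inf

    res = optimize.minimize_scalar(residual, bounds=(0.5, 3.5),
                                   method="bounded",
                                   options={"xatol": 1e-5})
    return float(res.x), float(res.fun)


def size_duration_scaling(catalog: AvalancheCatalog,
                          min_per_duration: int = 20,
                          min_duration: int = 1) -> float:
    """Regression slope of log <size> against log duration.

    At criticality this is 1/(sigma nu z); the critical branching value
    is 2."""
    durs, counts = np.unique(catalog.duration, return_counts=True)
    keep = durs[(durs >= min_duration) & (counts >= min_per_duration)]
    if keep.size < 2:
        raise ValueError("insufficient statistics for size-duration scaling")
    mean_s = np.array([catalog.size[catalog.duration == T].mean()
                       for T in keep])
    return float(stats.linregress(np.log(keep.astype(float)),
                                  np.log(mean_s)).slope)
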