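"""Generators with known ground truth for testing the estimators.

These produce Poisson spike trains, Galton-Watson branching-process
avalanche catalogs (critical at mean offspring m = 1, where the avalanche
size law has exponent 3/2 asymptotically), and discrete power-law samples.
Every generator is deterministic per seed and emits its ground truth
alongside the data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special

from .simulate import SpikeRecord

__all__ = ["BranchingConfig", "poisson_train", "branching_avalanches",
           "power_law_samples"]


def poisson_train(rate_hz: float, T_ms: float, seed: int = 0) -> np.ndarray:
    """Homogeneous Poisson spike times on [0, T) in ms."""
    if rate_hz < 0:
        raise ValueError("rate must be >= 0")
    rng = np.random.default_rng(seed)
    n = rng.poisson(rate_hz * T_ms * 1e-3)
    return np.sort(rng.uniform(0.0, T_ms, n))


@dataclass(frozen=True)
class BranchingConfig:
    """Galton-Watson avalanche generator.

    Each avalanche starts from ``n_seed`` spikes in generation 0; every
    spike in generation g produces offspring in generation g+1 with the
    given law (mean ``m``).  One generation maps to one time bin of
    ``bin_ms`` when serialized as a spike record; avalanches are separated
    by ``gap_bins`` empty bins so that detection at this bin width recovers
    the true catalog exactly."""

    m: float = 1.0
    law: str = "poisson"       # or "geometric"
    n_seed: int = 1
    max_generations: int = 10_000
    bin_ms: float = 5.0
    gap_bins: int = 3

    def __post_init__(self):
        if self.m < 0:
            raise ValueError("mean offspring must be >= 0")
        if self.law not in ("poisson", "geometric"):
            raise ValueError("offspring law must be poisson or geometric")


def branching_avalanches(config: BranchingConfig, n_avalanches: int,
                         seed: int = 0, n_neurons: int = 10_000):
    """Simulate branching-process avalanches and serialize as spikes.

    Returns ``(record, truth)`` where truth is a dict of per-avalanche
    ground-truth sizes, durations (generations), and per-generation
    profiles.  Spike times are placed at bin centers; neuron ids are drawn
    uniformly (identity does not matter for the catalog statistics)."""
    rng = np.random.default_rng(seed)
    sizes = np.empty(n_avalanches, dtype=np.int64)
    durations = np.empty(n_avalanches, dtype=np.int64)
    profiles = []
    times = []
    ids = []
    cursor = 0  # bin index
    for a in range(n_avalanches):
        prof = []
        n = config.n_seed
        g = 0
        while n > 0 and g < config.max_generations:
            prof.append(n)
            if config.law == "poisson":
                n = int(rng.poisson(config.m * n))
            else:
                # geometric on {0,1,...} with mean m: p = 1/(1+m)
                n = int(rng.geometric(1.0 / (1.0 + config.m), size=n).sum()
                        - n) if n else 0
            g += 1
        prof = np.array(prof, dtype=np.int64)
        profiles.append(prof)
        sizes[a] = prof.sum()
        durations[a] = prof.size
        for gi, cnt in enumerate(prof):
            t = (cursor + gi + 0.5) * config.bin_ms
            times.append(np.full(cnt, t))
            ids.append(rng.integers(0, n_neurons, cnt))
        cursor += prof.size + config.gap_bins
    t_arr = np.concatenate(times) if times else np.empty(0)
    id_arr = (np.concatenate(ids) if ids else np.empty(0, dtype=np.int64))
    order = np.argsort(t_arr, kind="stable")
    record = SpikeRecord(t_arr[order], id_arr[order], n_neurons, n_neurons,
                         cursor * config.bin_ms, config.bin_ms, seed)
    truth = {"sizes": sizes, "durations": durations, "profiles": profiles,
             "m": config.m}
    return record, truth


def power_law_samples(exponent: float, x_min: int, n: int,
                      seed: int = 0, cutoff: int = 1_000_000) -> np.ndarray:
    """Discrete power-law variates P(x) ~ x^-exponent for x >= x_min.

    Exact inverse-transform sampling through the Hurwitz-zeta CDF up to
    ``cutoff``; the (tiny) tail mass beyond the cutoff falls back to the
    continuous-approximation transform.  All samples are >= x_min."""
    if exponent <= 1:
        raise ValueError("exponent must be > 1")
    if n == 0:
        return np.empty(0, dtype=np.int64)
    rng = np.random.default_rng(seed)
    xs = np.arange(x_min, cutoff + 1, dtype=float)
    pmf = xs ** (-exponent)
    z = special.zeta(exponent, x_min)
    cdf = np.cumsum(pmf) / z
    r = rng.random(n)
    out = x_min + np.searchsorted(cdf, r, side="left")
    tail = out > cutoff
    if np.any(tail):
        # continuous inverse transform conditioned on exceeding the cutoff
        rt = rng.random(int(tail.sum()))
        out[tail] = np.floor(
            (cutoff + 0.5) * (1.0 - rt) ** (-1.0 / (exponent - 1.0)) + 0.5
        ).astype(np.int64)
    return out.astype(np.int64)
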