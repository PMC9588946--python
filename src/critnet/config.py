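"""Experiment configuration: YAML round-trip, validation, seed management.

A single structured file covers the network, neuron, drive, plasticity and
analysis sections; unknown keys are rejected and every run writes the fully
resolved configuration next to its outputs so that a run directory is
self-describing.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from .params import (ConfigError, DriveParams, NetworkConfig, NeuronParams,
                     STDPKernel, STPParams, WeightDist)

__all__ = ["ExperimentConfig", "load_config", "save_config", "spawn_seed"]


@dataclass
class ExperimentConfig:
    seed: int = 0
    scale: float = 1.0           # divides N and degrees jointly
    duration_ms: float = 10_000.0
    dt_ms: float = 0.1
    out_dir: str = "runs"
    network: NetworkConfig = field(default_factory=NetworkConfig)
    neuron: NeuronParams = field(default_factory=NeuronParams)
    drive: DriveParams = field(default_factory=DriveParams)
    stp: Optional[STPParams] = None
    stdp: Optional[dict] = None   # {"E": STDPKernel, "I": STDPKernel}

    def scaled_network(self) -> NetworkConfig:
        if self.scale == 1.0:
            return self.network
        s = self.scale
        n = self.network
        return dataclasses.replace(
            n, N_exc=max(1, int(n.N_exc / s)), N_inh=max(1, int(n.N_inh / s)),
            k_EE=max(1, int(n.k_EE / s)), k_EI=max(1, int(n.k_EI / s)),
            k_IE=max(1, int(n.k_IE / s)), k_II=max(1, int(n.k_II / s)))


_SECTION_TYPES = {
    "network": NetworkConfig,
    "neuron": NeuronParams,
    "drive": DriveParams,
    "stp": STPParams,
}
_SCALARS = {"seed", "scale", "duration_ms", "dt_ms", "out_dir"}


def _build_section(cls, data, name):
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - fields
    if unknown:
        raise ConfigError(f"unknown keys in section '{name}': "
                          f"{sorted(unknown)}")
    if cls is NetworkConfig and "weights" in data:
        data = dict(data)
        data["weights"] = {k: WeightDist(**v) if isinstance(v, dict)
                           else WeightDist(mean=float(v))
                           for k, v in data["weights"].items()}
    return cls(**data)


def load_config(path) -> ExperimentConfig:
    """Load and validate a YAML experiment configuration.

    Missing sections fall back to defaults; unknown keys raise
    :class:`ConfigError` with the offending names."""
    path = Path(path)
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError("top level must be a mapping")
    unknown = set(raw) - _SCALARS - set(_SECTION_TYPES) - {"stdp"}
    if unknown:
        raise ConfigError(f"unknown top-level keys: {sorted(unknown)}")
    kw = {k: raw[k] for k in _SCALARS if k in raw}
    for name, cls in _SECTION_TYPES.items():
        if name in raw and raw[name] is not None:
            kw[name] = _build_section(cls, raw[name], name)
    if raw.get("stdp"):
        kw["stdp"] = {k: _build_section(STDPKernel, v, f"stdp.{k}")
                      for k, v in raw["stdp"].items()}
    return ExperimentConfig(**kw)


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_plain(v)
                for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def save_config(config: ExperimentConfig, path) -> None:
    """Write the fully resolved configuration as YAML (round-trips through
    :func:`load_config`)."""
    data = _to_plain(config)
    data = {k: v for k, v in data.items() if v is not None}
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def spawn_seed(seed: int, stream: str) -> int:
    """Derive an independent per-module substream seed from the global seed.

    Toggling one analysis stream never perturbs the randomness of another.
    Result is < 2**31."""
    import zlib
    ss = np.random.SeedSequence([seed, zlib.crc32(stream.encode())])
    return int(ss.generate_state(1)[0] % (2**31 - 1))
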