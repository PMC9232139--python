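"""Configuration loading/validation and result serialization.

Run configurations are plain YAML (or JSON) mapping onto :class:`RunConfig`;
unknown keys are rejected with the offending location in the message, and
every result bundle embeds the fully-resolved configuration and seed so that
any published number can be regenerated from its bundle alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, InputError

__all__ = ["RunConfig", "load_config", "save_config", "write_bundle"]


@dataclass
class ModelSection:
    channels_file: str | None = None  # None -> packaged Table-1 defaults
    channel_overrides: dict = field(default_factory=dict)
    v_rest: float = -55.0
    g_leak: float = 1e-4
    e_leak: float | None = None
    temperature: float = 24.0


@dataclass
class SynapseSection:
    delay: float = 3.0
    g_sk: float = 0.03
    agonist_pulse_ms: float = 50.0


@dataclass
class ProtocolSection:
    name: str = "fig3_gabaa_fepsp"
    deterministic_isi: bool = True
    overrides: dict = field(default_factory=dict)


@dataclass
class NumericsSection:
    dt: float = 0.025
    settle_ms: float = 200.0
    spike_threshold: float = -15.0
    refractory_ms: float = 2.0

    def validate(self):
        if not (0 < self.dt <= 0.1):
            raise ConfigurationError(f"numerics.dt: expected 0 < dt <= 0.1, got {self.dt}")
        if self.settle_ms < 0:
            raise ConfigurationError("numerics.settle_ms: must be >= 0")


@dataclass
class RunConfig:
    model: ModelSection = field(default_factory=ModelSection)
    synapses: SynapseSection = field(default_factory=SynapseSection)
    protocol: ProtocolSection = field(default_factory=ProtocolSection)
    numerics: NumericsSection = field(default_factory=NumericsSection)
    seed: int = 0
    out_dir: str = "results"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


_SECTIONS = {
    "model": ModelSection,
    "synapses": SynapseSection,
    "protocol": ProtocolSection,
    "numerics": NumericsSection,
}


def _build_section(cls, data: dict, where: str):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    kwargs = {}
    for key, value in data.items():
        if key not in fields:
            raise ConfigurationError(
                f"unknown key {where}.{key!r}; expected one of {sorted(fields)}"
            )
        ftype = fields[key].type
        if ftype in ("float", "float | None") and value is not None:
            if not isinstance(value, (int, float)) or isinstance(value, bool):
                raise ConfigurationError(
                    f"{where}.{key}: expected a number, got {value!r}"
                )
            value = float(value)
        kwargs[key] = value
    return cls(**kwargs)


def load_config(path) -> RunConfig:
    """Load and validate a run configuration; absent keys take the built-in
    (Table-1) defaults, so an empty file yields the full default config."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigurationError(f"{path}: top level must be a mapping")
    kwargs = {}
    for key, value in raw.items():
        if key in _SECTIONS:
            if not isinstance(value, dict):
                raise ConfigurationError(f"{key}: expected a mapping")
            kwargs[key] = _build_section(_SECTIONS[key], value, key)
        elif key == "seed":
            if not isinstance(value, int):
                raise ConfigurationError(f"seed: expected an integer, got {value!r}")
            kwargs["seed"] = value
        elif key == "out_dir":
            kwargs["out_dir"] = str(value)
        else:
            raise ConfigurationError(
                f"unknown top-level key {key!r}; expected one of "
                f"{sorted([*_SECTIONS, 'seed', 'out_dir'])}"
            )
    cfg = RunConfig(**kwargs)
    cfg.numerics.validate()
    return cfg


def save_config(cfg: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_bundle(result, out_dir, config: RunConfig | None = None) -> dict:
    """Write a result bundle: traces.csv, events.jsonl, summary.json and the
    resolved config; returns (and writes) a manifest with checksums.

    *result* is a :class:`~entsim.experiments.ProtocolResult` (or None for a
    config-only bundle).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = []

    cfg = config or RunConfig()
    if result is not None:
        cfg.protocol.name = result.protocol
        cfg.seed = result.seed
    save_config(cfg, out / "config.resolved.yaml")
    files.append("config.resolved.yaml")

    if result is not None:
        if result.traces is not None:
            tr = result.traces
            df = pd.DataFrame(
                tr.v, columns=[f"v_seg{i}" for i in range(tr.v.shape[1])]
            )
            df.insert(0, "time_ms", tr.t)
            df.to_csv(out / "traces.csv", index=False, float_format="%.6g")
            files.append("traces.csv")
        with open(out / "events.jsonl", "w") as fh:
            for ts, amp in zip(result.spike_times, result.amplitudes):
                fh.write(json.dumps(
                    {"type": "spike", "t_ms": round(float(ts), 6),
                     "amplitude_mv": round(float(amp), 6)}) + "\n")
            for gen, n in sorted(result.input_spike_counts.items()):
                fh.write(json.dumps(
                    {"type": "input_spikes", "generator": gen, "count": int(n)}) + "\n")
        files.append("events.jsonl")
        summary = {
            "protocol": result.protocol,
            "seed": result.seed,
            "output_spike_count": int(result.output_spike_count),
            "spike_times_ms": [float(x) for x in result.spike_times],
            "amplitudes_mv": [float(x) for x in result.amplitudes],
            "input_spike_counts": {k: int(v) for k, v in
                                   result.input_spike_counts.items()},
            "weights_us": {k: float(v) for k, v in result.weights.items()},
            "window_ms": list(result.window),
            "extras": {k: v for k, v in result.extras.items()
                       if isinstance(v, (int, float, str, dict))},
        }
        (out / "summary.json").write_text(json.dumps(summary, indent=2))
        files.append("summary.json")

    manifest = {name: _sha256(out / name) for name in files}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
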