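"""Configuration files, state containers and run manifests.

Configuration is a YAML/JSON mapping with one section per parameter group
(``network``, ``neuron``, ``waveform``, ``nmda``, ``plasticity``,
``stdp``); omitted keys take the published defaults, unknown keys are
errors.  Simulation state (network, weights, calcium, spike records)
round-trips through an HDF5 container.  A ``RunManifest`` records the
config snapshot, all named RNG seeds and the output inventory of a run
directory so any result can be regenerated from the manifest alone.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional

import h5py
import numpy as np
import yaml

from . import __version__
from .construction import InputProjection, Network
from .params import (NetworkConfig, NeuronParams, NMDACurrentParams,
                     PlasticityParams, STDPParams, WaveformParams)

__all__ = ["Config", "load_config", "save_config", "save_state", "load_state",
           "RunManifest"]

_SECTIONS = {
    "network": NetworkConfig,
    "neuron": NeuronParams,
    "waveform": WaveformParams,
    "nmda": NMDACurrentParams,
    "plasticity": PlasticityParams,
    "stdp": STDPParams,
}


@dataclass
class Config:
    """Validated bundle of all parameter groups."""

    network: NetworkConfig = field(default_factory=NetworkConfig)
    neuron: NeuronParams = field(default_factory=NeuronParams)
    waveform: WaveformParams = field(default_factory=WaveformParams)
    nmda: NMDACurrentParams = field(default_factory=NMDACurrentParams)
    plasticity: PlasticityParams = field(default_factory=PlasticityParams)
    stdp: STDPParams = field(default_factory=STDPParams)

    def to_dict(self) -> dict:
        out = {}
        for name in _SECTIONS:
            d = dataclasses.asdict(getattr(self, name))
            if name == "network":
                d["dims"] = list(d["dims"])
            if name == "neuron":
                d["v_reset_range"] = list(d["v_reset_range"])
            out[name] = d
        return out

    @classmethod
    def from_dict(cls, data: dict) -> "Config":
        unknown = set(data) - set(_SECTIONS)
        if unknown:
            raise ValueError(f"unknown config sections: {sorted(unknown)}")
        kwargs = {}
        for name, klass in _SECTIONS.items():
            section = data.get(name, {})
            if not isinstance(section, dict):
                raise ValueError(f"section {name!r} must be a mapping")
            known = {f.name for f in dataclasses.fields(klass)}
            bad = set(section) - known
            if bad:
                raise ValueError(f"unknown keys in {name!r}: {sorted(bad)}")
            if name == "network" and "dims" in section:
                section = {**section, "dims": tuple(section["dims"])}
            if name == "neuron" and "v_reset_range" in section:
                section = {**section, "v_reset_range": tuple(section["v_reset_range"])}
            kwargs[name] = klass(**section)
        return cls(**kwargs)


def load_config(path) -> Config:
    """Read and validate a YAML/JSON configuration file."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return Config.from_dict(data or {})


def save_config(config: Config, path) -> None:
    path = Path(path)
    data = config.to_dict()
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2))
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))


_FORMAT_VERSION = 1


def save_state(path, network: Network,
               weights: Optional[np.ndarray] = None,
               calcium: Optional[np.ndarray] = None,
               records: Optional[dict] = None) -> None:
    """Write network + synapse state (+ optional spike records) to HDF5."""
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = _FORMAT_VERSION
        f.attrs["famnet_version"] = __version__
        g = f.create_group("network")
        g.create_dataset("positions", data=network.positions)
        g.create_dataset("is_excitatory", data=network.is_excitatory)
        g.create_dataset("pre", data=network.pre)
        g.create_dataset("post", data=network.post)
        g.create_dataset("weight", data=network.weight)
        if network.config is not None:
            g.attrs["config_json"] = json.dumps(network.config.to_dict())
        proj = network.input_projection
        if proj is not None:
            gi = f.create_group("input_projection")
            gi.attrs["n_channels"] = proj.n_channels
            gi.attrs["mode"] = proj.mode
            gi.create_dataset("channel", data=proj.channel)
            gi.create_dataset("post", data=proj.post)
            gi.create_dataset("weight", data=proj.weight)
        gs = f.create_group("state")
        if weights is not None:
            gs.create_dataset("weights", data=np.asarray(weights))
        if calcium is not None:
            gs.create_dataset("calcium", data=np.asarray(calcium))
        if records:
            gr = f.create_group("records")
            for name, rec in records.items():
                gg = gr.create_group(str(name))
                gg.create_dataset("neuron_ids", data=rec.neuron_ids)
                gg.create_dataset("times", data=rec.times)
                gg.attrs["duration"] = rec.duration
                gg.attrs["dt"] = rec.dt
                gg.attrs["n_neurons"] = rec.n_neurons
                gg.attrs["t_start"] = rec.t_start


def load_state(path, expect_shape: Optional[tuple] = None):
    """Round-trip partner of :func:`save_state`.

    Returns ``(network, state_dict)`` where ``state_dict`` holds
    ``weights``, ``calcium`` and ``records`` when present.  Raises on
    format-version mismatch or on a network shape different from
    ``expect_shape``.
    """
    from .dynamics import SpikeRecord

    with h5py.File(path, "r") as f:
        if int(f.attrs.get("format_version", -1)) != _FORMAT_VERSION:
            raise ValueError("unsupported state-container version")
        g = f["network"]
        config = None
        if "config_json" in g.attrs:
            config = NetworkConfig.from_dict(json.loads(g.attrs["config_json"]))
        net = Network(positions=g["positions"][...],
                      is_excitatory=g["is_excitatory"][...],
                      pre=g["pre"][...], post=g["post"][...],
                      weight=g["weight"][...], config=config)
        if expect_shape is not None and config is not None and \
                tuple(config.dims) != tuple(expect_shape):
            raise ValueError(
                f"state container holds a {tuple(config.dims)} network, "
                f"expected {tuple(expect_shape)}")
        if "input_projection" in f:
            gi = f["input_projection"]
            net.input_projection = InputProjection(
                n_channels=int(gi.attrs["n_channels"]),
                channel=gi["channel"][...], post=gi["post"][...],
                weight=gi["weight"][...], mode=str(gi.attrs["mode"]))
        state: Dict = {}
        gs = f["state"]
        for key in ("weights", "calcium"):
            if key in gs:
                state[key] = gs[key][...]
        if "records" in f:
            recs = {}
            for name, gg in f["records"].items():
                recs[name] = SpikeRecord(
                    neuron_ids=gg["neuron_ids"][...], times=gg["times"][...],
                    duration=float(gg.attrs["duration"]),
                    dt=float(gg.attrs["dt"]),
                    n_neurons=int(gg.attrs["n_neurons"]),
                    t_start=float(gg.attrs["t_start"]))
            state["records"] = recs
    return net, state


@dataclass
class RunManifest:
    """Reproducibility record for one run directory."""

    config: dict
    seeds: Dict[str, int]
    outputs: list = field(default_factory=list)
    version: str = __version__
    created: str = field(default_factory=lambda: _dt.datetime.now().isoformat())

    def save(self, run_dir) -> Path:
        run_dir = Path(run_dir)
        run_dir.mkdir(parents=True, exist_ok=True)
        path = run_dir / "manifest.json"
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2))
        return path

    @classmethod
    def load(cls, run_dir) -> "RunManifest":
        data = json.loads((Path(run_dir) / "manifest.json").read_text())
        return cls(**data)
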