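"""Run configuration, manifests and file-format glue.

YAML configs are validated into :class:`antlobe.engine.SimConfig`; every
run writes a manifest (config hash, seeds, package version) sufficient to
regenerate its outputs bit-exactly.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, asdict
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from . import network as net
from . import stimulus as stim
from .engine import SimConfig

log = logging.getLogger("antlobe")


class ConfigError(ValueError):
    """A configuration file failed validation."""


_DEFAULTS = {
    "variant": "I",
    "wiring_seed": 7,
    "master_seed": 0,
    "n_trials": 80,
    "duration": 10000.0,
    "dt": 0.01,
    "background": True,
    "input_gain": stim.INPUT_GAIN,
    "tau_in": stim.TAU_IN,
    "scale_ln_ln_gaba": False,
    "lfp_every": 10,
    "record_v": False,
    "rec_every": 10,
}


def config_from_dict(d: dict) -> SimConfig:
    """Build a validated SimConfig; unknown keys are rejected, defaults
    fill everything omitted."""
    d = dict(d or {})
    odor = d.pop("odor", None)
    fields = dict(_DEFAULTS)
    for key, val in d.items():
        if key not in fields:
            raise ConfigError(f"unknown config field {key!r}")
        fields[key] = val
    if not isinstance(fields["n_trials"], int) or fields["n_trials"] < 0:
        raise ConfigError("n_trials: must be a non-negative integer")
    if fields["dt"] <= 0:
        raise ConfigError("dt: must be positive")
    try:
        variant = net.get_variant(fields["variant"])
    except ValueError as e:
        raise ConfigError(str(e)) from None
    if odor is not None:
        if isinstance(odor, dict):
            if "overlap_seed" in odor:
                raise ConfigError("odor: use make_odor_pair for pairs")
            odor = (stim.make_odor(odor["seed"]) if "pn_indices" not in odor
                    else stim.odor_from_dict(odor))
        elif isinstance(odor, int):
            odor = stim.make_odor(odor)
    del variant
    cfg = SimConfig(odor=odor, **fields)
    for key, val in d.items():
        if val != _DEFAULTS.get(key):
            log.info("config override: %s = %r", key, val)
    return cfg


def load_config(path) -> SimConfig:
    try:
        d = yaml.safe_load(Path(path).read_text())
    except yaml.YAMLError as e:
        raise ConfigError(f"cannot parse {path}: {e}") from None
    return config_from_dict(d or {})


def config_to_dict(cfg: SimConfig) -> dict:
    d = {k: getattr(cfg, k) for k in _DEFAULTS}
    if cfg.odor is not None:
        d["odor"] = stim.odor_to_dict(cfg.odor)
    return d


def save_config(cfg: SimConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config_to_dict(cfg)))


# -------------------------------------------------------------- manifests

@dataclass
class RunManifest:
    """Provenance of one simulation run."""

    config_hash: str
    wiring_seed: int
    master_seed: int
    variant: str
    odor: dict | None
    code_version: str
    created: str

    @classmethod
    def for_config(cls, cfg: SimConfig) -> "RunManifest":
        blob = json.dumps(_jsonable(config_to_dict(cfg)), sort_keys=True)
        return cls(
            config_hash=hashlib.sha256(blob.encode()).hexdigest()[:16],
            wiring_seed=cfg.wiring_seed,
            master_seed=cfg.master_seed,
            variant=cfg.variant,
            odor=stim.odor_to_dict(cfg.odor) if cfg.odor is not None else None,
            code_version=__version__,
            created=datetime.now(timezone.utc).isoformat(timespec="seconds"),
        )

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def load(cls, path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))


def _jsonable(x):
    if isinstance(x, dict):
        return {k: _jsonable(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_jsonable(v) for v in x]
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    return x
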