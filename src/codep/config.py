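"""Configuration loading with schema validation and provenance tracking.

A run configuration is a flat YAML mapping with dot-namespaced keys
(``neuron.tau_m``, ``esp.A_LTP``, ``isp.alpha``, ``network.n_exc``,
``run.seed`` ...).  The schema is derived from the parameter dataclasses,
so every tunable has exactly one home.  Unknown keys are rejected with a
message naming the key; defaulted parameters are recorded so a run
manifest can state which values were user-supplied.

A few parameter defaults are literature-stated reference values (the
weight bounds, the Mg-block constants, the pathway input statistics);
all others are package choices.  ``provenance()`` reports which is
which, and every run manifest records which keys were user-supplied.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from .neurons import NeuronParams
from .plasticity import ESPParams, ISPParams

__all__ = ["RunConfig", "load_config", "config_hash", "dump_config"]

# parameters whose defaults are literature-stated reference values;
# everything else is a documented package choice
_TEXT_STATED = {
    "esp.w_max", "esp.w_min", "isp.w_max", "isp.w_min",
    "neuron.a_NMDA", "neuron.b_NMDA",
    "stimuli.p_star", "stimuli.p_bg_exc", "stimuli.p_bg_inh",
}

_RUN_DEFAULTS = {
    "protocol": "feedforward-stability",
    "seed": 0,
    "dt": 0.1,
    "T": 10_000.0,
    "out": "results",
    "scaled": True,
}

_STIMULI_DEFAULTS = {
    "p_star": 0.025,
    "tau_OU": 50.0,
    "p_bg_exc": 2e-4,
    "p_bg_inh": 4e-4,
    "tau_ref_exc": 5.0,
    "tau_ref_inh": 2.5,
}

_NETWORK_DEFAULTS = {
    "n_exc": 200, "n_inh": 50,
    "p_EE": 0.2, "p_EI": 0.2, "p_IE": 0.2, "p_II": 0.2,
    "w_EE_init": 0.1, "w_EI": 0.4, "w_IE_init": 0.5, "w_II": 1.0,
    "w_ext": 1.5,
}


def _dataclass_defaults(cls) -> dict:
    out = {}
    for f in dataclasses.fields(cls):
        if f.default is not dataclasses.MISSING:
            out[f.name] = f.default
        elif f.default_factory is not dataclasses.MISSING:  # type: ignore
            out[f.name] = f.default_factory()  # type: ignore
    return out


def _schema() -> dict:
    schema: dict[str, Any] = {}
    for ns, cls in (("neuron", NeuronParams), ("esp", ESPParams),
                    ("isp", ISPParams)):
        for name, default in _dataclass_defaults(cls).items():
            schema[f"{ns}.{name}"] = default
    for ns, table in (("run", _RUN_DEFAULTS), ("stimuli", _STIMULI_DEFAULTS),
                      ("network", _NETWORK_DEFAULTS)):
        for name, default in table.items():
            schema[f"{ns}.{name}"] = default
    return schema


class RunConfig:
    """Validated flat configuration with provenance of every default."""

    def __init__(self, values: dict | None = None):
        schema = _schema()
        values = dict(values or {})
        unknown = sorted(set(values) - set(schema))
        if unknown:
            raise KeyError(
                f"unknown configuration key(s): {', '.join(unknown)}; "
                "run 'codep validate --schema' for the accepted keys")
        self._values = dict(schema)
        self._values.update(values)
        self.user_keys = sorted(values)
        self.defaulted_keys = sorted(set(schema) - set(values))

    def __getitem__(self, key: str):
        return self._values[key]

    def get(self, key: str, default=None):
        return self._values.get(key, default)

    def namespace(self, ns: str) -> dict:
        prefix = ns + "."
        return {k[len(prefix):]: v for k, v in self._values.items()
                if k.startswith(prefix)}

    def neuron_params(self) -> NeuronParams:
        return NeuronParams(**self.namespace("neuron"))

    def esp_params(self) -> ESPParams:
        return ESPParams(**self.namespace("esp"))

    def isp_params(self) -> ISPParams:
        return ISPParams(**self.namespace("isp"))

    def provenance(self) -> dict:
        """Per-key origin: user | package-default | reference-default."""
        out = {}
        for k in self._values:
            if k in self.user_keys:
                out[k] = "user"
            elif k in _TEXT_STATED:
                out[k] = "reference-default"
            else:
                out[k] = "package-default"
        return out

    def as_dict(self) -> dict:
        return dict(self._values)


def load_config(path) -> RunConfig:
    """Load and validate a YAML configuration file (may be empty)."""
    path = Path(path)
    raw = yaml.safe_load(path.read_text()) if path.exists() else None
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: configuration must be a mapping")
    # allow nested namespaces as well as flat dotted keys
    flat: dict[str, Any] = {}
    for k, v in raw.items():
        if isinstance(v, dict):
            for k2, v2 in v.items():
                flat[f"{k}.{k2}"] = v2
        else:
            flat[k] = v
    return RunConfig(flat)


def dump_config(config: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config.as_dict(), sort_keys=True))


def _jsonable(v):
    if isinstance(v, (np.floating, np.integer)):
        return v.item()
    if isinstance(v, float) and np.isinf(v):
        return "inf"
    return v


def config_hash(config) -> str:
    """Deterministic short hash of a configuration mapping."""
    d = config.as_dict() if isinstance(config, RunConfig) else dict(config)
    blob = json.dumps({k: _jsonable(v) for k, v in sorted(d.items())},
                      sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]
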