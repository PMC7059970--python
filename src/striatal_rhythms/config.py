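"""Plain-text (YAML) round trip of run configurations.

A run configuration bundles the network specification, dopamine condition,
integration settings, noise specification and cell parameters.  Field
names match the dataclass fields; units follow the package convention
(mV, ms, uA/cm^2, mS/cm^2).
"""

from __future__ import annotations

import dataclasses

import yaml

from .cells import FSIParams, SPNParams
from .engine import IntegrationSettings, NoiseSpec
from .network import NetworkSpec, SynapseParams, DACondition, dopamine_condition

__all__ = ["save_config", "load_config", "config_to_dict", "config_from_dict"]

_SECTIONS = {
    "network": NetworkSpec,
    "settings": IntegrationSettings,
    "noise": NoiseSpec,
    "fsi": FSIParams,
    "spn": SPNParams,
    "synapse": SynapseParams,
}


def config_to_dict(*, network=None, condition=None, settings=None,
                   noise=None, fsi=None, spn=None, synapse=None) -> dict:
    out = {}
    objs = {"network": network, "settings": settings, "noise": noise,
            "fsi": fsi, "spn": spn, "synapse": synapse}
    for name, obj in objs.items():
        if obj is not None:
            out[name] = dataclasses.asdict(obj)
    if condition is not None:
        if isinstance(condition, DACondition):
            out["condition"] = dataclasses.asdict(condition)
        else:
            out["condition"] = {"label": str(condition)}
    return out


def config_from_dict(data: dict) -> dict:
    """Inverse of `config_to_dict`; unknown sections raise."""
    out = {}
    for name, section in data.items():
        if name == "condition":
            label = section.pop("label")
            out["condition"] = dopamine_condition(label, **section)
        elif name in _SECTIONS:
            out[name] = _SECTIONS[name](**section)
        else:
            raise KeyError(f"unknown config section {name!r}")
    return out


def save_config(path, **objects) -> None:
    with open(path, "w") as fh:
        fh.write("# striatal-rhythms run configuration\n"
                 "# units: mV, ms, uA/cm^2, mS/cm^2; rates in events/s\n")
        yaml.safe_dump(config_to_dict(**objects), fh, sort_keys=True)


def load_config(path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return config_from_dict(data)
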