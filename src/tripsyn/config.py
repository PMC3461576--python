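"""Configuration loading: YAML/TOML documents -> typed model objects.

A config document mirrors the dataclass structure, e.g.::

    diffusion: {D: 0.4, delta: 0.02, Q: 3000}
    geometry: {r_psd: 0.1, r_astro: 0.4, r_receptor: 0.1}
    eaat2: {density: 13000, coverage: 0.5}
    eaat3: null                      # omit or null to disable
    ampar: {nb_ampa: 80, rate_overrides: {"C2->D2": 0.5}}
    nmdar: {nb_nmda: 20, mg_out: 1.0}
    v_hold: -70.0

Unknown keys raise immediately; every kinetic rate constant is overridable
through the per-receptor ``rate_overrides`` mapping keyed ``"FROM->TO"``.
"""

from __future__ import annotations

from dataclasses import fields as dc_fields
from pathlib import Path

import yaml

from .ampar import AMPARParams
from .cleft import CleftGeometry, DiffusionParams
from .neuron import NeuronConfig
from .nmdar import NMDARParams
from .synapse import SynapseConfig
from .transporters import EAAT2Params, EAAT3Params

__all__ = ["load_config", "synapse_config_from_dict", "neuron_config_from_dict"]

_SECTION_TYPES = {
    "diffusion": DiffusionParams,
    "geometry": CleftGeometry,
    "eaat2": EAAT2Params,
    "eaat3": EAAT3Params,
    "ampar": AMPARParams,
    "nmdar": NMDARParams,
}


def _build(cls, data: dict):
    valid = {f.name for f in dc_fields(cls)}
    unknown = set(data) - valid
    if unknown:
        raise KeyError(f"unknown keys for {cls.__name__}: {sorted(unknown)}")
    data = dict(data)
    if "annulus" in data and data["annulus"] is not None:
        data["annulus"] = tuple(data["annulus"])
    return cls(**data)


def synapse_config_from_dict(doc: dict) -> SynapseConfig:
    """Build a :class:`SynapseConfig` from a plain (YAML-loaded) mapping."""
    doc = dict(doc or {})
    kwargs = {}
    for key, cls in _SECTION_TYPES.items():
        if key in doc:
            section = doc.pop(key)
            if section is None:
                kwargs[key] = None
            elif section in (True, "on"):
                kwargs[key] = cls()
            elif section in (False, "off"):
                kwargs[key] = None
            else:
                kwargs[key] = _build(cls, section)
    scalar_fields = {f.name for f in dc_fields(SynapseConfig)}
    unknown = set(doc) - scalar_fields
    if unknown:
        raise KeyError(f"unknown synapse config keys: {sorted(unknown)}")
    kwargs.update(doc)
    return SynapseConfig(**kwargs)


def neuron_config_from_dict(doc: dict) -> NeuronConfig:
    """Build a :class:`NeuronConfig` from a plain mapping."""
    return _build(NeuronConfig, dict(doc or {}))


def load_config(path) -> SynapseConfig:
    """Load a YAML config file into a :class:`SynapseConfig`.

    A top-level ``synapse:`` section is accepted (and any ``neuron:``
    section ignored here); otherwise the document itself is the synapse
    config.
    """
    doc = yaml.safe_load(Path(path).read_text()) or {}
    if "synapse" in doc:
        doc = doc["synapse"] or {}
    return synapse_config_from_dict(doc)
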