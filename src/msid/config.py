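"""Plain-text configuration loading.

Kinetic parameters are readable from YAML (or simple ``key: value`` lines,
which are a YAML subset), either as explicit rate constants or as a named
benchmark case::

    # explicit
    k1f: 10.0
    k1b: 100.0
    k2: 1.0
    e0: 0.5

    # or by name
    case: case1

Pipeline configurations load from YAML with optional ``node``, ``jacobian``,
``csp`` and ``sindy`` sub-sections mapping onto the corresponding dataclass
fields.
"""

from __future__ import annotations

from dataclasses import fields as dc_fields
from pathlib import Path

import yaml

from .jacobian import JacobianNetConfig
from .kinetics import KineticParameters, case_parameters, derive_constants
from .node import NodeConfig
from .pipeline import CSPSettings, PipelineConfig, SindySettings
from .simulate import NoiseSpec

__all__ = ["load_kinetic_parameters", "load_pipeline_config"]


def _read(path) -> dict:
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"configuration {path} did not parse to a mapping")
    return data


def load_kinetic_parameters(path) -> KineticParameters:
    """Kinetic parameters from a YAML / key:value file."""
    data = _read(path)
    if "case" in data:
        return case_parameters(str(data["case"]))
    try:
        return derive_constants(float(data["k1f"]), float(data["k1b"]),
                                float(data["k2"]), float(data["e0"]))
    except KeyError as exc:
        raise ValueError(f"missing rate constant {exc} in {path}") from None


def _build(cls, data: dict):
    names = {f.name for f in dc_fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} fields: {sorted(unknown)}")
    return cls(**data)


def load_pipeline_config(path) -> PipelineConfig:
    """Full pipeline configuration from YAML."""
    data = _read(path)
    kw = dict(data)
    for key, cls in (("node", NodeConfig), ("jacobian", JacobianNetConfig),
                     ("csp", CSPSettings), ("sindy", SindySettings),
                     ("noise", NoiseSpec)):
        if key in kw and isinstance(kw[key], dict):
            kw[key] = _build(cls, kw[key])
    return _build(PipelineConfig, kw)
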