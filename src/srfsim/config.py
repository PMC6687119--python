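"""Structured-text configuration, serialisation and run manifests.

Configs are YAML documents with sections ``[cell]``, ``[conditions]``,
``[srf]``, ``[protocol]`` and ``[tissue]``.  Every CLI run writes a
manifest (config hash, seed, package version) next to its outputs so a
result can always be traced back to its inputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import yaml

from .cell0d import CellParams
from .sampling import DWFitParams, GeneralDynamicParams, SRFDistribution
from .spatial import ClampProtocol, SpatialParams

log = logging.getLogger("srfsim")

__all__ = [
    "load_config",
    "save_config",
    "distribution_from_dict",
    "distribution_to_dict",
    "general_dynamic_from_dict",
    "cell_params_from_config",
    "spatial_params_from_config",
    "write_manifest",
]


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"config root must be a mapping: {path}")
    return cfg


def save_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


def _from_dict(cls, d: dict):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(d) - names
    if unknown:
        raise KeyError(f"unknown {cls.__name__} fields: {sorted(unknown)}")
    return cls(**d)


def distribution_from_dict(d: dict) -> SRFDistribution:
    d = dict(d)
    if "dw_params" in d and isinstance(d["dw_params"], dict):
        d["dw_params"] = _from_dict(DWFitParams, d["dw_params"])
    return _from_dict(SRFDistribution, d)


def distribution_to_dict(d: SRFDistribution) -> dict:
    out = dataclasses.asdict(d)
    if out.get("dw_params") is None:
        out.pop("dw_params", None)
    return out


def general_dynamic_from_dict(d: dict) -> GeneralDynamicParams:
    return _from_dict(GeneralDynamicParams, d)


def cell_params_from_config(cfg: dict) -> CellParams:
    d = dict(cfg.get("cell", {}))
    for flag, value in cfg.get("conditions", {}).items():
        d[flag] = bool(value)
    return _from_dict(CellParams, d)


def spatial_params_from_config(cfg: dict) -> SpatialParams:
    d = dict(cfg.get("spatial", {}))
    if "dims" in d:
        d["dims"] = tuple(d["dims"])
    for flag, value in cfg.get("conditions", {}).items():
        if flag in ("r_cru_cru", "r_serca_ncx"):
            d[flag] = bool(value)
    return _from_dict(SpatialParams, d)


def clamp_protocol_from_config(cfg: dict) -> ClampProtocol:
    d = dict(cfg.get("protocol", {}))
    if "casr_steps" in d:
        d["casr_steps"] = tuple(d["casr_steps"])
    return _from_dict(ClampProtocol, d)


def write_manifest(outdir, seed: int, config: dict | None = None,
                   extra: dict | None = None) -> Path:
    from . import __version__

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    blob = yaml.safe_dump(config or {}, sort_keys=True).encode()
    manifest = {
        "srfsim_version": __version__,
        "seed": int(seed),
        "config_sha256": hashlib.sha256(blob).hexdigest(),
    }
    manifest.update(extra or {})
    path = outdir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1)
    log.info("manifest written to %s", path)
    return path
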