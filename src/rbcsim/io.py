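"""Configuration loading, HDF5/CSV output and run provenance."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import yaml

from .mie import ScatteringMatrixCurve

__all__ = [
    "load_config",
    "config_hash",
    "provenance",
    "save_mm_h5",
    "load_mm_h5",
]

from . import __version__ as _version


def load_config(path) -> dict:
    """Read a YAML or JSON configuration file into a dict."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must define a mapping")
    return cfg


def config_hash(cfg: dict) -> str:
    """Stable short hash of a configuration mapping."""
    canon = json.dumps(cfg, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def provenance(cfg: dict | None = None, seed: int | None = None, **extra) -> dict:
    meta = {"rbcsim_version": _version}
    if cfg is not None:
        meta["config_hash"] = config_hash(cfg)
    if seed is not None:
        meta["seed"] = int(seed)
    meta.update(extra)
    return meta


def save_mm_h5(path, curve: ScatteringMatrixCurve, meta: dict | None = None) -> None:
    """Write an angle-resolved Mueller curve: /mm/raw, /mm/normalized, /meta."""
    norm = curve.normalized()
    with h5py.File(path, "w") as f:
        f.create_dataset("angles", data=np.asarray(curve.angles))
        f.create_dataset("mm/raw", data=np.asarray(curve.mm))
        f.create_dataset("mm/normalized", data=np.asarray(norm.mm))
        grp = f.create_group("meta")
        for key, val in (meta or {}).items():
            grp.attrs[key] = json.dumps(val) if isinstance(val, (dict, list, tuple)) else val


def load_mm_h5(path) -> tuple[ScatteringMatrixCurve, dict]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"Mueller-matrix file not found: {path}")
    with h5py.File(path, "r") as f:
        curve = ScatteringMatrixCurve(
            angles=f["angles"][...], mm=f["mm/raw"][...], normalization="raw"
        )
        meta = dict(f["meta"].attrs) if "meta" in f else {}
    return curve, meta
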