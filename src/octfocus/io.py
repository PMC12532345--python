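"""Reading and writing B-scan stacks and configuration files."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import tifffile
import yaml

from .simulator import BScan, OUParams, SystemParams

__all__ = [
    "write_stack",
    "read_stack",
    "load_config",
    "system_params_from_config",
    "ou_params_from_config",
]


def write_stack(path, stack) -> None:
    """Write B-scans as a multi-page TIFF (``.tif``/``.tiff``) or a 3D
    ``.npy`` array (frames x depth x lateral), float32."""
    path = Path(path)
    frames = [b.intensity if isinstance(b, BScan) else np.asarray(b) for b in stack]
    data = np.stack(frames).astype(np.float32)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, data)
    elif path.suffix.lower() == ".npy":
        np.save(path, data)
    else:
        raise ValueError(f"unsupported stack format: {path.suffix}")


def read_stack(path) -> list:
    """Read a multi-page TIFF or 3D ``.npy`` stack into a list of BScan."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        data = tifffile.imread(path)
    elif path.suffix.lower() == ".npy":
        data = np.load(path)
    else:
        raise ValueError(f"unsupported stack format: {path.suffix}")
    if data.ndim == 2:
        data = data[None]
    return [BScan(intensity=frame.astype(float)) for frame in data]


def load_config(path) -> dict:
    """Load a YAML (or JSON; YAML is a superset) configuration file."""
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def system_params_from_config(config: dict) -> SystemParams:
    """Build SystemParams from a config dict's ``system`` section (missing
    fields keep their defaults)."""
    return SystemParams(**config.get("system", {}))


def ou_params_from_config(config: dict, key: str) -> OUParams:
    """Build OUParams from e.g. the ``ou_motion`` / ``ou_defocus``
    sections."""
    if key not in config:
        raise KeyError(f"config has no '{key}' section")
    return OUParams(**config[key])
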