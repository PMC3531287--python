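"""Shared I/O: volume reading/writing, config files, output metadata.

Volumes are multi-page TIFF stacks or directories of equally sized PNG/TIFF
slices in lexicographic z-order (z index 0 = mound base).  RGB slices are
converted to 8-bit grayscale on read.  CSV outputs carry a single leading
comment line embedding the package version, seed and effective-config hash,
so equal (config, seed) runs produce byte-identical files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import tifffile
import yaml
from PIL import Image

from . import __version__
from .imaging import IntensityVolume, to_grayscale

__all__ = [
    "read_volume",
    "write_volume",
    "load_config",
    "config_hash",
    "write_csv",
    "write_truth_json",
]

_SLICE_SUFFIXES = {".png", ".tif", ".tiff"}


def _as_gray(arr: np.ndarray, source: str) -> np.ndarray:
    if arr.ndim == 3 and arr.shape[-1] in (3, 4):
        return to_grayscale(arr[..., :3])
    if arr.ndim != 2:
        raise ValueError(f"{source}: expected a 2D (or RGB) slice, got shape {arr.shape}")
    if arr.dtype == np.uint8:
        return arr
    if np.issubdtype(arr.dtype, np.integer) and arr.max(initial=0) <= 255 and arr.min(initial=0) >= 0:
        return arr.astype(np.uint8)
    raise ValueError(f"{source}: unsupported bit depth {arr.dtype} (8-bit expected)")


def read_volume(
    path: str | Path, pixel_um: float = 3.3, slice_um: float = 3.3
) -> IntensityVolume:
    """Load an intensity volume from a TIFF stack or a slice directory."""
    path = Path(path)
    if path.is_dir():
        files = sorted(
            p for p in path.iterdir() if p.suffix.lower() in _SLICE_SUFFIXES
        )
        if not files:
            raise FileNotFoundError(f"no PNG/TIFF slices found in {path}")
        slices = []
        shape = None
        for f in files:
            arr = _as_gray(np.asarray(Image.open(f)), f.name)
            if shape is None:
                shape = arr.shape
            elif arr.shape != shape:
                raise ValueError(
                    f"slice {f.name} has shape {arr.shape}, expected {shape}"
                )
            slices.append(arr)
        data = np.stack(slices)
    else:
        data = np.asarray(tifffile.imread(path))
        if data.ndim == 2:
            data = data[None]
        if data.ndim == 4:  # multi-page RGB
            data = np.stack([_as_gray(p, str(path)) for p in data])
        data = np.stack([_as_gray(p, str(path)) for p in data])
    return IntensityVolume(data, pixel_um=pixel_um, slice_um=slice_um)


def write_volume(volume: IntensityVolume, path: str | Path) -> None:
    """Write a volume as an uncompressed multi-page 8-bit TIFF."""
    tifffile.imwrite(Path(path), volume.data.astype(np.uint8))


def load_config(
    path: str | Path | None,
    cls,
    overrides: Mapping[str, Any] | None = None,
):
    """Build a config dataclass from a YAML file plus flag overrides.

    Unknown keys are rejected with the offending name; explicit overrides
    (CLI flags) win over file values.  An empty/missing file yields all
    defaults.
    """
    values: dict[str, Any] = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        values.update(loaded)
    if overrides:
        values.update({k: v for k, v in overrides.items() if v is not None})
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(values) - valid
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "discs" in values and values["discs"] is not None:
        values["discs"] = tuple(
            ((float(c[0]), float(c[1])), float(r)) for c, r in values["discs"]
        )
    return cls(**values)


def config_hash(config: Any) -> str:
    """Stable short hash of a config dataclass (or mapping)."""
    if dataclasses.is_dataclass(config) and not isinstance(config, type):
        payload = dataclasses.asdict(config)
    else:
        payload = dict(config)
    text = json.dumps(payload, sort_keys=True, default=str)
    return hashlib.sha256(text.encode()).hexdigest()[:12]


def write_csv(
    df: pd.DataFrame, path: str | Path, seed: int, config: Any, float_format: str = "%.10g"
) -> None:
    """Write a CSV with a metadata comment line (version, seed, config hash)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = f"# myxofruit={__version__} seed={seed} config_sha={config_hash(config)}\n"
    with open(path, "w") as fh:
        fh.write(meta)
        df.to_csv(fh, index=False, float_format=float_format)


def write_truth_json(truth: Any, path: str | Path) -> None:
    """Serialize a generator truth record (dataclass) to JSON."""
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        raise TypeError(f"cannot serialize {type(o)}")

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if dataclasses.is_dataclass(truth) and not isinstance(truth, type):
        truth = dataclasses.asdict(truth)
    path.write_text(json.dumps(truth, indent=2, default=default))
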