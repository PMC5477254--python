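"""TIFF and config I/O.

Images and label volumes travel as multi-page TIFFs (pages = z-planes,
optionally a 4th time axis).  Configuration is YAML with a flat, documented
schema; unknown keys are rejected so typos fail loudly.
"""

from __future__ import annotations

import os
from typing import Union

import numpy as np
import tifffile
import yaml

from .types import ImageStack4D, LabelVolume, RunConfig

__all__ = [
    "read_stack",
    "write_stack",
    "read_labels",
    "write_labels",
    "load_config",
]

_CONFIG_KEYS = {
    "stage1_grid",
    "stage2_grid",
    "volume_ratio_min",
    "spacing",
    "time_interval",
    "seed",
    "physical_distance",
}


def _read_array(path: Union[str, os.PathLike], axis_order: str) -> np.ndarray:
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    arr = tifffile.imread(str(path))
    if arr.ndim == 2:
        arr = arr[np.newaxis]
    if arr.ndim == 3:
        arr = arr[np.newaxis]
    if arr.ndim != 4:
        raise ValueError(f"{path}: expected 2–4 dims, got {arr.ndim}")
    if axis_order != "tzyx":
        order = tuple("tzyx".index(a) for a in axis_order)
        arr = np.transpose(arr, np.argsort(order))
    return arr


def read_stack(
    path: Union[str, os.PathLike],
    axis_order: str = "tzyx",
    spacing: tuple[float, float, float] = (0.5, 1.0, 1.0),
    time_interval: float = 15.0,
) -> ImageStack4D:
    """Read a multi-page TIFF as an intensity stack in (t, z, y, x) order.

    A 3D file is promoted to a single-time-point stack; a 2D file to a
    single-plane, single-time-point stack.
    """
    arr = _read_array(path, axis_order)
    if not np.issubdtype(arr.dtype, np.number):
        raise ValueError(f"{path}: non-numeric pixel type {arr.dtype}")
    return ImageStack4D(arr.astype(np.float64), spacing=spacing,
                        time_interval=time_interval)


def write_stack(stack: ImageStack4D, path: Union[str, os.PathLike]) -> None:
    """Write an intensity stack as a float32 multi-page TIFF."""
    tifffile.imwrite(str(path), stack.values.astype(np.float32),
                     photometric="minisblack")


def read_labels(path: Union[str, os.PathLike], axis_order: str = "tzyx") -> LabelVolume:
    """Read an integer label volume from a multi-page TIFF."""
    arr = _read_array(path, axis_order)
    if not np.issubdtype(arr.dtype, np.integer):
        raise ValueError(f"{path}: label TIFF must be integer-typed, got {arr.dtype}")
    return LabelVolume(arr.astype(np.int64))


def write_labels(labels: LabelVolume, path: Union[str, os.PathLike]) -> None:
    """Write labels losslessly; 16-bit container, widened to 32-bit when needed."""
    vmax = int(labels.values.max(initial=0))
    dtype = np.uint16 if vmax <= np.iinfo(np.uint16).max else np.uint32
    tifffile.imwrite(str(path), labels.values.astype(dtype),
                     photometric="minisblack")


def load_config(path: Union[str, os.PathLike]) -> RunConfig:
    """Parse a YAML run configuration, filling documented defaults.

    Schema (all keys optional)::

        stage1_grid: {gaussian_sigma: [...], c: [...], b: [...],
                      n_iter: [...], depth_adjust_strength: [...]}
        stage2_grid: {alpha: [...], avg_filter_size: [...]}
        volume_ratio_min: 0.95
        spacing: [dz, dy, dx]      # micrometres
        time_interval: 15.0        # seconds
        seed: 0
        physical_distance: false
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    unknown = set(raw) - _CONFIG_KEYS
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    if "spacing" in raw:
        raw["spacing"] = tuple(raw["spacing"])
    return RunConfig(**raw)
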