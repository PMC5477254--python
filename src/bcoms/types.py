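"""Core containers shared by every stage of the pipeline.

All volumetric data follows one axis convention: ``(t, z, y, x)``, 0-based,
with ``z = 0`` the bottom (deepest) focal plane.  Physical voxel spacing is
carried as ``(dz, dy, dx)`` in micrometres and lives in the container, not in
TIFF tags, because spacing tags are unreliable across writers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "ImageStack4D",
    "LabelVolume",
    "RunConfig",
    "BcomsError",
    "SegmentationError",
]


class BcomsError(Exception):
    """Base class for errors raised by this package."""


class SegmentationError(BcomsError):
    """A segmentation stage failed on its input (e.g. vanished contour)."""


def _as_4d(values: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(values)
    if arr.ndim == 3:  # single time point
        arr = arr[np.newaxis]
    if arr.ndim != 4:
        raise ValueError(f"{name} must be 3D or 4D (t, z, y, x); got ndim={arr.ndim}")
    if any(s < 1 for s in arr.shape):
        raise ValueError(f"{name} has an empty axis: shape={arr.shape}")
    return arr


@dataclass
class ImageStack4D:
    """A 3D time-lapse fluorescence stack.

    Parameters
    ----------
    values : ndarray, shape (t, z, y, x)
        Non-negative, finite intensities.  A 3D array is promoted to a
        single-time-point stack.
    spacing : tuple of float
        Physical voxel spacing ``(dz, dy, dx)`` in micrometres.
    time_interval : float
        Seconds between consecutive time points.
    """

    values: np.ndarray
    spacing: tuple[float, float, float] = (0.5, 1.0, 1.0)
    time_interval: float = 15.0

    def __post_init__(self) -> None:
        self.values = _as_4d(self.values, "ImageStack4D.values").astype(
            np.float64, copy=False
        )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("intensities must be finite")
        if self.values.min() < 0:
            raise ValueError("intensities must be >= 0")
        self.spacing = tuple(float(s) for s in self.spacing)  # type: ignore[assignment]
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive floats; got {self.spacing}")
        if self.time_interval <= 0:
            raise ValueError("time_interval must be > 0")

    @property
    def shape(self) -> tuple[int, int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]


@dataclass
class LabelVolume:
    """Integer cell/seed labels on the ``(t, z, y, x)`` grid.

    Label 0 is reserved for background (or membrane lines in a cell
    segmentation).  ``label_table`` optionally maps each integer label to a
    persistent cell identity (a string stable across time points and, at a
    scripted division, extended with a child suffix).
    """

    values: np.ndarray
    label_table: Optional[dict[int, str]] = None

    def __post_init__(self) -> None:
        self.values = _as_4d(self.values, "LabelVolume.values")
        if not np.issubdtype(self.values.dtype, np.integer):
            raise ValueError("labels must be integers")
        if self.values.min() < 0:
            raise ValueError("labels must be >= 0")
        if self.label_table is None:
            self.label_table = {
                int(l): str(int(l)) for l in np.unique(self.values) if l != 0
            }

    @property
    def shape(self) -> tuple[int, int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def labels_at(self, t: int) -> np.ndarray:
        labs = np.unique(self.values[t])
        return labs[labs > 0]

    def identity_of(self, label: int) -> str:
        assert self.label_table is not None
        return self.label_table.get(int(label), str(int(label)))


@dataclass
class RunConfig:
    """Everything a full optimisation run needs besides the images.

    ``stage1_grid`` / ``stage2_grid`` map axis names to ordered value lists;
    the Cartesian product of each is searched exhaustively.  The single
    biological threshold exposed to users is ``volume_ratio_min``: the
    smallest admissible ratio of minimum to maximum embryo volume across the
    recording (the embryo neither grows nor shrinks appreciably during early
    development, so a correct whole-embryo segmentation keeps this near 1).
    """

    stage1_grid: dict[str, list] = field(
        default_factory=lambda: {
            "gaussian_sigma": [1.0],
            "c": [1.0, 4.0, 16.0],
            "b": [1.0],
            "n_iter": [40],
            "depth_adjust_strength": [0.0, 1.0],
        }
    )
    stage2_grid: dict[str, list] = field(
        default_factory=lambda: {"alpha": [0.0, 1.0, 3.0], "avg_filter_size": [1, 3]}
    )
    volume_ratio_min: float = 0.95
    spacing: tuple[float, float, float] = (0.5, 1.0, 1.0)
    time_interval: float = 15.0
    seed: int = 0
    physical_distance: bool = False
    """If True, the seed distance transform uses physical spacing (alpha is
    then intensity per micrometre); if False, voxel units."""

    def __post_init__(self) -> None:
        for name, grid in (("stage1_grid", self.stage1_grid),
                           ("stage2_grid", self.stage2_grid)):
            if not grid:
                raise ValueError(f"{name} must have at least one axis")
            for axis, vals in grid.items():
                if not isinstance(vals, (list, tuple)) or len(vals) == 0:
                    raise ValueError(f"{name} axis {axis!r} is empty")
        if not (0 < self.volume_ratio_min <= 1):
            raise ValueError("volume_ratio_min must be in (0, 1]")
        self.spacing = tuple(float(s) for s in self.spacing)  # type: ignore[assignment]
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing components must be > 0")
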