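"""Per-cell 3D shape features.

The 13 core features per cell per time point:

=============== ==============================================================
Volume          voxel count x dz*dy*dx
PerimeterXY     sum over z-planes of the 2D cross-section boundary length
                (4-connected boundary-segment count, scaled by in-plane
                spacing); PerimeterYZ / PerimeterZX analogous along x / y
CentroidX/Y/Z   mean voxel-centre coordinate, physical units, image frame
Width/Height/   bounding-box extent along x / y / z
Depth
SurfaceArea     triangulated isosurface (marching cubes at 0.5 on the padded,
                lightly smoothed binary mask)
Convexity       Volume / convex-hull Volume (solidity), on voxelized hulls
Sphericity      pi^(1/3) * (6 V)^(2/3) / SurfaceArea
=============== ==============================================================

An optional extended set (equivalent diameter, bounding-box volume, extent,
principal-axis lengths, elongation, flatness, compactness, surface-to-volume
ratio, convex surface area, max Feret diameter) brings the table toward the
25 features commonly used for cell morphometry; these are a documented
convention of this package, not a fixed external standard.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist
from skimage.measure import marching_cubes, mesh_surface_area
from skimage.morphology import convex_hull_image

from .types import LabelVolume

__all__ = ["CORE_FEATURES", "EXTENDED_FEATURES", "compute_features",
           "features_over_time"]

CORE_FEATURES = [
    "Volume", "PerimeterXY", "PerimeterYZ", "PerimeterZX",
    "CentroidX", "CentroidY", "CentroidZ",
    "Width", "Height", "Depth",
    "SurfaceArea", "Convexity", "Sphericity",
]

EXTENDED_FEATURES = [
    "EquivalentDiameter", "BoundingBoxVolume", "Extent",
    "MajorAxisLength", "IntermediateAxisLength", "MinorAxisLength",
    "Elongation", "Flatness", "Compactness", "SurfaceToVolumeRatio",
    "ConvexSurfaceArea", "MaxFeretDiameter",
]

SMALL_CELL_VOXELS = 8


def _transitions(mask: np.ndarray, axis: int) -> int:
    """Count foreground/background face transitions along an axis,
    including transitions against the array border."""
    pad = [(0, 0)] * mask.ndim
    pad[axis] = (1, 1)
    padded = np.pad(mask, pad)
    return int(np.abs(np.diff(padded.astype(np.int8), axis=axis)).sum())


def _perimeters(mask: np.ndarray, spacing) -> tuple[float, float, float]:
    dz, dy, dx = spacing
    # cross-sections at fixed z, boundary segments in the (y, x) plane:
    # an exposed face perpendicular to x has length dy and vice versa
    per_xy = _transitions(mask, 2) * dy + _transitions(mask, 1) * dx
    # fixed x, (z, y) plane
    per_yz = _transitions(mask, 0) * dy + _transitions(mask, 1) * dz
    # fixed y, (z, x) plane
    per_zx = _transitions(mask, 0) * dx + _transitions(mask, 2) * dz
    return float(per_xy), float(per_yz), float(per_zx)


_MESH_SIGMA = 0.7  # voxels; tames digitization staircase before meshing


def _surface_area(mask: np.ndarray, spacing) -> float:
    """Triangulated isosurface area of a binary mask.

    The mask is padded and lightly Gaussian-smoothed before marching cubes:
    meshing the raw staircase overestimates the area of smooth (cell-like)
    surfaces by 6-10%, while the smoothed isosurface is accurate to ~1% for
    a digitized ball of radius >= 12.  Small polyhedra with flat axis-
    aligned faces are conversely underestimated; cells are smooth, so the
    smooth-surface regime is the one this estimator is tuned for.
    """
    padded = np.pad(mask, 3).astype(np.float64)
    smoothed = ndimage.gaussian_filter(padded, _MESH_SIGMA)
    verts, faces, _, _ = marching_cubes(smoothed, level=0.5, spacing=tuple(spacing))
    return float(mesh_surface_area(verts, faces))


def _cell_features(mask: np.ndarray, spacing, extended: bool) -> dict:
    dz, dy, dx = spacing
    zz, yy, xx = np.nonzero(mask)
    n_vox = len(zz)
    voxel_vol = dz * dy * dx
    volume = n_vox * voxel_vol
    z0, z1 = int(zz.min()), int(zz.max())
    y0, y1 = int(yy.min()), int(yy.max())
    x0, x1 = int(xx.min()), int(xx.max())
    sub = mask[z0:z1 + 1, y0:y1 + 1, x0:x1 + 1]
    per_xy, per_yz, per_zx = _perimeters(sub, spacing)
    try:
        area = _surface_area(sub, spacing)
    except (ValueError, RuntimeError):
        area = np.nan
    try:
        hull_vox = int(convex_hull_image(np.pad(sub, 1), offset_coordinates=False).sum())
        convexity = n_vox / hull_vox if hull_vox > 0 else np.nan
    except (QhullError, ValueError):
        hull_vox = None
        convexity = np.nan
    sphericity = (
        np.pi ** (1 / 3) * (6 * volume) ** (2 / 3) / area if area and area > 0 else np.nan
    )
    feats = {
        "Volume": volume,
        "PerimeterXY": per_xy,
        "PerimeterYZ": per_yz,
        "PerimeterZX": per_zx,
        "CentroidX": float(xx.mean()) * dx,
        "CentroidY": float(yy.mean()) * dy,
        "CentroidZ": float(zz.mean()) * dz,
        "Width": (x1 - x0 + 1) * dx,
        "Height": (y1 - y0 + 1) * dy,
        "Depth": (z1 - z0 + 1) * dz,
        "SurfaceArea": area,
        "Convexity": convexity,
        "Sphericity": sphericity,
    }
    if extended:
        feats.update(_extended_features(sub, spacing, feats, hull_vox))
    feats["small_cell_flag"] = n_vox < SMALL_CELL_VOXELS
    return feats


def _extended_features(sub, spacing, feats, hull_vox) -> dict:
    dz, dy, dx = spacing
    voxel_vol = dz * dy * dx
    v, a = feats["Volume"], feats["SurfaceArea"]
    bbv = feats["Width"] * feats["Height"] * feats["Depth"]
    zz, yy, xx = np.nonzero(sub)
    pts = np.column_stack([zz * dz, yy * dy, xx * dx])
    out = {
        "EquivalentDiameter": (6 * v / np.pi) ** (1 / 3),
        "BoundingBoxVolume": bbv,
        "Extent": v / bbv,
        "Compactness": 36 * np.pi * v**2 / a**3 if a and a > 0 else np.nan,
        "SurfaceToVolumeRatio": a / v if v > 0 else np.nan,
        "ConvexSurfaceArea": np.nan,
        "MaxFeretDiameter": np.nan,
        "MajorAxisLength": np.nan,
        "IntermediateAxisLength": np.nan,
        "MinorAxisLength": np.nan,
        "Elongation": np.nan,
        "Flatness": np.nan,
    }
    if len(pts) >= 2:
        cov = np.cov(pts.T)
        eig = np.sort(np.linalg.eigvalsh(np.atleast_2d(cov)))[::-1]
        eig = np.clip(eig, 0, None)
        lengths = 4.0 * np.sqrt(eig)  # ellipsoid-equivalent axis lengths
        out["MajorAxisLength"], out["IntermediateAxisLength"], out["MinorAxisLength"] = (
            float(lengths[0]), float(lengths[1]), float(lengths[2])
        )
        if lengths[0] > 0:
            out["Elongation"] = float(lengths[1] / lengths[0])
        if lengths[1] > 0:
            out["Flatness"] = float(lengths[2] / lengths[1])
    try:
        hull_img = convex_hull_image(np.pad(sub, 1), offset_coordinates=False)
        out["ConvexSurfaceArea"] = _surface_area(hull_img, spacing)
        hull = ConvexHull(pts) if len(pts) >= 4 else None
        if hull is not None:
            vpts = pts[hull.vertices]
            out["MaxFeretDiameter"] = float(pdist(vpts).max())
    except (QhullError, ValueError, RuntimeError):
        pass
    return out


def compute_features(
    cells: LabelVolume,
    spacing: tuple[float, float, float],
    extended: bool = False,
) -> pd.DataFrame:
    """Feature table with one row per (time point, cell label).

    Cells with fewer than 8 voxels are flagged (``small_cell_flag``) because
    hull and mesh estimates are unstable there; their features are still
    emitted.  Units follow ``spacing`` (micrometres when spacing is
    physical, voxels when spacing is (1, 1, 1)).
    """
    if any(s <= 0 for s in spacing):
        raise ValueError("spacing components must be > 0")
    rows = []
    for t in range(cells.shape[0]):
        for lab in cells.labels_at(t):
            mask = cells.values[t] == lab
            row = {"t": t, "label": int(lab),
                   "identity": cells.identity_of(int(lab))}
            row.update(_cell_features(mask, spacing, extended))
            rows.append(row)
    if not rows:
        raise ValueError("label volume contains no cells")
    return pd.DataFrame(rows)


def features_over_time(
    cells: LabelVolume,
    spacing: tuple[float, float, float],
    extended: bool = False,
) -> pd.DataFrame:
    """Feature table keyed by persistent cell identity.

    Adds a ``gap_flag`` row (features NaN) for every time point at which an
    identity disappears between its first and last appearance, so missing
    cells are visible rather than silently dropped.  At a scripted division
    the parent identity simply ends and two child identities begin.
    """
    df = compute_features(cells, spacing, extended=extended)
    dup = df.duplicated(subset=["t", "identity"], keep=False)
    if dup.any():
        bad = df.loc[dup, ["t", "identity"]].drop_duplicates()
        raise ValueError(f"identity collision: {bad.to_dict('records')}")
    df["gap_flag"] = False
    gap_rows = []
    for ident, grp in df.groupby("identity"):
        ts = sorted(grp["t"])
        missing = set(range(ts[0], ts[-1] + 1)) - set(ts)
        for t in sorted(missing):
            gap_rows.append({"t": t, "identity": ident, "label": -1,
                             "gap_flag": True})
    if gap_rows:
        df = pd.concat([df, pd.DataFrame(gap_rows)], ignore_index=True)
    return df.sort_values(["identity", "t"]).reset_index(drop=True)
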