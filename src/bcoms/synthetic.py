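"""Synthetic multi-cell embryo phantoms with microscopy-like degradations.

The generator emulates what a spinning-disk confocal recording of an early
*C. elegans*-like embryo looks like to a segmentation pipeline:

* a roughly ellipsoidal embryo whose interior is partitioned into cells;
* bright thin membrane shells on cell–cell interfaces and on the embryo
  surface, over a dimmer cytoplasm and a dark background;
* image quality falling off with focal depth (scattering/absorption) and
  with time (photobleaching), plus additive detector noise;
* membrane stretches lying parallel to the focal planes imaged
  discontinuously — modelled as contiguous gaps punched into membrane
  surfaces whose normal is close to the z axis.

Ground-truth cells are nearest-centre (Voronoi) regions clipped to the
ellipsoid, so the truth partition is voxel-exact, space-filling and
analytically controlled by a single set of points.  Seed "nuclei" are small
balls around the centres, labelled consistently over time so lineage
identity is the label.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage

from .types import ImageStack4D, LabelVolume

__all__ = ["SyntheticEmbryoSpec", "generate_embryo", "degrade"]


@dataclass
class SyntheticEmbryoSpec:
    """Parameters of one synthetic recording.

    Intensities are in arbitrary camera counts; the three levels must be
    ordered ``membrane_peak > cytoplasm_level > background_level >= 0``.
    ``depth_attenuation`` multiplies each plane by
    ``depth_attenuation ** (z_max - z)`` (z = 0 is the deepest plane) and
    ``bleach_rate`` multiplies time point ``t`` by ``bleach_rate ** t``.
    ``gap_fraction`` is the fraction of membrane voxels on near-horizontal
    surfaces (normal within ``gap_angle_deg`` of the z axis) deleted in
    contiguous patches.
    """

    shape: tuple[int, int, int, int] = (5, 24, 64, 64)
    semi_axes: tuple[float, float, float] = (10.0, 27.0, 29.0)  # (z, y, x) voxels
    n_cells: int = 7
    membrane_thickness: float = 1.0
    membrane_peak: float = 120.0
    cytoplasm_level: float = 25.0
    background_level: float = 4.0
    depth_attenuation: float = 0.97
    bleach_rate: float = 0.98
    noise_sd: float = 2.0
    gap_fraction: float = 0.4
    gap_angle_deg: float = 30.0
    gap_patch_radius: int = 2
    """Chebyshev radius of each contiguous deleted membrane patch."""
    rng_seed: int = 0
    divisions: tuple[tuple[int, int], ...] = ()
    """Scripted splits: (time point, parent label). From that time point on
    the parent's centre is replaced by two offset child centres."""
    spacing: tuple[float, float, float] = (0.5, 1.0, 1.0)
    time_interval: float = 15.0
    min_center_separation: Optional[float] = None
    centers: Optional[tuple[tuple[float, float, float], ...]] = None
    """Explicit cell centres in (z, y, x) voxel coordinates.  When given they
    replace random sampling (``n_cells`` must match), which makes interface
    orientations scriptable for controlled experiments."""

    def __post_init__(self) -> None:
        if len(self.shape) != 4 or any(s < 1 for s in self.shape):
            raise ValueError("shape must be 4 positive extents (t, z, y, x)")
        if not (self.membrane_peak > self.cytoplasm_level > self.background_level >= 0):
            raise ValueError(
                "require membrane_peak > cytoplasm_level > background_level >= 0"
            )
        for name in ("depth_attenuation", "bleach_rate"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must be in (0, 1]")
        if not (0 <= self.gap_fraction < 1):
            raise ValueError("gap_fraction must be in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.membrane_thickness < 1:
            raise ValueError("membrane_thickness must be >= 1 voxel")
        rz, ry, rx = self.semi_axes
        _, nz, ny, nx = self.shape
        if rz > (nz - 1) / 2 or ry > (ny - 1) / 2 or rx > (nx - 1) / 2:
            raise ValueError("ellipsoid larger than grid")


def _ellipsoid_norm(shape3d, semi_axes):
    nz, ny, nx = shape3d
    cz, cy, cx = (nz - 1) / 2, (ny - 1) / 2, (nx - 1) / 2
    z, y, x = np.ogrid[:nz, :ny, :nx]
    rz, ry, rx = semi_axes
    return np.sqrt(
        ((z - cz) / rz) ** 2 + ((y - cy) / ry) ** 2 + ((x - cx) / rx) ** 2
    ), (cz, cy, cx)


def _sample_centers(spec: SyntheticEmbryoSpec, rng: np.random.Generator) -> np.ndarray:
    """Rejection-sample ``n_cells`` centres inside the scaled ellipsoid."""
    rz, ry, rx = spec.semi_axes
    volume = 4 / 3 * np.pi * rz * ry * rx
    equiv_diam = 2 * (3 * volume / (4 * np.pi * spec.n_cells)) ** (1 / 3)
    d_min = (
        spec.min_center_separation
        if spec.min_center_separation is not None
        else 0.7 * equiv_diam
    )
    _, nz, ny, nx = spec.shape
    center = np.array([(nz - 1) / 2, (ny - 1) / 2, (nx - 1) / 2])
    semi = np.array([rz, ry, rx])
    for _ in range(200):  # restarts
        pts: list[np.ndarray] = []
        for _ in range(5000):
            u = rng.uniform(-0.75, 0.75, size=3)
            if np.sum((u / 0.75) ** 2) > 1:
                continue
            p = center + u * semi
            if all(np.linalg.norm(p - q) >= d_min for q in pts):
                pts.append(p)
            if len(pts) == spec.n_cells:
                return np.array(pts)
    raise ValueError("cells too numerous to separate at the requested spacing")


def _apply_divisions(
    centers: np.ndarray,
    labels: list[int],
    identities: dict[int, str],
    spec: SyntheticEmbryoSpec,
    rng: np.random.Generator,
):
    """Per-time-point (centers, labels) honouring scripted divisions."""
    epochs = []  # (t_start, centers, labels)
    cur_centers = centers.copy()
    cur_labels = list(labels)
    epochs.append((0, cur_centers.copy(), list(cur_labels)))
    next_label = max(labels) + 1
    for t_div, parent in sorted(spec.divisions):
        if parent not in cur_labels:
            raise ValueError(f"division parent label {parent} not alive at t={t_div}")
        i = cur_labels.index(parent)
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        delta = 0.18 * min(spec.semi_axes) * direction
        c = cur_centers[i]
        cur_centers = np.delete(cur_centers, i, axis=0)
        del cur_labels[i]
        for suffix, sign in (("a", 1.0), ("b", -1.0)):
            identities[next_label] = identities[parent] + suffix
            cur_centers = np.vstack([cur_centers, c + sign * delta])
            cur_labels.append(next_label)
            next_label += 1
        epochs.append((int(t_div), cur_centers.copy(), list(cur_labels)))
    return epochs


def _voronoi_truth(shape3d, inside, centers, labels):
    nz, ny, nx = shape3d
    z, y, x = np.meshgrid(
        np.arange(nz), np.arange(ny), np.arange(nx), indexing="ij"
    )
    best = np.full(shape3d, np.inf)
    second = np.full(shape3d, np.inf)
    lab = np.zeros(shape3d, dtype=np.int32)
    nearest_idx = np.zeros(shape3d, dtype=np.int32)
    second_idx = np.zeros(shape3d, dtype=np.int32)
    for i, (c, l) in enumerate(zip(centers, labels)):
        d = np.sqrt((z - c[0]) ** 2 + (y - c[1]) ** 2 + (x - c[2]) ** 2)
        closer = d < best
        second = np.where(closer, best, np.minimum(second, d))
        second_idx = np.where(closer, nearest_idx, second_idx)
        between = (~closer) & (d < second)
        second_idx = np.where(between, i, second_idx)
        best = np.where(closer, d, best)
        nearest_idx = np.where(closer, i, nearest_idx)
        lab = np.where(closer, l, lab)
    lab = np.where(inside, lab, 0)
    return lab, nearest_idx, second_idx


def _interface_voxels(truth3d):
    """Voxels whose 6-neighbourhood crosses a label change (incl. outside)."""
    b = np.zeros(truth3d.shape, dtype=bool)
    inside = truth3d > 0
    for ax in range(3):
        for shift in (1, -1):
            rolled = np.roll(truth3d, shift, axis=ax)
            diff = rolled != truth3d
            # rolled wraps around; treat wrapped face as outside (label 0)
            sl = [slice(None)] * 3
            sl[ax] = 0 if shift == 1 else -1
            diff[tuple(sl)] = truth3d[tuple(sl)] != 0
            b |= diff & inside
    return b


def _membrane_mask(truth3d, thickness):
    b = _interface_voxels(truth3d)
    if thickness <= 1:
        return b
    dist = ndimage.distance_transform_edt(~b)
    return dist < thickness


def _horizontal_candidates(spec, truth3d, membrane, centers, nearest_idx, second_idx):
    """Membrane voxels whose local surface normal is near the z axis."""
    inside = truth3d > 0
    outside_adjacent = _interface_to_outside(truth3d)
    norm_grad = _ellipsoid_gradient(spec)
    cos_lim = np.cos(np.deg2rad(spec.gap_angle_deg))
    zz, yy, xx = np.nonzero(membrane)
    normal = np.empty((len(zz), 3))
    # interface voxels: normal along the line joining the two nearest centres
    ni = nearest_idx[zz, yy, xx]
    si = second_idx[zz, yy, xx]
    normal = centers[si] - centers[ni]
    # surface voxels: ellipsoid gradient
    surf = outside_adjacent[zz, yy, xx]
    if surf.any():
        normal[surf] = norm_grad[:, zz[surf], yy[surf], xx[surf]].T
    mag = np.linalg.norm(normal, axis=1)
    mag[mag == 0] = 1.0
    cosz = np.abs(normal[:, 0]) / mag
    keep = cosz >= cos_lim
    mask = np.zeros(truth3d.shape, dtype=bool)
    mask[zz[keep], yy[keep], xx[keep]] = True
    return mask


def _interface_to_outside(truth3d):
    inside = truth3d > 0
    eroded = ndimage.binary_erosion(
        inside, structure=ndimage.generate_binary_structure(3, 1), border_value=0
    )
    return inside & ~eroded


def _ellipsoid_gradient(spec):
    _, nz, ny, nx = spec.shape
    rz, ry, rx = spec.semi_axes
    cz, cy, cx = (nz - 1) / 2, (ny - 1) / 2, (nx - 1) / 2
    z, y, x = np.meshgrid(np.arange(nz), np.arange(ny), np.arange(nx), indexing="ij")
    return np.stack(
        [(z - cz) / rz**2, (y - cy) / ry**2, (x - cx) / rx**2]
    )


def _punch_gaps(membrane, candidates, gap_fraction, rng, patch_radius=2):
    """Delete contiguous patches of candidate membrane voxels.

    Patches (Chebyshev radius 2 around random candidate voxels) emulate
    stretches of membrane imaged discontinuously, rather than salt-and-pepper
    dropout which an averaging filter would simply close.
    """
    coords = np.argwhere(candidates)
    if len(coords) == 0 or gap_fraction == 0:
        return np.zeros(membrane.shape, dtype=bool)
    target = int(round(gap_fraction * len(coords)))
    order = rng.permutation(len(coords))
    deleted = np.zeros(membrane.shape, dtype=bool)
    n_deleted = 0
    for idx in order:
        if n_deleted >= target:
            break
        z, y, x = coords[idx]
        if deleted[z, y, x]:
            continue
        cheb = np.max(np.abs(coords - coords[idx]), axis=1) <= patch_radius
        patch = coords[cheb]
        newly = ~deleted[patch[:, 0], patch[:, 1], patch[:, 2]]
        deleted[patch[:, 0], patch[:, 1], patch[:, 2]] = True
        n_deleted += int(newly.sum())
    return deleted


def _seed_balls(truth3d, centers, labels):
    seeds = np.zeros(truth3d.shape, dtype=np.int32)
    zz, yy, xx = np.meshgrid(
        np.arange(truth3d.shape[0]),
        np.arange(truth3d.shape[1]),
        np.arange(truth3d.shape[2]),
        indexing="ij",
    )
    for c, l in zip(centers, labels):
        region = truth3d == l
        inradius = ndimage.distance_transform_edt(region)[
            int(round(c[0])), int(round(c[1])), int(round(c[2]))
        ]
        r = max(1.0, inradius / 3.0)
        ball = (zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2 <= r**2
        seeds[ball & region] = l
    return seeds


def degrade(stack: ImageStack4D, spec: SyntheticEmbryoSpec) -> ImageStack4D:
    """Apply depth attenuation, photobleaching, then noise; clip at zero.

    Order is fixed and documented: multiplicative attenuation first (depth
    then time commute), additive Gaussian noise second, clipping last.
    """
    t_n, z_n = stack.shape[0], stack.shape[1]
    if stack.shape != tuple(spec.shape):
        raise ValueError(f"stack shape {stack.shape} != spec shape {spec.shape}")
    z = np.arange(z_n)
    depth = spec.depth_attenuation ** (z_n - 1 - z)
    bleach = spec.bleach_rate ** np.arange(t_n)
    out = stack.values * depth[None, :, None, None] * bleach[:, None, None, None]
    if spec.noise_sd > 0:
        rng = np.random.default_rng([spec.rng_seed, 3])
        out = out + rng.normal(0.0, spec.noise_sd, size=out.shape)
    out = np.clip(out, 0.0, None)
    return ImageStack4D(out, spacing=spec.spacing, time_interval=spec.time_interval)


def generate_embryo(
    spec: SyntheticEmbryoSpec,
) -> tuple[ImageStack4D, LabelVolume, LabelVolume]:
    """Generate (membrane image, seed nuclei, ground-truth cells).

    Returns
    -------
    membrane : ImageStack4D
        Degraded membrane-channel recording.
    seeds : LabelVolume
        Small balls around each cell centre, labels matching the truth.
    truth : LabelVolume
        Voxel-exact cell partition of the embryo interior (0 outside).
    """
    rng_centers = np.random.default_rng([spec.rng_seed, 1])
    rng_gaps = np.random.default_rng([spec.rng_seed, 2])
    t_n, nz, ny, nx = spec.shape
    shape3d = (nz, ny, nx)
    norm, _ = _ellipsoid_norm(shape3d, spec.semi_axes)
    inside = norm <= 1.0

    if spec.centers is not None:
        if len(spec.centers) != spec.n_cells:
            raise ValueError("len(centers) must equal n_cells")
        centers0 = np.asarray(spec.centers, dtype=float)
    else:
        centers0 = _sample_centers(spec, rng_centers)
    labels0 = list(range(1, spec.n_cells + 1))
    identities = {l: f"c{l}" for l in labels0}
    epochs = _apply_divisions(centers0, labels0, identities, spec, rng_centers)

    truth = np.zeros(spec.shape, dtype=np.int32)
    seeds = np.zeros(spec.shape, dtype=np.int32)
    clean = np.zeros(spec.shape, dtype=np.float64)

    for ei, (t_start, centers, labels) in enumerate(epochs):
        t_end = epochs[ei + 1][0] if ei + 1 < len(epochs) else t_n
        if t_start >= t_n or t_start >= t_end:
            continue
        truth3d, nearest_idx, second_idx = _voronoi_truth(
            shape3d, inside, centers, labels
        )
        membrane = _membrane_mask(truth3d, spec.membrane_thickness)
        cand = _horizontal_candidates(
            spec, truth3d, membrane, centers, nearest_idx, second_idx
        )
        gaps = _punch_gaps(membrane, cand, spec.gap_fraction, rng_gaps,
                           spec.gap_patch_radius)
        img = np.full(shape3d, spec.background_level)
        img[inside] = spec.cytoplasm_level
        img[membrane & ~gaps] = spec.membrane_peak
        seeds3d = _seed_balls(truth3d, centers, labels)
        for t in range(t_start, t_end):
            truth[t] = truth3d
            seeds[t] = seeds3d
            clean[t] = img

    membrane_stack = degrade(
        ImageStack4D(clean, spacing=spec.spacing, time_interval=spec.time_interval),
        spec,
    )
    table = dict(identities)
    return (
        membrane_stack,
        LabelVolume(seeds, label_table=dict(table)),
        LabelVolume(truth.astype(np.int32), label_table=dict(table)),
    )
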