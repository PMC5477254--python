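"""Stage 1: whole-embryo segmentation by a region-based active contour.

The embryonic region is segmented per time point with a two-phase
piecewise-constant (Chan–Vese-type) evolution implemented morphologically,
so the result is deterministic.  The curve-length (smoothing/contraction)
weight is brightness-adaptive::

    cb(t) = c * vars(t) ** b

where ``vars(t)`` is the population variance of the intensities enclosed by
the initial embryonic region at time ``t``.  Dimmer stacks (deeper bleaching)
have smaller variance and therefore receive a weaker contraction bias; with
``b = 1`` the whole evolution is invariant to a global intensity rescaling,
which is exactly the property needed to survive photobleaching.

The stage exposes the selection objective (mean membrane intensity under the
per-plane embryo edge) and the two biological constraints (all seed nuclei
enclosed; near-constant embryo volume over time) used by the optimizer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .types import ImageStack4D, LabelVolume, SegmentationError

__all__ = [
    "LevelSetParams",
    "EmbryoStageResult",
    "initial_region",
    "depth_adjust",
    "contraction_bias",
    "segment_embryo",
    "extract_edges",
    "objective_embryo",
    "constraint_nuclei_enclosed",
    "constraint_volume_stability",
]

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)
_CROSS_2D = ndimage.generate_binary_structure(2, 1)


@dataclass
class LevelSetParams:
    """Tunable parameters of the embryo-region stage (the stage-1 grid axes)."""

    gaussian_sigma: float = 1.0
    c: float = 1.0          # contraction-bias coefficient
    b: float = 1.0          # contraction-bias exponent on the variance
    n_iter: int = 40
    depth_adjust_strength: float = 1.0

    def __post_init__(self) -> None:
        if self.gaussian_sigma < 0:
            raise ValueError("gaussian_sigma must be >= 0")
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")
        if self.c < 0:
            raise ValueError("c must be >= 0")
        if not (0 <= self.depth_adjust_strength <= 1):
            raise ValueError("depth_adjust_strength must be in [0, 1]")


@dataclass
class EmbryoStageResult:
    mask: np.ndarray     # bool (t, z, y, x) — S_emb
    edge: np.ndarray     # bool (t, z, y, x) — S_edge
    volumes: np.ndarray  # voxel count per time point
    v_min: int
    v_max: int


def initial_region(membrane: ImageStack4D) -> np.ndarray:
    """Initial 3D embryo region from the temporally summed stack.

    Sums the 4D stack over time, keeps voxels strictly above the mean of the
    summed stack, and retains only the largest 26-connected component.
    """
    summed = membrane.values.sum(axis=0)
    mask = summed > summed.mean()
    if not mask.any():
        raise SegmentationError("initial region is empty (constant image?)")
    labels, n = ndimage.label(mask, structure=_STRUCT_26)
    if n > 1:
        counts = np.bincount(labels.ravel())
        counts[0] = 0
        mask = labels == counts.argmax()
    return mask


def _plane_means(vol: np.ndarray, init: np.ndarray) -> tuple[np.ndarray, float]:
    """Per-plane in-contour means and their unweighted average.

    Planes whose in-contour cross-section is empty get NaN and are excluded
    from the average.
    """
    nz = vol.shape[0]
    mu = np.full(nz, np.nan)
    for z in range(nz):
        sel = init[z]
        if sel.any():
            mu[z] = vol[z][sel].mean()
    if np.all(np.isnan(mu)):
        raise SegmentationError("initial region empty on every plane")
    return mu, float(np.nanmean(mu))


def _depth_adjust_3d(vol: np.ndarray, init: np.ndarray, strength: float) -> np.ndarray:
    if strength == 0:
        return vol
    mu, mu_bar = _plane_means(vol, init)
    out = vol.copy()
    for z in range(vol.shape[0]):
        if np.isnan(mu[z]):
            continue
        if mu[z] == 0:
            raise SegmentationError(
                f"zero in-contour mean on nonempty plane z={z}; cannot depth-adjust"
            )
        out[z] = vol[z] * (mu_bar / mu[z]) ** strength
    return out


def depth_adjust(
    membrane: ImageStack4D, init: np.ndarray, strength: float
) -> ImageStack4D:
    """Equalize per-plane brightness inside the initial contour.

    Each plane ``z`` is multiplied by ``(mu_bar / mu_z) ** strength`` where
    ``mu_z`` is the mean intensity inside the initial contour on that plane
    and ``mu_bar`` the unweighted average of the per-plane means.  At
    ``strength = 0`` this is the identity; at 1, plane means are equalized
    (and a second application is a no-op).
    """
    out = np.stack(
        [_depth_adjust_3d(membrane.values[t], init, strength)
         for t in range(membrane.n_timepoints)]
    )
    return ImageStack4D(out, spacing=membrane.spacing,
                        time_interval=membrane.time_interval)


def contraction_bias(
    membrane_t: np.ndarray, init: np.ndarray, c: float, b: float
) -> float:
    """Brightness-adaptive curve-length weight ``c * vars(t) ** b``.

    ``vars(t)`` is the *population* variance of the intensities enclosed by
    the initial embryonic region.  ``b = 0`` returns ``c`` for any image.
    """
    if not init.any():
        raise ValueError("initial region is empty")
    if b == 0:
        return float(c)
    vars_t = float(np.var(membrane_t[init]))
    return float(c * vars_t**b)


def _evolve_3d(
    adjusted: np.ndarray, init: np.ndarray, cb: float, n_iter: int
) -> np.ndarray:
    """Morphological two-phase piecewise-constant contour evolution.

    Per iteration: compute the two phase means, then flip only voxels in the
    one-voxel boundary band according to the sign of

        F = (I - c_in)^2 - (I - c_out)^2 + cb * (1 - 2 * box_mean(u))

    The last term is a discrete curvature/contraction force: positive on
    locally convex foreground boundary, so a larger ``cb`` smooths and
    shrinks the contour.
    """
    u = init.copy()
    for _ in range(n_iter):
        if not u.any():
            raise SegmentationError("contour vanished during evolution")
        c_in = adjusted[u].mean()
        c_out = adjusted[~u].mean() if (~u).any() else c_in
        curv = 1.0 - 2.0 * ndimage.uniform_filter(u.astype(np.float64), size=3)
        f = (adjusted - c_in) ** 2 - (adjusted - c_out) ** 2 + cb * curv
        band = ndimage.binary_dilation(u, _STRUCT_26) & ~ndimage.binary_erosion(
            u, _STRUCT_26, border_value=0
        )
        grow = band & (f < 0)
        shrink = band & (f > 0)
        u = u.copy()
        u[grow] = True
        u[shrink] = False
    if not u.any():
        raise SegmentationError("contour vanished during evolution")
    u = ndimage.binary_fill_holes(u)
    labels, n = ndimage.label(u, structure=_STRUCT_26)
    if n > 1:
        counts = np.bincount(labels.ravel())
        counts[0] = 0
        u = labels == counts.argmax()
    return u


def segment_embryo(
    membrane: ImageStack4D, init: np.ndarray, params: LevelSetParams
) -> EmbryoStageResult:
    """Segment the embryonic region at every time point.

    Per time point: Gaussian smoothing, per-plane depth adjustment, then the
    morphological two-phase evolution from ``init`` with the curve-length
    weight ``contraction_bias(t)``.  Each time point starts from the same
    initial region, so time points are independent; the volume-stability
    constraint couples them only at evaluation.
    """
    t_n = membrane.n_timepoints
    masks = np.zeros(membrane.shape, dtype=bool)
    for t in range(t_n):
        raw = membrane.values[t]
        a = ndimage.gaussian_filter(raw, params.gaussian_sigma) \
            if params.gaussian_sigma > 0 else raw
        a = _depth_adjust_3d(a, init, params.depth_adjust_strength)
        cb = contraction_bias(raw, init, params.c, params.b)
        masks[t] = _evolve_3d(a, init, cb, params.n_iter)
    edges = extract_edges(masks)
    volumes = masks.reshape(t_n, -1).sum(axis=1)
    return EmbryoStageResult(
        mask=masks,
        edge=edges,
        volumes=volumes,
        v_min=int(volumes.min()),
        v_max=int(volumes.max()),
    )


def extract_edges(mask: np.ndarray) -> np.ndarray:
    """Per-focal-plane inner boundary of a 4D (or 3D) binary mask.

    On each (t, z) plane, a voxel is edge iff it is in the mask and at least
    one of its 4 planar neighbours (or the image frame) is outside.  Vertical
    neighbours are never consulted: the edge is a per-plane contour.
    """
    squeeze = mask.ndim == 3
    m = mask[np.newaxis] if squeeze else mask
    edge = np.zeros_like(m, dtype=bool)
    for t in range(m.shape[0]):
        for z in range(m.shape[1]):
            plane = m[t, z]
            if not plane.any():
                continue
            eroded = ndimage.binary_erosion(plane, _CROSS_2D, border_value=0)
            edge[t, z] = plane & ~eroded
    return edge[0] if squeeze else edge


def objective_embryo(membrane: ImageStack4D, edge: np.ndarray) -> float:
    """Mean membrane intensity over the embryo-edge voxels (to maximize)."""
    if not edge.any():
        raise ValueError("edge mask is empty")
    return float(membrane.values[edge].mean())


def constraint_nuclei_enclosed(seeds: LabelVolume, mask: np.ndarray) -> bool:
    """True iff no seed voxel falls outside the embryo mask (equality
    constraint: the count of excluded seed voxels must be exactly zero)."""
    if seeds.shape != mask.shape:
        raise ValueError("seed and mask shapes differ")
    return not bool(np.any((seeds.values > 0) & ~mask))


def constraint_volume_stability(volumes, ratio_min: float) -> bool:
    """True iff min(volume) / max(volume) >= ratio_min over time."""
    v = np.asarray(volumes, dtype=np.float64)
    if v.size == 0:
        raise ValueError("empty volume series")
    if np.any(v <= 0):
        raise ValueError("embryo volume vanished at some time point")
    return bool(v.min() / v.max() >= ratio_min)
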