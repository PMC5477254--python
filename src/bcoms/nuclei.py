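"""Nuclei segmentation: DoG blob detection to produce watershed seeds.

Per time point, the nuclei channel is band-pass filtered with a 3D
difference of Gaussians, thresholded adaptively at ``mean + k * sd`` of the
response, and split into 26-connected components; components below a size
threshold are dropped.  Labels are linked across time by maximal voxel
overlap so a nucleus keeps its label until it splits.

Users who already have curated seeds can bypass this module entirely and
feed a seed label volume straight to the pipeline — the nuclei channel is
only ever used to produce seeds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .types import ImageStack4D, LabelVolume, SegmentationError

__all__ = ["NucleiParams", "segment_nuclei", "validate_seeds"]

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class NucleiParams:
    dog_sigma_small: float = 1.5
    dog_sigma_large: float = 4.0
    threshold_k: float = 2.0     # threshold = mean + k * sd of the DoG response
    min_size: int = 27           # voxels

    def __post_init__(self) -> None:
        if not (0 < self.dog_sigma_small < self.dog_sigma_large):
            raise ValueError("require 0 < dog_sigma_small < dog_sigma_large")
        if self.min_size < 1:
            raise ValueError("min_size must be >= 1")


def _segment_3d(vol: np.ndarray, params: NucleiParams) -> np.ndarray:
    dog = ndimage.gaussian_filter(vol, params.dog_sigma_small) - ndimage.gaussian_filter(
        vol, params.dog_sigma_large
    )
    thr = dog.mean() + params.threshold_k * dog.std()
    fg = dog > thr
    labels, n = ndimage.label(fg, structure=_STRUCT_26)
    if n == 0:
        raise SegmentationError("zero components after thresholding")
    counts = np.bincount(labels.ravel())
    keep = np.flatnonzero(counts >= params.min_size)
    keep = keep[keep > 0]
    if len(keep) == 0:
        raise SegmentationError("zero components after size filtering")
    out = np.zeros_like(labels)
    for new, old in enumerate(keep, start=1):
        out[labels == old] = new
    return out


def _link_by_overlap(prev: np.ndarray, cur: np.ndarray, next_label: int):
    """Relabel ``cur`` so maximally overlapping components keep their label.

    Ties broken by larger overlap fraction (of the current component), then
    by smaller previous label.  Unmatched components get fresh labels.
    """
    out = np.zeros_like(cur)
    cur_labels = [int(l) for l in np.unique(cur) if l > 0]
    used_prev: set[int] = set()
    cands = []
    for cl in cur_labels:
        sel = cur == cl
        size = int(sel.sum())
        over = np.bincount(prev[sel].ravel())
        for pl in np.flatnonzero(over):
            if pl == 0:
                continue
            cands.append((int(over[pl]), over[pl] / size, -int(pl), cl, int(pl)))
    assigned: dict[int, int] = {}
    for ov, frac, negpl, cl, pl in sorted(cands, reverse=True):
        if cl in assigned or pl in used_prev:
            continue
        assigned[cl] = pl
        used_prev.add(pl)
    for cl in cur_labels:
        if cl in assigned:
            out[cur == cl] = assigned[cl]
        else:
            out[cur == cl] = next_label
            next_label += 1
    return out, next_label


def segment_nuclei(nuclei_image: ImageStack4D, params: NucleiParams) -> LabelVolume:
    """Segment nuclei at every time point and link labels over time."""
    t_n = nuclei_image.n_timepoints
    out = np.zeros(nuclei_image.shape, dtype=np.int32)
    out[0] = _segment_3d(nuclei_image.values[0], params)
    next_label = int(out[0].max()) + 1
    for t in range(1, t_n):
        cur = _segment_3d(nuclei_image.values[t], params)
        out[t], next_label = _link_by_overlap(out[t - 1], cur, next_label)
    return LabelVolume(out)


def validate_seeds(seeds: LabelVolume) -> pd.DataFrame:
    """Per-time-point seed diagnostics with quality flags.

    Reports label counts, volumes, minimum centroid separation, and flags
    labels touching the grid boundary or vanishing then reappearing in time.
    """
    rows = []
    t_n, nz, ny, nx = seeds.shape
    presence: dict[int, list[int]] = {}
    for t in range(t_n):
        labs = seeds.labels_at(t)
        centroids = {}
        for lab in labs:
            presence.setdefault(int(lab), []).append(t)
            sel = seeds.values[t] == lab
            zz, yy, xx = np.nonzero(sel)
            touches = bool(
                (zz.min() == 0) or (zz.max() == nz - 1)
                or (yy.min() == 0) or (yy.max() == ny - 1)
                or (xx.min() == 0) or (xx.max() == nx - 1)
            )
            centroids[int(lab)] = np.array([zz.mean(), yy.mean(), xx.mean()])
            rows.append(
                {
                    "t": t,
                    "label": int(lab),
                    "volume_voxels": int(sel.sum()),
                    "touches_boundary": touches,
                    "continuity_flag": False,
                }
            )
        labs_list = sorted(centroids)
        for i, lab in enumerate(labs_list):
            dmin = np.inf
            for other in labs_list:
                if other != lab:
                    dmin = min(dmin, float(np.linalg.norm(centroids[lab] - centroids[other])))
            for r in rows:
                if r["t"] == t and r["label"] == lab:
                    r["min_centroid_distance"] = dmin if np.isfinite(dmin) else np.nan
    df = pd.DataFrame(rows)
    for lab, ts in presence.items():
        ts_sorted = sorted(ts)
        gaps = set(range(ts_sorted[0], ts_sorted[-1] + 1)) - set(ts_sorted)
        if gaps:
            df.loc[df["label"] == lab, "continuity_flag"] = True
    return df
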