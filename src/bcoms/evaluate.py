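"""Segmentation evaluation: feature deviations and per-voxel distances.

Three procedures, usable on any pair of label volumes:

* percent deviation of shape features against a voxel-exact ground truth,
* percent deviation between adjacent time points of one segmentation
  (shapes barely change over one short imaging interval, so this is a
  truth-free consistency check),
* per-voxel distance maps from each segmented cell to its matched truth
  cell, which localize *where* a segmentation deviates.

Cells are matched by maximal voxel overlap so the evaluator also works on
segmentations produced outside this package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .features import CORE_FEATURES
from .types import LabelVolume

__all__ = [
    "CellCorrespondence",
    "DeviationReport",
    "match_cells",
    "deviation_vs_truth",
    "deviation_adjacent_timepoints",
    "pixel_distance_map",
]


@dataclass
class CellCorrespondence:
    """Injective seg-label <-> truth-label matching per time point."""

    pairs: dict[int, list[tuple[int, int, int, float]]]
    """t -> list of (seg_label, truth_label, overlap_voxels, jaccard)."""
    unmatched_seg: dict[int, list[int]] = field(default_factory=dict)
    unmatched_truth: dict[int, list[int]] = field(default_factory=dict)

    def mapping(self, t: int) -> dict[int, int]:
        return {s: tr for s, tr, _, _ in self.pairs.get(t, [])}


@dataclass
class DeviationReport:
    """Percent deviations: per cell entry, per feature, and headline.

    ``grand_mean``/``grand_sd`` are the mean and sample SD over the
    *per-feature means* — the headline "average deviation among all
    features" — not over all cell-by-feature entries (also available as
    ``entry_mean``)."""

    per_entry: pd.DataFrame
    per_feature: pd.Series
    grand_mean: float
    grand_sd: float
    entry_mean: float
    n_excluded_zero_truth: int = 0


def match_cells(seg: LabelVolume, truth: LabelVolume) -> CellCorrespondence:
    """Greedy maximal-overlap matching per time point.

    Pairs are taken in order of decreasing overlap, ties broken by larger
    Jaccard index, then by smaller (seg, truth) labels; each label is used
    at most once per time point.
    """
    if seg.shape != truth.shape:
        raise ValueError("seg and truth shapes differ")
    pairs: dict[int, list[tuple[int, int, int, float]]] = {}
    un_s: dict[int, list[int]] = {}
    un_t: dict[int, list[int]] = {}
    for t in range(seg.shape[0]):
        s, r = seg.values[t].ravel(), truth.values[t].ravel()
        both = (s > 0) & (r > 0)
        sizes_s = dict(zip(*np.unique(s[s > 0], return_counts=True)))
        sizes_r = dict(zip(*np.unique(r[r > 0], return_counts=True)))
        cands = []
        if both.any():
            combo = s[both].astype(np.int64) * (r.max() + 1) + r[both]
            uniq, counts = np.unique(combo, return_counts=True)
            for u, n in zip(uniq, counts):
                sl, tl = int(u // (r.max() + 1)), int(u % (r.max() + 1))
                union = sizes_s[sl] + sizes_r[tl] - n
                cands.append((int(n), n / union, -sl, -tl, sl, tl))
        matched: list[tuple[int, int, int, float]] = []
        used_s: set[int] = set()
        used_t: set[int] = set()
        for n, jac, _, _, sl, tl in sorted(cands, reverse=True):
            if sl in used_s or tl in used_t:
                continue
            matched.append((sl, tl, int(n), float(jac)))
            used_s.add(sl)
            used_t.add(tl)
        pairs[t] = sorted(matched)
        un_s[t] = sorted(set(map(int, sizes_s)) - used_s)
        un_t[t] = sorted(set(map(int, sizes_r)) - used_t)
    return CellCorrespondence(pairs=pairs, unmatched_seg=un_s, unmatched_truth=un_t)


def _deviation_report(dev: pd.DataFrame, features: list[str],
                      n_excluded: int) -> DeviationReport:
    per_feature = dev[features].mean(skipna=True)
    vals = per_feature.dropna()
    grand_mean = float(vals.mean())
    grand_sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
    entry_mean = float(np.nanmean(dev[features].to_numpy(dtype=float)))
    return DeviationReport(
        per_entry=dev,
        per_feature=per_feature,
        grand_mean=grand_mean,
        grand_sd=grand_sd,
        entry_mean=entry_mean,
        n_excluded_zero_truth=n_excluded,
    )


def deviation_vs_truth(
    f_seg: pd.DataFrame,
    f_truth: pd.DataFrame,
    correspondence: CellCorrespondence,
    features: list[str] | None = None,
) -> DeviationReport:
    """Percent feature deviation of a segmentation from ground truth.

    Per matched cell and feature: ``|truth - seg| / truth * 100``.  Entries
    with a zero truth value are excluded from the means and counted in
    ``n_excluded_zero_truth``.
    """
    features = features or [f for f in CORE_FEATURES if f in f_seg.columns]
    rows = []
    n_excluded = 0
    for t, matched in correspondence.pairs.items():
        for sl, tl, _, _ in matched:
            seg_row = f_seg[(f_seg["t"] == t) & (f_seg["label"] == sl)]
            truth_row = f_truth[(f_truth["t"] == t) & (f_truth["label"] == tl)]
            if seg_row.empty or truth_row.empty:
                continue
            out = {"t": t, "seg_label": sl, "truth_label": tl}
            for f in features:
                tv = float(truth_row.iloc[0][f])
                sv = float(seg_row.iloc[0][f])
                if tv == 0 or not np.isfinite(tv) or not np.isfinite(sv):
                    out[f] = np.nan
                    if tv == 0:
                        n_excluded += 1
                    continue
                out[f] = abs(tv - sv) / abs(tv) * 100.0
            rows.append(out)
    if not rows:
        raise ValueError("no matched cells present in both feature tables")
    return _deviation_report(pd.DataFrame(rows), features, n_excluded)


def deviation_adjacent_timepoints(
    f: pd.DataFrame, features: list[str] | None = None
) -> DeviationReport:
    """Percent feature deviation between consecutive time points.

    For every persistent identity present at both ``t`` and ``t + 1``:
    ``|f(t+1) - f(t)| / f(t) * 100``, averaged across all pairs and cells,
    then across features.  Pairs spanning a division contribute nothing
    because the parent identity does not exist at ``t + 1``.
    """
    if "identity" not in f.columns:
        raise ValueError("feature table needs an 'identity' column")
    features = features or [c for c in CORE_FEATURES if c in f.columns]
    f = f[~f.get("gap_flag", pd.Series(False, index=f.index)).fillna(False)]
    rows = []
    n_excluded = 0
    for ident, grp in f.groupby("identity"):
        grp = grp.sort_values("t")
        ts = list(grp["t"])
        by_t = {int(r["t"]): r for _, r in grp.iterrows()}
        for t in ts:
            if t + 1 not in by_t:
                continue
            prev, nxt = by_t[t], by_t[t + 1]
            out = {"identity": ident, "t": t}
            for feat in features:
                pv, nv = float(prev[feat]), float(nxt[feat])
                if pv == 0 or not np.isfinite(pv) or not np.isfinite(nv):
                    out[feat] = np.nan
                    if pv == 0:
                        n_excluded += 1
                    continue
                out[feat] = abs(nv - pv) / abs(pv) * 100.0
            rows.append(out)
    if not rows:
        raise ValueError("no adjacent-time-point pairs found")
    return _deviation_report(pd.DataFrame(rows), features, n_excluded)


def pixel_distance_map(
    seg: LabelVolume,
    truth: LabelVolume,
    correspondence: CellCorrespondence,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> tuple[np.ndarray, pd.DataFrame]:
    """Distance of every segmented-cell voxel to its matched truth cell.

    For each matched pair, each voxel of the seg cell gets the Euclidean
    distance (with ``spacing``) to the nearest voxel of the *matched* truth
    cell — never to another cell.  Unmatched seg cells stay NaN in the map
    and are reported with NaN summaries.

    Returns the 4D distance map (NaN outside seg cells) and a per-cell
    summary with max and mean distances.
    """
    dist = np.full(seg.shape, np.nan)
    rows = []
    for t in range(seg.shape[0]):
        mapping = correspondence.mapping(t)
        for sl in seg.labels_at(t):
            sel = seg.values[t] == sl
            tl = mapping.get(int(sl))
            if tl is None:
                rows.append({"t": t, "seg_label": int(sl), "truth_label": None,
                             "max_distance": np.nan, "mean_distance": np.nan,
                             "matched": False})
                continue
            d = ndimage.distance_transform_edt(
                truth.values[t] != tl, sampling=spacing
            )
            dist[t][sel] = d[sel]
            rows.append({"t": t, "seg_label": int(sl), "truth_label": int(tl),
                         "max_distance": float(d[sel].max()),
                         "mean_distance": float(d[sel].mean()),
                         "matched": True})
    return dist, pd.DataFrame(rows)
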