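"""Exhaustive constrained grid search over both segmentation stages.

The framework's selection rule: run the segmentation with *every* parameter
set in the declared grid, score each result with an image-consistency
objective, discard results violating the biological constraints, and keep
the feasible maximizer.  Stage 2 searches only on stage 1's single winner,
so the cost is the sum — not the product — of the two grid sizes.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Callable, Iterator

import numpy as np

from . import cells as _cells
from . import embryo as _embryo
from .types import BcomsError, ImageStack4D, LabelVolume, RunConfig, SegmentationError

__all__ = [
    "ParameterGrid",
    "EvaluationRecord",
    "InfeasibleGridError",
    "enumerate_grid",
    "optimize_stage",
    "run_bcoms",
]


@dataclass
class ParameterGrid:
    """Ordered named axes whose Cartesian product is searched."""

    axes: dict[str, list]

    def __post_init__(self) -> None:
        if not self.axes:
            raise ValueError("grid must have at least one axis")
        for name, vals in self.axes.items():
            if len(vals) == 0:
                raise ValueError(f"grid axis {name!r} is empty")
        if len(set(self.axes)) != len(self.axes):
            raise ValueError("axis names must be unique")

    @property
    def cardinality(self) -> int:
        return math.prod(len(v) for v in self.axes.values())


@dataclass
class EvaluationRecord:
    """One evaluated parameter set: objective, feasibility, diagnostics."""

    stage: str
    params: dict
    objective: float           # NaN when the segmentation itself failed
    feasible: bool
    constraint_details: dict = field(default_factory=dict)
    error: str | None = None

    def to_json_dict(self) -> dict:
        return {
            "stage": self.stage,
            "params": self.params,
            "objective": None if math.isnan(self.objective) else self.objective,
            "feasible": self.feasible,
            "constraints": self.constraint_details,
            "error": self.error,
        }


class InfeasibleGridError(BcomsError):
    """No parameter set satisfied the constraints; carries all records so
    the user can see which constraint eliminated each candidate."""

    def __init__(self, stage: str, records: list[EvaluationRecord]):
        self.stage = stage
        self.records = records
        killers = {}
        for r in records:
            failed = [k for k, v in r.constraint_details.items() if not v.get("passed")]
            killers[str(r.params)] = failed or ([r.error] if r.error else ["unknown"])
        super().__init__(
            f"stage {stage!r}: no feasible parameter set among {len(records)}; "
            f"eliminating constraints per candidate: {killers}"
        )


def enumerate_grid(grid: ParameterGrid) -> Iterator[dict]:
    """Lexicographic Cartesian product, first axis slowest."""
    names = list(grid.axes)
    for combo in itertools.product(*(grid.axes[n] for n in names)):
        yield dict(zip(names, combo))


def optimize_stage(
    evaluate: Callable[[dict], tuple[float, dict]],
    grid: ParameterGrid,
    stage: str = "stage",
) -> tuple[dict, list[EvaluationRecord]]:
    """Evaluate every parameter set; return the feasible maximizer.

    ``evaluate`` maps a parameter dict to ``(objective, constraint_details)``
    where each constraint detail is ``{"passed": bool, ...measurements}``.
    A raised :class:`SegmentationError` marks the candidate infeasible with a
    NaN objective.  Ties are broken by enumeration order (first wins).
    """
    records: list[EvaluationRecord] = []
    best: dict | None = None
    best_obj = -np.inf
    for params in enumerate_grid(grid):
        try:
            obj, details = evaluate(params)
            feasible = all(d.get("passed", False) for d in details.values())
            rec = EvaluationRecord(stage, params, float(obj), feasible, details)
        except SegmentationError as exc:
            rec = EvaluationRecord(
                stage, params, float("nan"), False,
                {"segmentation": {"passed": False, "error": str(exc)}},
                error=str(exc),
            )
        records.append(rec)
        if rec.feasible and rec.objective > best_obj:
            best, best_obj = params, rec.objective
    if best is None:
        raise InfeasibleGridError(stage, records)
    return best, records


def run_bcoms(
    membrane: ImageStack4D, seeds: LabelVolume, config: RunConfig
) -> tuple[_embryo.EmbryoStageResult, _cells.CellStageResult, dict]:
    """Full two-stage optimized segmentation.

    Stage 1 (embryonic region) maximizes the embryo-edge objective subject
    to the nuclei-enclosure and volume-stability constraints.  Its winning
    mask is fixed, then stage 2 (cells/membranes) maximizes the membrane
    objective; stage 2's only constraint — every nucleus enclosed by its own
    cell — is enforced by the seeded watershed itself and treated as a
    segmentation failure when violated.

    Returns the winning stage results plus a log dict with one record per
    evaluated parameter set per stage and the selected parameter sets.
    """
    for t in range(seeds.shape[0]):
        if len(seeds.labels_at(t)) == 0:
            raise ValueError(f"seeds empty at time point {t}")
    init = _embryo.initial_region(membrane)
    cache: dict[tuple, _embryo.EmbryoStageResult] = {}

    def eval_stage1(params: dict) -> tuple[float, dict]:
        ls = _embryo.LevelSetParams(**params)
        res = _embryo.segment_embryo(membrane, init, ls)
        cache[tuple(sorted(params.items()))] = res
        obj = _embryo.objective_embryo(membrane, res.edge)
        enclosed = _embryo.constraint_nuclei_enclosed(seeds, res.mask)
        excluded = int(np.sum((seeds.values > 0) & ~res.mask))
        stable = _embryo.constraint_volume_stability(
            res.volumes, config.volume_ratio_min
        )
        details = {
            "nuclei_enclosed": {"passed": enclosed, "excluded_seed_voxels": excluded},
            "volume_stability": {
                "passed": stable,
                "v_min": res.v_min,
                "v_max": res.v_max,
                "ratio": res.v_min / res.v_max,
                "ratio_min": config.volume_ratio_min,
            },
        }
        return obj, details

    grid1 = ParameterGrid(config.stage1_grid)
    try:
        best1, records1 = optimize_stage(eval_stage1, grid1, stage="embryo_region")
    except InfeasibleGridError:
        raise
    embryo_result = cache[tuple(sorted(best1.items()))]

    spacing = config.spacing if config.physical_distance else None
    cache2: dict[tuple, _cells.CellStageResult] = {}

    def eval_stage2(params: dict) -> tuple[float, dict]:
        hp = _cells.HybridParams(**params)
        res = _cells.segment_cells(
            membrane, seeds, embryo_result.mask, hp, spacing=spacing
        )
        cache2[tuple(sorted(params.items()))] = res
        obj = _cells.objective_membrane(membrane, res.membrane)
        n_seed = [len(seeds.labels_at(t)) for t in range(seeds.shape[0])]
        n_cell = [len(res.cells.labels_at(t)) for t in range(seeds.shape[0])]
        details = {
            "seeds_enclosed": {"passed": True},  # enforced inside segment_cells
            "label_counts": {
                "passed": n_seed == n_cell,
                "seed_labels": n_seed,
                "cell_labels": n_cell,
            },
        }
        return obj, details

    grid2 = ParameterGrid(config.stage2_grid)
    best2, records2 = optimize_stage(eval_stage2, grid2, stage="membrane_cells")
    cell_result = cache2[tuple(sorted(best2.items()))]

    logs = {
        "stage1": [r.to_json_dict() for r in records1],
        "stage2": [r.to_json_dict() for r in records2],
        "selected": {"stage1": best1, "stage2": best2},
    }
    return embryo_result, cell_result, logs
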