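"""Stage affinities and optimal assignment for the matching cascade.

Each cascade stage turns (predicted track states, detections) into a cost
matrix plus a feasibility mask; infeasible cells (outside the stage gate)
are never part of a returned match.  Assignment is the Hungarian optimum
restricted to feasible cells.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .boxes import BoundingBox
from .kalman import CHI2_GATE_95_4DOF, KalmanBoxFilter, TrackState

#: finite stand-in for masked cells so the solver stays well-posed; matches
#: landing on such a cell are discarded afterwards.
_MASKED_COST = 1e12


class Stage(enum.Enum):
    """Cascade stages, in the order they run."""

    MOTION = "motion"
    IOU = "iou"
    DISTANCE = "distance"


@dataclass(frozen=True)
class StageGates:
    """Feasibility gates, one per stage.

    motion_gate: squared-Mahalanobis ceiling (chi-square 0.95, 4 dof).
    iou_gate: minimum overlap for the IoU stage; loose by default because
        swimming fish deform their boxes strongly between frames.
    dist_gate_factor: centroid distance ceiling, in units of the mean of the
        two boxes' diagonals.
    """

    motion_gate: float = CHI2_GATE_95_4DOF
    iou_gate: float = 0.1
    dist_gate_factor: float = 1.0


@dataclass
class CostMatrix:
    values: np.ndarray  # (n_tracks, n_detections)
    feasible: np.ndarray  # same shape, bool

    def __post_init__(self) -> None:
        if self.values.shape != self.feasible.shape:
            raise ValueError("values and feasibility mask must share a shape")


@dataclass
class MatchSet:
    pairs: list[tuple[int, int]]
    unmatched_tracks: list[int]
    unmatched_detections: list[int]


def iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection over union of two boxes, in [0, 1].

    All areas are computed from corner differences so identical boxes give
    exactly 1.0 (mixing width*height with corner arithmetic loses an ulp).
    """
    iw = min(a.right, b.right) - max(a.left, b.left)
    ih = min(a.bottom, b.bottom) - max(a.top, b.top)
    if iw <= 0 or ih <= 0:
        return 0.0
    inter = iw * ih
    area_a = (a.right - a.left) * (a.bottom - a.top)
    area_b = (b.right - b.left) * (b.bottom - b.top)
    return inter / (area_a + area_b - inter)


def centroid_distance(a: BoundingBox, b: BoundingBox) -> float:
    """Euclidean distance between box centers, in pixels."""
    return math.hypot(a.cx - b.cx, a.cy - b.cy)


def build_cost_matrix(
    stage: Stage,
    kf: KalmanBoxFilter,
    states: list[TrackState],
    detections: list[BoundingBox],
    gates: StageGates,
    ref_boxes: list[BoundingBox] | None = None,
) -> CostMatrix:
    """Per-stage cost + feasibility over (track, detection) pairs.

    Motion: squared Mahalanobis distance, gated by ``motion_gate``.
    IoU: 1 - IoU between the track's extrapolated box and the detection,
    gated below ``iou_gate`` overlap.  Distance: centroid distance between
    the predicted centroid and the detection's, gated above
    ``dist_gate_factor`` times the mean of the two boxes' diagonals.

    ``ref_boxes`` optionally supplies each track's last observed box; the
    IoU and Distance stages then use its width/height re-centred at the
    Kalman-predicted position instead of the filter's smoothed shape — for
    strongly deforming targets the one-frame-old observed shape is far more
    faithful than the filtered one.
    """
    n, m = len(states), len(detections)
    values = np.zeros((n, m))
    feasible = np.zeros((n, m), dtype=bool)
    if n == 0 or m == 0:
        return CostMatrix(values, feasible)

    def extrapolated(i: int) -> BoundingBox:
        st = states[i]
        if ref_boxes is None:
            return st.predicted_box()
        ref = ref_boxes[i]
        cx, cy = st.mean[0], st.mean[1]
        return BoundingBox(cx - ref.width / 2.0, cy - ref.height / 2.0, ref.width, ref.height)

    if stage is Stage.MOTION:
        for i, st in enumerate(states):
            d2 = kf.gating_distances(st, detections)
            values[i] = d2
            feasible[i] = d2 <= gates.motion_gate
    elif stage is Stage.IOU:
        for i in range(n):
            pbox = extrapolated(i)
            for j, dbox in enumerate(detections):
                ov = iou(pbox, dbox)
                values[i, j] = 1.0 - ov
                feasible[i, j] = ov >= gates.iou_gate
    elif stage is Stage.DISTANCE:
        for i in range(n):
            pbox = extrapolated(i)
            for j, dbox in enumerate(detections):
                dist = centroid_distance(pbox, dbox)
                values[i, j] = dist
                feasible[i, j] = dist <= gates.dist_gate_factor * (
                    (pbox.diagonal + dbox.diagonal) / 2.0
                )
    else:  # pragma: no cover - exhaustive enum
        raise ValueError(f"unknown stage: {stage!r}")
    return CostMatrix(values, feasible)


def solve_assignment(costs: CostMatrix) -> MatchSet:
    """Minimum-cost one-to-one assignment over feasible cells.

    Infeasible cells are replaced by a large finite constant before solving;
    any assignment pair landing on one is dropped, so gated pairs are never
    returned.  Empty matrices yield an empty match set.
    """
    n, m = costs.values.shape
    if n == 0 or m == 0 or not costs.feasible.any():
        return MatchSet([], list(range(n)), list(range(m)))
    work = np.where(costs.feasible, costs.values, _MASKED_COST)
    rows, cols = linear_sum_assignment(work)
    pairs = [
        (int(r), int(c)) for r, c in zip(rows, cols) if costs.feasible[r, c]
    ]
    pairs.sort()
    matched_r = {r for r, _ in pairs}
    matched_c = {c for _, c in pairs}
    return MatchSet(
        pairs,
        [i for i in range(n) if i not in matched_r],
        [j for j in range(m) if j not in matched_c],
    )
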