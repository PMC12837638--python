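"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive — exhaustive enumeration over
permutations and trajectory bijections — and shares no code path with the
package's optimised implementations.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

_MASKED = 1e12


def box_iou(a, b) -> float:
    """Plain-geometry IoU, written independently of fishmot.affinity."""
    ax2, ay2 = a.left + a.width, a.top + a.height
    bx2, by2 = b.left + b.width, b.top + b.height
    iw = min(ax2, bx2) - max(a.left, b.left)
    ih = min(ay2, by2) - max(a.top, b.top)
    if iw <= 0 or ih <= 0:
        return 0.0
    inter = iw * ih
    union = (ax2 - a.left) * (ay2 - a.top) + (bx2 - b.left) * (by2 - b.top) - inter
    return inter / union


def brute_force_assignment(values: np.ndarray, feasible: np.ndarray):
    """Best complete matching by enumeration, then feasibility filtering.

    Mirrors the contract of solve_assignment: a complete min-cost matching is
    chosen with masked costs substituted for infeasible cells, and any chosen
    infeasible pair is discarded afterwards.  Returns (pairs, feasible_cost).
    """
    n, m = values.shape
    work = np.where(feasible, values, _MASKED)
    best_total, best = math.inf, []
    if n <= m:
        for cols in itertools.permutations(range(m), n):
            total = sum(work[i, c] for i, c in enumerate(cols))
            if total < best_total:
                best_total = total
                best = [(i, c) for i, c in enumerate(cols)]
    else:
        for rows in itertools.permutations(range(n), m):
            total = sum(work[r, j] for j, r in enumerate(rows))
            if total < best_total:
                best_total = total
                best = [(r, j) for j, r in enumerate(rows)]
    pairs = sorted((r, c) for r, c in best if feasible[r, c])
    cost = sum(values[r, c] for r, c in pairs)
    return pairs, cost


def id_counts_oracle(gt, pred, thr: float = 0.5):
    """IDTP/IDFP/IDFN by exhaustive search over trajectory bijections."""

    def coloc(a, b) -> int:
        common = a.boxes.keys() & b.boxes.keys()
        return sum(1 for f in common if box_iou(a.boxes[f], b.boxes[f]) >= thr)

    total_gt = sum(len(t.boxes) for t in gt)
    total_pred = sum(len(t.boxes) for t in pred)
    best = 0
    n, m = len(gt), len(pred)
    if n and m:
        padded = list(range(m)) + [None] * n
        for assign in itertools.permutations(padded, n):
            s = sum(
                coloc(gt[i], pred[j]) for i, j in enumerate(assign) if j is not None
            )
            best = max(best, s)
    return best, total_pred - best, total_gt - best


def clear_oracle(gt, pred, thr: float = 0.5):
    """Per-frame CLEAR matchings by brute force, with the continuity rule.

    Returns (matches_per_frame, counts dict) where counts has TP/FP/FN/IDSW/GT
    and the summed (1 - IoU) distance.
    """
    gt_frames: dict[int, dict] = {}
    for t in gt:
        for f, b in t.boxes.items():
            gt_frames.setdefault(f, {})[t.identity] = b
    pr_frames: dict[int, dict] = {}
    for t in pred:
        for f, b in t.boxes.items():
            pr_frames.setdefault(f, {})[t.identity] = b

    frames = sorted(set(gt_frames) | set(pr_frames))
    counts = {"TP": 0, "FP": 0, "FN": 0, "IDSW": 0, "GT": 0, "dist": 0.0}
    matches_per_frame = {}
    prev: dict[int, int] = {}
    last: dict[int, int] = {}
    for f in frames:
        gts = gt_frames.get(f, {})
        prs = pr_frames.get(f, {})
        counts["GT"] += len(gts)
        pairs = []
        used_p = set()
        for g, p in prev.items():
            if g in gts and p in prs and box_iou(gts[g], prs[p]) >= thr:
                pairs.append((g, p))
                used_p.add(p)
        free_g = [g for g in sorted(gts) if g not in {a for a, _ in pairs}]
        free_p = [p for p in sorted(prs) if p not in used_p]
        if free_g and free_p:
            values = np.array(
                [[1.0 - box_iou(gts[g], prs[p]) for p in free_p] for g in free_g]
            )
            feas = np.array(
                [[box_iou(gts[g], prs[p]) >= thr for p in free_p] for g in free_g]
            )
            extra, _ = brute_force_assignment(values, feas)
            pairs.extend((free_g[i], free_p[j]) for i, j in extra)
        pairs.sort()
        matches_per_frame[f] = pairs
        counts["TP"] += len(pairs)
        counts["FN"] += len(gts) - len(pairs)
        counts["FP"] += len(prs) - len(pairs)
        for g, p in pairs:
            counts["dist"] += max(1.0 - box_iou(gts[g], prs[p]), 0.0)
            if g in last and last[g] != p:
                counts["IDSW"] += 1
            last[g] = p
        prev = dict(pairs)
    return matches_per_frame, counts


def random_micro_scene(rng, max_objects: int = 4, max_frames: int = 5):
    """A small random gt/pred trajectory pair for oracle comparisons."""
    from fishmot.boxes import BoundingBox, Trajectory

    n_gt = int(rng.integers(1, max_objects + 1))
    n_pred = int(rng.integers(0, max_objects + 1))
    n_frames = int(rng.integers(1, max_frames + 1))
    gt = []
    for i in range(n_gt):
        t = Trajectory(i + 1)
        for f in range(1, n_frames + 1):
            if rng.uniform() < 0.8:
                t.boxes[f] = BoundingBox(
                    rng.uniform(0, 200), rng.uniform(0, 200),
                    rng.uniform(10, 40), rng.uniform(10, 40),
                )
        if t.boxes:
            gt.append(t)
    if not gt:
        gt = [Trajectory(1, {1: BoundingBox(0, 0, 10, 10)})]
    pred = []
    all_gt_boxes = [(f, b) for t in gt for f, b in t.boxes.items()]
    for j in range(n_pred):
        t = Trajectory(j + 1)
        for f in range(1, n_frames + 1):
            u = rng.uniform()
            if u < 0.5 and any(ff == f for ff, _ in all_gt_boxes):
                # near-copy of some gt box on this frame: plausible match
                cands = [b for ff, b in all_gt_boxes if ff == f]
                b = cands[int(rng.integers(0, len(cands)))]
                t.boxes[f] = BoundingBox(
                    b.left + rng.uniform(-3, 3), b.top + rng.uniform(-3, 3),
                    b.width * rng.uniform(0.9, 1.1), b.height * rng.uniform(0.9, 1.1),
                )
            elif u < 0.7:
                t.boxes[f] = BoundingBox(
                    rng.uniform(0, 200), rng.uniform(0, 200),
                    rng.uniform(10, 40), rng.uniform(10, 40),
                )
        if t.boxes:
            pred.append(t)
    return gt, pred
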