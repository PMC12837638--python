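"""Multi-object tracking evaluation: CLEAR, identity, coverage and HOTA.

Three matching layers feed the reported quantities:

* **CLEAR** — per-frame correspondences with a continuity rule: pairs
  matched on the previous frame persist while their overlap stays above the
  threshold; the remainder is re-assigned optimally on IoU.  Yields FP, FN,
  identity switches, MOTA, and MOTP (mean 1 - IoU over matches, lower
  better), plus per-trajectory coverage for MT/ML.
* **Identity** — one global bipartite matching between ground-truth and
  predicted trajectories (dummy-augmented, so trajectories may stay
  unmatched) minimising non-co-located frames; yields IDTP/IDFP/IDFN and
  hence IDF1/IDP/IDR.
* **HOTA** — per-frame matching biased by a global alignment score, scored
  at a single localisation threshold by default (a multi-threshold average
  is available via ``alphas``); yields DetA, AssA and HOTA = sqrt(DetA·AssA).
"""

from __future__ import annotations

import csv
import json
import logging
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .affinity import iou
from .boxes import BoundingBox, Trajectory
from .motchallenge import read_trajectories

log = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = 1

_MASKED = 1e12


@dataclass
class MetricCounts:
    """Global tallies behind MOTA/IDF1 and friends."""

    FP: int = 0
    FN: int = 0
    IDSW: int = 0
    GT: int = 0
    TP: int = 0
    IDTP: int = 0
    IDFP: int = 0
    IDFN: int = 0


@dataclass
class ClearResult:
    counts: MetricCounts
    distances: list[float]  # 1 - IoU per matched pair
    matches_per_frame: dict[int, list[tuple[int, int]]]  # frame -> (gt id, pred id)
    coverage: dict[int, float]  # gt identity -> tracked fraction of lifespan


@dataclass
class HotaComponents:
    DetA: float
    AssA: float
    HOTA: float
    TP: int = 0
    FP: int = 0
    FN: int = 0


def _frame_index(trajs: Sequence[Trajectory]) -> dict[int, list[tuple[int, BoundingBox]]]:
    frames: dict[int, list[tuple[int, BoundingBox]]] = {}
    for t in trajs:
        for f, b in t.boxes.items():
            frames.setdefault(f, []).append((t.identity, b))
    for f in frames:
        frames[f].sort(key=lambda p: p[0])
    return frames


# ---------------------------------------------------------------------------
# CLEAR
# ---------------------------------------------------------------------------

def clear_match(
    gt: Sequence[Trajectory],
    pred: Sequence[Trajectory],
    iou_threshold: float = 0.5,
) -> ClearResult:
    """Frame-by-frame CLEAR correspondences with the continuity rule."""
    gt_frames = _frame_index(gt)
    pred_frames = _frame_index(pred)
    all_frames = sorted(set(gt_frames) | set(pred_frames))

    counts = MetricCounts()
    distances: list[float] = []
    matches_per_frame: dict[int, list[tuple[int, int]]] = {}
    tracked_frames: dict[int, int] = {t.identity: 0 for t in gt}

    prev_pairs: dict[int, int] = {}  # matches on the immediately previous frame
    last_match: dict[int, int] = {}  # most recent match ever, for IDSW

    for frame in all_frames:
        gts = gt_frames.get(frame, [])
        prs = pred_frames.get(frame, [])
        counts.GT += len(gts)
        g_ids = [g for g, _ in gts]
        p_ids = [p for p, _ in prs]
        g_pos = {g: i for i, g in enumerate(g_ids)}
        p_pos = {p: j for j, p in enumerate(p_ids)}

        overlaps = np.zeros((len(gts), len(prs)))
        for i, (_, gb) in enumerate(gts):
            for j, (_, pb) in enumerate(prs):
                overlaps[i, j] = iou(gb, pb)

        pairs: list[tuple[int, int]] = []
        used_g: set[int] = set()
        used_p: set[int] = set()
        # continuity: persist still-valid previous-frame correspondences
        for g, p in prev_pairs.items():
            if g in g_pos and p in p_pos and overlaps[g_pos[g], p_pos[p]] >= iou_threshold:
                pairs.append((g, p))
                used_g.add(g)
                used_p.add(p)
        # optimal assignment on the remainder, maximising total IoU
        free_g = [g for g in g_ids if g not in used_g]
        free_p = [p for p in p_ids if p not in used_p]
        if free_g and free_p:
            cost = np.full((len(free_g), len(free_p)), _MASKED)
            for a, g in enumerate(free_g):
                for b, p in enumerate(free_p):
                    ov = overlaps[g_pos[g], p_pos[p]]
                    if ov >= iou_threshold:
                        cost[a, b] = 1.0 - ov
            rows, cols = linear_sum_assignment(cost)
            for a, b in zip(rows, cols):
                if cost[a, b] < _MASKED:
                    pairs.append((free_g[a], free_p[b]))

        pairs.sort()
        matches_per_frame[frame] = pairs
        counts.TP += len(pairs)
        counts.FN += len(gts) - len(pairs)
        counts.FP += len(prs) - len(pairs)
        for g, p in pairs:
            distances.append(max(1.0 - overlaps[g_pos[g], p_pos[p]], 0.0))
            tracked_frames[g] = tracked_frames.get(g, 0) + 1
            if g in last_match and last_match[g] != p:
                counts.IDSW += 1
            last_match[g] = p
        prev_pairs = dict(pairs)

    coverage = {
        t.identity: tracked_frames.get(t.identity, 0) / len(t.boxes) for t in gt
    }
    return ClearResult(counts, distances, matches_per_frame, coverage)


def mota(counts: MetricCounts) -> float:
    """1 - (FN + FP + IDSW) / GT; unbounded below, at most 1."""
    if counts.GT <= 0:
        raise ValueError("MOTA undefined for GT = 0")
    return 1.0 - (counts.FN + counts.FP + counts.IDSW) / counts.GT


def motp(distances: Sequence[float]) -> float:
    """Mean (1 - IoU) over matched pairs; 0 is perfect localisation."""
    if len(distances) == 0:
        raise ValueError("MOTP undefined with zero matched pairs")
    return float(np.mean(distances))


# ---------------------------------------------------------------------------
# Identity metrics
# ---------------------------------------------------------------------------

def _colocated_frames(a: Trajectory, b: Trajectory, thr: float) -> int:
    common = a.boxes.keys() & b.boxes.keys()
    return sum(1 for f in common if iou(a.boxes[f], b.boxes[f]) >= thr)


def id_global_assignment(
    gt: Sequence[Trajectory],
    pred: Sequence[Trajectory],
    iou_threshold: float = 0.5,
) -> tuple[int, int, int]:
    """Global trajectory-level matching; returns (IDTP, IDFP, IDFN).

    Trajectories are matched one-to-one (with dummies, so any trajectory may
    stay unmatched) minimising the number of frames where the pair is not
    co-located, i.e. maximising the total number of co-located frames.
    """
    n, m = len(gt), len(pred)
    total_gt = sum(len(t.boxes) for t in gt)
    total_pred = sum(len(t.boxes) for t in pred)
    if n == 0 or m == 0:
        return 0, total_pred, total_gt

    size = n + m
    cost = np.zeros((size, size))
    gt_len = [len(t.boxes) for t in gt]
    pr_len = [len(t.boxes) for t in pred]
    coloc = np.zeros((n, m), dtype=int)
    for i, g in enumerate(gt):
        for j, p in enumerate(pred):
            coloc[i, j] = _colocated_frames(g, p, iou_threshold)
            cost[i, j] = gt_len[i] + pr_len[j] - 2 * coloc[i, j]
    for i in range(n):  # gt vs dummy: every gt frame missed
        cost[i, m:] = _MASKED
        cost[i, m + i] = gt_len[i]
    for j in range(m):  # pred vs dummy: every pred frame false
        cost[n:, j] = _MASKED
        cost[n + j, j] = pr_len[j]
    cost[n:, m:] = 0.0

    rows, cols = linear_sum_assignment(cost)
    idtp = int(sum(coloc[i, j] for i, j in zip(rows, cols) if i < n and j < m))
    return idtp, total_pred - idtp, total_gt - idtp


def idf1_idp_idr(idtp: int, idfp: int, idfn: int) -> tuple[float, float, float]:
    """(IDF1, IDP, IDR); zero denominators yield 0 with a warning."""

    def _ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            warnings.warn(f"{name} has zero denominator; reporting 0", stacklevel=2)
            return 0.0
        return num / den

    idf1 = _ratio(2 * idtp, 2 * idtp + idfp + idfn, "IDF1")
    idp = _ratio(idtp, idtp + idfp, "IDP")
    idr = _ratio(idtp, idtp + idfn, "IDR")
    return idf1, idp, idr


def mt_ml(coverage: dict[int, float]) -> tuple[float, float]:
    """Mostly-tracked (coverage >= 0.8) and mostly-lost (< 0.2) fractions."""
    n = len(coverage)
    if n == 0:
        raise ValueError("MT/ML undefined with no ground-truth trajectories")
    n_mt = sum(1 for c in coverage.values() if c >= 0.8)
    n_ml = sum(1 for c in coverage.values() if c < 0.2)
    return n_mt / n, n_ml / n


# ---------------------------------------------------------------------------
# HOTA
# ---------------------------------------------------------------------------

def hota(
    gt: Sequence[Trajectory],
    pred: Sequence[Trajectory],
    iou_threshold: float = 0.5,
    alphas: Sequence[float] | None = None,
) -> HotaComponents:
    """HOTA = sqrt(DetA · AssA) at one threshold, or averaged over ``alphas``.

    Per-frame matching maximises the product of a global track-alignment
    score and the frame IoU (the standard HOTA matching), keeping pairs at
    IoU >= alpha.  A(c) for a true positive with identity pair (g, p) is
    TPA / (TPA + FNA + FPA) with TPA the pair's joint matches across the
    sequence and FNA/FPA the remaining detections of g and p.
    """
    if alphas is None:
        return _hota_single(gt, pred, iou_threshold)
    parts = [_hota_single(gt, pred, a) for a in alphas]
    return HotaComponents(
        DetA=float(np.mean([p.DetA for p in parts])),
        AssA=float(np.mean([p.AssA for p in parts])),
        HOTA=float(np.mean([p.HOTA for p in parts])),
    )


def _hota_single(
    gt: Sequence[Trajectory], pred: Sequence[Trajectory], alpha: float
) -> HotaComponents:
    total_gt = sum(len(t.boxes) for t in gt)
    total_pred = sum(len(t.boxes) for t in pred)
    if total_gt == 0 and total_pred == 0:
        return HotaComponents(0.0, 0.0, 0.0)
    if total_gt == 0 or total_pred == 0:
        return HotaComponents(0.0, 0.0, 0.0, 0, total_pred, total_gt)

    gt_frames = _frame_index(gt)
    pred_frames = _frame_index(pred)
    all_frames = sorted(set(gt_frames) | set(pred_frames))
    gt_ids = sorted(t.identity for t in gt)
    pr_ids = sorted(t.identity for t in pred)
    g_of = {g: i for i, g in enumerate(gt_ids)}
    p_of = {p: j for j, p in enumerate(pr_ids)}

    sims: dict[int, np.ndarray] = {}
    potential = np.zeros((len(gt_ids), len(pr_ids)))
    gt_count = np.zeros(len(gt_ids))
    pr_count = np.zeros(len(pr_ids))
    for frame in all_frames:
        gts = gt_frames.get(frame, [])
        prs = pred_frames.get(frame, [])
        sim = np.zeros((len(gts), len(prs)))
        for i, (_, gb) in enumerate(gts):
            for j, (_, pb) in enumerate(prs):
                sim[i, j] = iou(gb, pb)
        sims[frame] = sim
        for i, (g, _) in enumerate(gts):
            gt_count[g_of[g]] += 1
        for j, (p, _) in enumerate(prs):
            pr_count[p_of[p]] += 1
        if len(gts) and len(prs):
            denom = sim.sum(0)[None, :] + sim.sum(1)[:, None] - sim
            soft = np.divide(sim, denom, out=np.zeros_like(sim), where=denom > 1e-12)
            rows = [g_of[g] for g, _ in gts]
            cols = [p_of[p] for p, _ in prs]
            potential[np.ix_(rows, cols)] += soft

    align_den = gt_count[:, None] + pr_count[None, :] - potential
    global_align = np.divide(
        potential, align_den, out=np.zeros_like(potential), where=align_den > 1e-12
    )

    tp = fp = fn = 0
    matches = np.zeros((len(gt_ids), len(pr_ids)), dtype=int)
    tp_pairs: list[tuple[int, int]] = []  # (gt idx, pred idx) per TP
    eps = np.finfo(float).eps
    for frame in all_frames:
        gts = gt_frames.get(frame, [])
        prs = pred_frames.get(frame, [])
        if not gts or not prs:
            fn += len(gts)
            fp += len(prs)
            continue
        sim = sims[frame]
        rows = [g_of[g] for g, _ in gts]
        cols = [p_of[p] for p, _ in prs]
        score = global_align[np.ix_(rows, cols)] * sim
        ri, ci = linear_sum_assignment(-score)
        matched = 0
        for i, j in zip(ri, ci):
            if sim[i, j] >= alpha - eps and sim[i, j] > 0:
                matched += 1
                matches[rows[i], cols[j]] += 1
                tp_pairs.append((rows[i], cols[j]))
        tp += matched
        fn += len(gts) - matched
        fp += len(prs) - matched

    det_a = tp / (tp + fp + fn) if (tp + fp + fn) else 0.0
    if tp:
        ass_scores = [
            matches[i, j] / (gt_count[i] + pr_count[j] - matches[i, j])
            for i, j in tp_pairs
        ]
        ass_a = float(np.mean(ass_scores))
    else:
        ass_a = 0.0
    return HotaComponents(det_a, ass_a, math.sqrt(det_a * ass_a), tp, fp, fn)


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

def evaluate_trajectories(
    gt: Sequence[Trajectory],
    pred: Sequence[Trajectory],
    iou_threshold: float = 0.5,
    hota_alphas: Sequence[float] | None = None,
) -> dict:
    """Full metric report over in-memory trajectories.

    Degenerate inputs (empty prediction or ground truth) produce 0-valued
    metrics with warnings rather than errors, so batch evaluation survives
    empty clips.
    """
    gt_range = _span(gt)
    pred_range = _span(pred)
    if gt_range and pred_range and gt_range != pred_range:
        log.warning(
            "frame ranges differ (gt %s vs pred %s); evaluating on the union",
            gt_range,
            pred_range,
        )

    clear = clear_match(gt, pred, iou_threshold)
    c = clear.counts
    idtp, idfp, idfn = id_global_assignment(gt, pred, iou_threshold)
    c.IDTP, c.IDFP, c.IDFN = idtp, idfp, idfn
    idf1, idp, idr = idf1_idp_idr(idtp, idfp, idfn)
    h = hota(gt, pred, iou_threshold, alphas=hota_alphas)

    if c.GT > 0:
        mota_v = mota(c)
        mt, ml = mt_ml(clear.coverage)
    else:
        warnings.warn("no ground-truth boxes; reporting 0 metrics")
        mota_v, mt, ml = 0.0, 0.0, 0.0
    if clear.distances:
        motp_v = motp(clear.distances)
    else:
        warnings.warn("no matched pairs; reporting MOTP = 0")
        motp_v = 0.0

    return {
        "schema_version": REPORT_SCHEMA_VERSION,
        "iou_threshold": iou_threshold,
        "mota": mota_v,
        "motp": motp_v,
        "idf1": idf1,
        "idp": idp,
        "idr": idr,
        "mt": mt,
        "ml": ml,
        "hota": h.HOTA,
        "deta": h.DetA,
        "assa": h.AssA,
        "fp": c.FP,
        "fn": c.FN,
        "idsw": c.IDSW,
        "tp": c.TP,
        "gt": c.GT,
        "idtp": c.IDTP,
        "idfp": c.IDFP,
        "idfn": c.IDFN,
        "num_gt_trajectories": len(gt),
        "num_pred_trajectories": len(pred),
    }


def _span(trajs: Sequence[Trajectory]) -> tuple[int, int] | None:
    frames = [f for t in trajs for f in t.boxes]
    if not frames:
        return None
    return min(frames), max(frames)


def evaluate(
    gt_path: str | Path,
    result_path: str | Path,
    iou_threshold: float = 0.5,
    hota_alphas: Sequence[float] | None = None,
) -> dict:
    """Evaluate a result file against a ground-truth file."""
    gt = read_trajectories(gt_path)
    pred = read_trajectories(result_path, use_consider_flag=False)
    return evaluate_trajectories(gt, pred, iou_threshold, hota_alphas)


def write_report(report: dict, json_path: str | Path, csv_path: str | Path | None = None) -> None:
    """Serialise a metric report as JSON and, optionally, one-row CSV."""
    with open(json_path, "w", encoding="utf-8", newline="\n") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    if csv_path is not None:
        keys = sorted(report)
        with open(csv_path, "w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(keys)
            writer.writerow([report[k] for k in keys])
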