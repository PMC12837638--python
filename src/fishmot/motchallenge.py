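"""MOTChallenge CSV dialect I/O.

The dialect is one row per box::

    frame, id, bb_left, bb_top, bb_width, bb_height, conf, x, y, z

Detections carry id = -1; ground-truth and result rows carry a positive
identity.  Files store 1-based pixel coordinates; everything in memory is
0-based continuous, converted here at the boundary.  The world-coordinate
columns (x, y, z) are ignored on read and written as -1.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Sequence
from dataclasses import dataclass
from pathlib import Path

from .boxes import BoundingBox, Detection, Trajectory

log = logging.getLogger(__name__)

_MIN_FIELDS = 7


class MotParseError(ValueError):
    """A malformed row; the message carries the offending line number."""


class MotIntegrityError(ValueError):
    """Structurally valid file violating a dataset invariant."""


@dataclass(frozen=True)
class TrackRecord:
    """One tracker output row: identity + box + score on a frame."""

    frame: int
    identity: int
    box: BoundingBox
    score: float
    coasted: bool = False


def _parse_fields(line: str, lineno: int) -> list[float]:
    parts = line.split(",")
    if len(parts) < _MIN_FIELDS:
        raise MotParseError(
            f"line {lineno}: expected >= {_MIN_FIELDS} comma-separated fields, "
            f"got {len(parts)}: {line!r}"
        )
    try:
        return [float(p) for p in parts[:_MIN_FIELDS]]
    except ValueError as exc:
        raise MotParseError(f"line {lineno}: non-numeric field ({exc})") from None


def read_detections(path: str | Path) -> list[Detection]:
    """Read a detection file, ordered by frame then file order.

    Rows with non-positive width/height are rejected; their count is
    reported through the module logger.
    """
    detections: list[tuple[int, int, Detection]] = []
    rejected = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            f = _parse_fields(line, lineno)
            frame = int(f[0])
            if frame < 1:
                raise MotParseError(f"line {lineno}: frame must be >= 1, got {frame}")
            if f[4] <= 0 or f[5] <= 0:
                rejected += 1
                continue
            box = BoundingBox(f[2] - 1.0, f[3] - 1.0, f[4], f[5])
            score = min(max(f[6], 0.0), 1.0)
            detections.append((frame, lineno, Detection(frame, box, score)))
    if rejected:
        log.warning("%s: rejected %d rows with non-positive box dimensions", path, rejected)
    detections.sort(key=lambda t: (t[0], t[1]))
    return [d for _, _, d in detections]


def read_trajectories(path: str | Path, *, use_consider_flag: bool = True) -> list[Trajectory]:
    """Read a ground-truth or result file into per-identity trajectories.

    In ground-truth files the conf column doubles as a consider/visibility
    flag: rows with conf == 0 are skipped when *use_consider_flag* is true.
    Duplicate (frame, id) pairs are an integrity error.
    """
    trajs: dict[int, Trajectory] = {}
    rejected = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            f = _parse_fields(line, lineno)
            frame, ident = int(f[0]), int(f[1])
            if frame < 1:
                raise MotParseError(f"line {lineno}: frame must be >= 1, got {frame}")
            if ident < 1:
                raise MotParseError(
                    f"line {lineno}: identity must be positive, got {ident}"
                )
            if use_consider_flag and f[6] == 0:
                continue
            if f[4] <= 0 or f[5] <= 0:
                rejected += 1
                continue
            traj = trajs.setdefault(ident, Trajectory(ident))
            if frame in traj.boxes:
                raise MotIntegrityError(
                    f"line {lineno}: duplicate (frame={frame}, id={ident}) row"
                )
            traj.boxes[frame] = BoundingBox(f[2] - 1.0, f[3] - 1.0, f[4], f[5])
    if rejected:
        log.warning("%s: rejected %d rows with non-positive box dimensions", path, rejected)
    return [trajs[i] for i in sorted(trajs)]


# gt and result files share the dialect; keep both names at the surface.
read_ground_truth = read_trajectories


def write_tracks(records: Iterable[TrackRecord], path: str | Path) -> None:
    """Write result records in the MOTChallenge result dialect.

    Rows are sorted by (frame, id) and formatted with fixed precision so a
    given input always produces byte-identical output.
    """
    rows = sorted(records, key=lambda r: (r.frame, r.identity))
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for r in rows:
            if r.identity < 1:
                raise ValueError(f"identity must be positive, got {r.identity}")
            b = r.box
            fh.write(
                f"{r.frame},{r.identity},{b.left + 1.0:.2f},{b.top + 1.0:.2f},"
                f"{b.width:.2f},{b.height:.2f},{r.score:.4f},-1,-1,-1\n"
            )


def write_trajectories(trajs: Sequence[Trajectory], path: str | Path) -> None:
    """Write trajectories in the ground-truth dialect (conf = 1)."""
    rows: list[tuple[int, int, BoundingBox]] = []
    for t in trajs:
        rows.extend((frame, t.identity, box) for frame, box in t.boxes.items())
    rows.sort()
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for frame, ident, b in rows:
            fh.write(
                f"{frame},{ident},{b.left + 1.0:.2f},{b.top + 1.0:.2f},"
                f"{b.width:.2f},{b.height:.2f},1,-1,-1,-1\n"
            )


def write_detections(dets: Sequence[Detection], path: str | Path) -> None:
    """Write detections (id = -1) in the detection dialect."""
    rows = sorted(range(len(dets)), key=lambda i: (dets[i].frame, i))
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for i in rows:
            d = dets[i]
            b = d.box
            fh.write(
                f"{d.frame},-1,{b.left + 1.0:.2f},{b.top + 1.0:.2f},"
                f"{b.width:.2f},{b.height:.2f},{d.score:.4f},-1,-1,-1\n"
            )


def records_to_trajectories(records: Iterable[TrackRecord]) -> list[Trajectory]:
    """Group result records into per-identity trajectories."""
    trajs: dict[int, Trajectory] = {}
    for r in records:
        traj = trajs.setdefault(r.identity, Trajectory(r.identity))
        if r.frame in traj.boxes:
            raise MotIntegrityError(
                f"duplicate (frame={r.frame}, id={r.identity}) record"
            )
        traj.boxes[r.frame] = r.box
    return [trajs[i] for i in sorted(trajs)]


def group_by_frame(
    detections: Sequence[Detection], frame_range: tuple[int, int] | None = None
) -> list[tuple[int, list[Detection]]]:
    """Bucket detections per frame over a contiguous frame range.

    Frames without detections yield empty lists, so a tracker stepping over
    the result still ages (and eventually purges) coasting tracks.
    """
    if not detections and frame_range is None:
        return []
    if frame_range is None:
        frame_range = (min(d.frame for d in detections), max(d.frame for d in detections))
    lo, hi = frame_range
    buckets: dict[int, list[Detection]] = {f: [] for f in range(lo, hi + 1)}
    for d in detections:
        buckets.setdefault(d.frame, []).append(d)
    return [(f, buckets[f]) for f in sorted(buckets)]
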