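"""Online cascade-correspondence tracker.

Each frame runs three association stages in a fixed order — motion
consistency (Mahalanobis under the Kalman prediction), IoU overlap, and
centroid distance — where every stage only sees the tracks and detections
left unmatched by the stages before it.  Matched tracks are corrected with
the detection; leftover high-confidence detections found new tracks;
leftover tracks coast on the motion model with a decayed score until they
either rematch or have missed more than ``max_age`` consecutive frames, at
which point they are purged and their identity is retired for good.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import yaml

from .affinity import Stage, StageGates, build_cost_matrix, solve_assignment
from .boxes import BoundingBox, Detection
from .kalman import CHI2_GATE_95_4DOF, KalmanBoxFilter, TrackState
from .motchallenge import TrackRecord

log = logging.getLogger(__name__)

CASCADE_ORDER: tuple[Stage, ...] = (Stage.MOTION, Stage.IOU, Stage.DISTANCE)


@dataclass
class TrackerConfig:
    """All tracker knobs.

    theta_new: minimum detection score to found a new track (track_thresh).
    pre_thresh: floor on ingested detection scores; weaker detections are
        discarded before any matching.
    max_age: a track is purged once it has missed *more than* this many
        consecutive frames (3 frames of misses survive; the 4th purges).
    decay_factor: multiplicative per-frame score decay while coasting.
    """

    theta_new: float = 0.4
    pre_thresh: float = 0.4
    max_age: int = 3
    decay_factor: float = 0.9
    motion_gate: float = CHI2_GATE_95_4DOF
    iou_gate: float = 0.1
    dist_gate_factor: float = 1.0
    std_pos_weight: float = 1.0 / 20
    std_vel_weight: float = 1.0 / 160
    suppress_coasted: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.theta_new <= 1.0:
            raise ValueError(f"theta_new must lie in [0, 1], got {self.theta_new}")
        if self.max_age < 0:
            raise ValueError(f"max_age must be >= 0, got {self.max_age}")
        if not 0.0 < self.decay_factor <= 1.0:
            raise ValueError(f"decay_factor must lie in (0, 1], got {self.decay_factor}")

    @property
    def gates(self) -> StageGates:
        return StageGates(self.motion_gate, self.iou_gate, self.dist_gate_factor)

    @classmethod
    def from_mapping(cls, mapping: dict) -> "TrackerConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown tracker config keys: {sorted(unknown)}")
        return cls(**mapping)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TrackerConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_mapping(data)

    def to_mapping(self) -> dict:
        return {f: getattr(self, f) for f in self.__dataclass_fields__}


@dataclass
class Track:
    """Identity-bearing tracker state."""

    identity: int
    state: TrackState
    score: float
    last_box: BoundingBox
    misses: int = 0
    age: int = 1


class CascadeTracker:
    """Stateful per-sequence tracker; feed frames in increasing order."""

    def __init__(self, config: TrackerConfig | None = None) -> None:
        self.config = config or TrackerConfig()
        self.kf = KalmanBoxFilter(
            std_pos_weight=self.config.std_pos_weight,
            std_vel_weight=self.config.std_vel_weight,
        )
        self.tracks: list[Track] = []
        self._next_identity = 1
        self._last_frame: int | None = None

    # -- cascade -------------------------------------------------------

    def match(
        self,
        stage: Stage,
        detections: list[Detection],
        matched_tracks: set[int],
        matched_dets: set[int],
    ) -> list[tuple[int, int]]:
        """Run one stage over the yet-unmatched tracks and detections.

        Returns (track index, detection index) pairs in the caller's full
        index space and augments the matched sets in place.
        """
        t_idx = [i for i in range(len(self.tracks)) if i not in matched_tracks]
        d_idx = [j for j in range(len(detections)) if j not in matched_dets]
        if not t_idx or not d_idx:
            return []
        costs = build_cost_matrix(
            stage,
            self.kf,
            [self.tracks[i].state for i in t_idx],
            [detections[j].box for j in d_idx],
            self.config.gates,
            ref_boxes=[self.tracks[i].last_box for i in t_idx],
        )
        result = solve_assignment(costs)
        pairs = [(t_idx[r], d_idx[c]) for r, c in result.pairs]
        matched_tracks.update(r for r, _ in pairs)
        matched_dets.update(c for _, c in pairs)
        return pairs

    # -- lifecycle ------------------------------------------------------

    def step(self, frame: int, detections: list[Detection]) -> list[TrackRecord]:
        """Advance one frame; returns this frame's output records."""
        if self._last_frame is not None and frame <= self._last_frame:
            raise ValueError(
                f"frames must be strictly increasing: got {frame} after {self._last_frame}"
            )
        self._last_frame = frame

        detections = self._ingest(frame, detections)

        # (i) propagate every live track one frame
        for tr in self.tracks:
            tr.state = self.kf.predict(tr.state)
            tr.age += 1

        # (ii) cascade over the fixed stage order
        matched_tracks: set[int] = set()
        matched_dets: set[int] = set()
        pairs: list[tuple[int, int]] = []
        for stage in CASCADE_ORDER:
            pairs.extend(self.match(stage, detections, matched_tracks, matched_dets))

        output: list[TrackRecord] = []

        # (iii) correct matched tracks; the emitted box is the detection's
        for ti, dj in pairs:
            tr = self.tracks[ti]
            det = detections[dj]
            tr.state = self.kf.update(tr.state, det.box)
            tr.score = det.score
            tr.misses = 0
            tr.last_box = det.box
            output.append(TrackRecord(frame, tr.identity, det.box, det.score))

        # (iv) leftover confident detections found new tracks
        for dj, det in enumerate(detections):
            if dj in matched_dets:
                continue
            if det.score > self.config.theta_new:
                tr = Track(
                    identity=self._next_identity,
                    state=self.kf.init_state(det.box),
                    score=det.score,
                    last_box=det.box,
                )
                self._next_identity += 1
                self.tracks.append(tr)
                output.append(TrackRecord(frame, tr.identity, det.box, det.score))

        # (v) unmatched tracks coast with decayed score, or are purged
        emitted = {r.identity for r in output}  # matched or newborn this frame
        survivors: list[Track] = []
        for tr in self.tracks:
            if tr.identity in emitted:
                survivors.append(tr)
                continue
            decay_score(tr, self.config)
            if tr.misses > self.config.max_age:
                continue  # purged; identity retired
            survivors.append(tr)
            box = tr.state.predicted_box()
            output.append(TrackRecord(frame, tr.identity, box, tr.score, coasted=True))
        self.tracks = survivors

        output.sort(key=lambda r: r.identity)
        return output

    def _ingest(self, frame: int, detections: list[Detection]) -> list[Detection]:
        kept: list[Detection] = []
        for det in detections:
            b = det.box
            if not all(
                math.isfinite(v) for v in (b.left, b.top, b.width, b.height, det.score)
            ):
                log.warning("frame %d: rejected non-finite detection %r", frame, det)
                continue
            if det.score < self.config.pre_thresh:
                continue
            kept.append(det)
        return kept


def decay_score(track: Track, config: TrackerConfig) -> Track:
    """One missed frame: multiply the score down and count the miss."""
    track.score *= config.decay_factor
    track.misses += 1
    return track


def run_sequence(
    frames: Iterable[tuple[int, list[Detection]]],
    config: TrackerConfig | None = None,
) -> list[TrackRecord]:
    """Track a whole sequence of (frame, detections) pairs.

    Deterministic given input and config.  Coasted records are filtered out
    when ``config.suppress_coasted`` (the default); they would otherwise
    count as false positives under standard evaluation.
    """
    config = config or TrackerConfig()
    tracker = CascadeTracker(config)
    records: list[TrackRecord] = []
    for frame, dets in frames:
        records.extend(tracker.step(frame, dets))
    if config.suppress_coasted:
        records = [r for r in records if not r.coasted]
    return records
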