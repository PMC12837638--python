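"""Seeded fish-school scene generator.

Produces ground-truth trajectories for a school of fish in a fixed camera
view (1920 x 1080 by default, 30 FPS, short 25-frame clips, up to 75
simultaneously visible fish — the recording conditions of a dense grass-carp
aquaculture tank) and a corrupted detection stream derived from them with
the failure modes a tracker must survive: coordinate jitter, detection
dropout, occlusion-conditional dropout (the rear fish of an overlapping pair
disappears), clutter, and targets leaving the frame.

Motion is a minimal zonal schooling model (repulsion / alignment /
attraction on headings with a capped turn rate); body boxes are
heading-dependent with a sinusoidal tail-beat aspect modulation, standing in
for the non-rigid deformation of swimming fish.  Everything is deterministic
for a fixed seed: the scene seed spawns one child RNG stream per fish plus
dedicated streams for corruption and clutter.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .affinity import iou
from .boxes import BoundingBox, Detection, Trajectory
from .motchallenge import write_detections, write_trajectories


@dataclass(frozen=True)
class SimConfig:
    """Scene parameters; defaults emulate the dense-tank recording setup."""

    n_fish: int = 75
    arena_width: float = 1920.0
    arena_height: float = 1080.0
    fps: float = 30.0
    n_frames: int = 25
    # 8-25 cm total length mapped to 40-160 px box heights
    body_length_range: tuple[float, float] = (40.0, 160.0)
    speed_range: tuple[float, float] = (60.0, 240.0)  # px/s
    schooling_strength: float = 0.5
    turn_rate_cap: float = 0.3  # rad/frame
    heading_noise: float = 0.05  # rad/frame std
    tail_beat_amplitude: float = 0.15  # fractional aspect modulation
    tail_beat_frequency: float = 3.0  # Hz
    allow_exit: bool = True
    # corruption
    coord_noise_sigma: float = 0.0  # px, Gaussian on box corners
    miss_probability: float = 0.0  # independent per-box dropout
    occlusion_iou_threshold: float = 0.4
    occlusion_drop_probability: float = 0.0  # smaller box of overlapped pair
    clutter_rate: float = 0.0  # Poisson mean false boxes per frame
    base_score: float = 1.0
    jitter_score_penalty: float = 2.0  # per unit (jitter / diagonal)
    overlap_score_penalty: float = 0.3  # times max IoU with another fish
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_fish < 1:
            raise ValueError("n_fish must be >= 1")
        if self.arena_width <= 0 or self.arena_height <= 0:
            raise ValueError("arena dimensions must be positive")
        for name in ("miss_probability", "occlusion_drop_probability"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")

    def to_json_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["body_length_range"] = list(self.body_length_range)
        d["speed_range"] = list(self.speed_range)
        return d

    @classmethod
    def from_json_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        d["body_length_range"] = tuple(d["body_length_range"])
        d["speed_range"] = tuple(d["speed_range"])
        return cls(**d)


#: clip archetype presets; they differ in corruption parameters (plus a
#: stronger tail beat for the deformation archetype).
PRESETS: dict[str, dict] = {
    "zero-corruption": {},
    "normal": {
        "coord_noise_sigma": 1.0,
        "miss_probability": 0.03,
        "occlusion_drop_probability": 0.3,
        "clutter_rate": 0.5,
    },
    "mf25-like": {
        "coord_noise_sigma": 2.0,
        "miss_probability": 0.06,
        "occlusion_drop_probability": 0.5,
        "clutter_rate": 1.0,
    },
    "severe-occlusion": {
        "coord_noise_sigma": 2.0,
        "miss_probability": 0.06,
        "occlusion_iou_threshold": 0.25,
        "occlusion_drop_probability": 0.85,
        "clutter_rate": 1.0,
    },
    "severely-deformed": {
        "coord_noise_sigma": 5.0,
        "miss_probability": 0.06,
        "occlusion_drop_probability": 0.4,
        "clutter_rate": 1.0,
        "tail_beat_amplitude": 0.3,
    },
    "multi-density": {
        "coord_noise_sigma": 2.0,
        "miss_probability": 0.1,
        "occlusion_iou_threshold": 0.3,
        "occlusion_drop_probability": 0.6,
        "clutter_rate": 2.0,
    },
}


def preset_config(name: str, **overrides) -> SimConfig:
    """Build a :class:`SimConfig` from a named archetype plus overrides."""
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; available: {sorted(PRESETS)}")
    params = dict(PRESETS[name])
    params.update(overrides)
    return SimConfig(**params)


@dataclass
class SimScene:
    config: SimConfig
    gt: list[Trajectory]
    detections: dict[int, list[Detection]]
    events: list[dict] = field(default_factory=list)


# ---------------------------------------------------------------------------
# School motion
# ---------------------------------------------------------------------------

_ZONE_REPULSION = 60.0
_ZONE_ALIGNMENT = 180.0
_ZONE_ATTRACTION = 450.0
_WALL_MARGIN = 80.0


def _fish_box(x: float, y: float, length: float, heading: float, beat: float) -> BoundingBox:
    # heading-dependent extent: a horizontal swimmer is wide, a vertical one tall
    w = length * (0.30 + 0.60 * abs(math.cos(heading))) * beat
    h = length * (0.30 + 0.60 * abs(math.sin(heading))) / beat
    return BoundingBox(x - w / 2.0, y - h / 2.0, max(w, 2.0), max(h, 2.0))


def _clip_box(b: BoundingBox, cfg: SimConfig) -> BoundingBox:
    left = max(b.left, 0.0)
    top = max(b.top, 0.0)
    right = min(b.right, cfg.arena_width)
    bottom = min(b.bottom, cfg.arena_height)
    return BoundingBox(left, top, max(right - left, 1.0), max(bottom - top, 1.0))


def simulate_school(config: SimConfig) -> tuple[list[Trajectory], list[dict]]:
    """Generate ground-truth trajectories; returns (trajectories, events).

    Fish whose centre leaves the arena are marked exited and do not return
    within the clip (exits are absorbing), so a ground-truth trajectory is a
    single contiguous lifespan.
    """
    rng_root = np.random.SeedSequence(config.seed)
    fish_rngs = [np.random.default_rng(s) for s in rng_root.spawn(config.n_fish)]

    n = config.n_fish
    lo_l, hi_l = config.body_length_range
    lo_s, hi_s = config.speed_range
    dt = 1.0 / config.fps

    length = np.empty(n)
    speed = np.empty(n)
    heading = np.empty(n)
    phase = np.empty(n)
    pos = np.empty((n, 2))
    margin = 0.08
    for i, rng in enumerate(fish_rngs):
        length[i] = rng.uniform(lo_l, hi_l)
        speed[i] = rng.uniform(lo_s, hi_s)
        heading[i] = rng.uniform(-math.pi, math.pi)
        phase[i] = rng.uniform(0, 2 * math.pi)
        pos[i, 0] = rng.uniform(margin * config.arena_width, (1 - margin) * config.arena_width)
        pos[i, 1] = rng.uniform(margin * config.arena_height, (1 - margin) * config.arena_height)

    alive = np.ones(n, dtype=bool)
    trajs = [Trajectory(i + 1) for i in range(n)]
    events: list[dict] = []

    for frame in range(1, config.n_frames + 1):
        # record boxes first, then advance
        t = (frame - 1) * dt
        for i in range(n):
            if not alive[i]:
                continue
            beat = 1.0 + config.tail_beat_amplitude * math.sin(
                2 * math.pi * config.tail_beat_frequency * t + phase[i]
            )
            box = _fish_box(pos[i, 0], pos[i, 1], length[i], heading[i], beat)
            trajs[i].boxes[frame] = _clip_box(box, config)

        if frame == config.n_frames:
            break

        new_heading = heading.copy()
        for i in range(n):
            if not alive[i]:
                continue
            steer = np.zeros(2)
            if config.schooling_strength > 0:
                rep = np.zeros(2)
                ali = np.zeros(2)
                att = np.zeros(2)
                n_att = 0
                for j in range(n):
                    if j == i or not alive[j]:
                        continue
                    d = pos[j] - pos[i]
                    dist = math.hypot(d[0], d[1])
                    if dist < 1e-9:
                        continue
                    if dist < _ZONE_REPULSION:
                        rep -= d / (dist * dist)
                    elif dist < _ZONE_ALIGNMENT:
                        ali += np.array([math.cos(heading[j]), math.sin(heading[j])])
                    elif dist < _ZONE_ATTRACTION:
                        att += d / dist
                        n_att += 1
                if n_att:
                    att /= n_att
                steer = config.schooling_strength * (
                    2.0 * rep * _ZONE_REPULSION + 1.0 * ali + 0.5 * att
                )
            # wall avoidance: steer toward the interior near the boundary
            # (soft when exits are allowed, so fast fish can still leave)
            wall = np.zeros(2)
            if pos[i, 0] < _WALL_MARGIN:
                wall[0] += 1.0
            elif pos[i, 0] > config.arena_width - _WALL_MARGIN:
                wall[0] -= 1.0
            if pos[i, 1] < _WALL_MARGIN:
                wall[1] += 1.0
            elif pos[i, 1] > config.arena_height - _WALL_MARGIN:
                wall[1] -= 1.0
            weight = 1.5 if config.allow_exit else 3.0
            steer = steer + weight * wall

            if np.any(steer != 0.0):
                desired = math.atan2(
                    math.sin(heading[i]) + steer[1], math.cos(heading[i]) + steer[0]
                )
                turn = _wrap_angle(desired - heading[i])
            else:
                turn = 0.0
            turn += (
                fish_rngs[i].normal(0.0, config.heading_noise)
                if config.heading_noise > 0
                else 0.0
            )
            turn = float(np.clip(turn, -config.turn_rate_cap, config.turn_rate_cap))
            new_heading[i] = _wrap_angle(heading[i] + turn)

        heading = new_heading
        for i in range(n):
            if not alive[i]:
                continue
            step = speed[i] * dt
            pos[i, 0] += step * math.cos(heading[i])
            pos[i, 1] += step * math.sin(heading[i])
        _separate_bodies(pos, length, alive)
        for i in range(n):
            if not alive[i]:
                continue
            outside = not (
                0.0 <= pos[i, 0] <= config.arena_width
                and 0.0 <= pos[i, 1] <= config.arena_height
            )
            if outside:
                if config.allow_exit:
                    alive[i] = False
                    events.append(
                        {"frame": frame + 1, "type": "exit", "identity": i + 1}
                    )
                else:
                    # reflect off the wall, clamp inside
                    if pos[i, 0] < 0 or pos[i, 0] > config.arena_width:
                        heading[i] = _wrap_angle(math.pi - heading[i])
                    if pos[i, 1] < 0 or pos[i, 1] > config.arena_height:
                        heading[i] = _wrap_angle(-heading[i])
                    pos[i, 0] = float(np.clip(pos[i, 0], 1.0, config.arena_width - 1.0))
                    pos[i, 1] = float(np.clip(pos[i, 1], 1.0, config.arena_height - 1.0))

    return [t for t in trajs if t.boxes], events


def _wrap_angle(a: float) -> float:
    return math.atan2(math.sin(a), math.cos(a))


_MIN_SEP_FRACTION = 0.35  # of the pair's mean body length


def _separate_bodies(pos: np.ndarray, length: np.ndarray, alive: np.ndarray) -> None:
    """Push overlapping fish apart: projected body centres cannot coincide.

    A few symmetric relaxation passes resolve pairwise overlaps below a
    body-length-scaled minimum separation; this is the solid-body constraint
    of a shallow school (boxes may still overlap heavily — fish are long)."""
    n = len(pos)
    for _ in range(3):
        moved = False
        for i in range(n):
            if not alive[i]:
                continue
            for j in range(i + 1, n):
                if not alive[j]:
                    continue
                min_sep = _MIN_SEP_FRACTION * (length[i] + length[j]) / 2.0
                d = pos[j] - pos[i]
                dist = math.hypot(d[0], d[1])
                if dist >= min_sep:
                    continue
                if dist < 1e-9:
                    ang = 2.399963 * (i + 1)  # deterministic fallback direction
                    u = np.array([math.cos(ang), math.sin(ang)])
                else:
                    u = d / dist
                push = (min_sep - dist) / 2.0
                pos[i] -= u * push
                pos[j] += u * push
                moved = True
        if not moved:
            break


# ---------------------------------------------------------------------------
# Detection corruption
# ---------------------------------------------------------------------------

def corrupt(
    gt: list[Trajectory], config: SimConfig
) -> tuple[dict[int, list[Detection]], list[dict]]:
    """Derive a corrupted detection stream from ground truth.

    Per box: Gaussian corner jitter, independent dropout, and an additional
    occlusion dropout for the smaller box of a strongly overlapped pair (a
    2-D depth proxy: the rear fish is hidden).  Poisson clutter boxes with
    low scores are added per frame.  Detection scores start from
    ``base_score`` and lose jitter and overlap penalties, clipped to [0, 1].
    """
    root = np.random.SeedSequence(config.seed)
    # streams 0..n-1 are per-fish (used by the school); corruption uses
    # dedicated streams derived from the same scene seed
    children = root.spawn(config.n_fish + 2)
    rng = np.random.default_rng(children[config.n_fish])
    clutter_rng = np.random.default_rng(children[config.n_fish + 1])

    frames = sorted({f for t in gt for f in t.boxes})
    detections: dict[int, list[Detection]] = {f: [] for f in frames}
    events: list[dict] = []

    for frame in frames:
        present = [(t.identity, t.boxes[frame]) for t in gt if frame in t.boxes]
        # occlusion: the smaller of a strongly overlapping pair may vanish
        occluded: set[int] = set()
        if config.occlusion_drop_probability > 0:
            for a in range(len(present)):
                for b in range(a + 1, len(present)):
                    ia, ba = present[a]
                    ib, bb = present[b]
                    if iou(ba, bb) > config.occlusion_iou_threshold:
                        victim = ia if ba.area <= bb.area else ib
                        if rng.uniform() < config.occlusion_drop_probability:
                            occluded.add(victim)
                            events.append(
                                {
                                    "frame": frame,
                                    "type": "occlusion_drop",
                                    "identity": victim,
                                }
                            )
        for ident, box in present:
            if ident in occluded:
                continue
            if config.miss_probability > 0 and rng.uniform() < config.miss_probability:
                events.append({"frame": frame, "type": "dropout", "identity": ident})
                continue
            if config.coord_noise_sigma > 0:
                j = rng.normal(0.0, config.coord_noise_sigma, size=4)
            else:
                j = np.zeros(4)
            left = box.left + j[0]
            top = box.top + j[1]
            right = box.right + j[2]
            bottom = box.bottom + j[3]
            w = max(right - left, 2.0)
            h = max(bottom - top, 2.0)
            noisy = BoundingBox(left, top, w, h)
            max_overlap = max(
                (iou(box, ob) for oid, ob in present if oid != ident), default=0.0
            )
            jitter_mag = float(np.mean(np.abs(j))) / box.diagonal
            score = (
                config.base_score
                - config.jitter_score_penalty * jitter_mag
                - config.overlap_score_penalty * max_overlap
            )
            score = float(np.clip(score, 0.0, 1.0))
            detections[frame].append(Detection(frame, noisy, score))
        if config.clutter_rate > 0:
            k = clutter_rng.poisson(config.clutter_rate)
            for _ in range(int(k)):
                w = clutter_rng.uniform(20.0, 120.0)
                h = clutter_rng.uniform(20.0, 120.0)
                x = clutter_rng.uniform(0.0, config.arena_width - w)
                y = clutter_rng.uniform(0.0, config.arena_height - h)
                s = float(clutter_rng.uniform(0.05, 0.6))
                detections[frame].append(Detection(frame, BoundingBox(x, y, w, h), s))
                events.append({"frame": frame, "type": "clutter"})
    return detections, events


def make_scene(config: SimConfig, out_dir: str | Path | None = None) -> SimScene:
    """Generate a full scene; optionally write gt.txt / det.txt / scene.json.

    The JSON sidecar holds the complete config (seed included); replaying it
    through :func:`load_scene_config` reproduces the files byte-identically.
    """
    gt, school_events = simulate_school(config)
    detections, corr_events = corrupt(gt, config)
    scene = SimScene(config, gt, detections, school_events + corr_events)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_trajectories(gt, out / "gt.txt")
        flat = [d for f in sorted(detections) for d in detections[f]]
        write_detections(flat, out / "det.txt")
        with open(out / "scene.json", "w", encoding="utf-8", newline="\n") as fh:
            json.dump(config.to_json_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")
    return scene


def load_scene_config(sidecar_path: str | Path) -> SimConfig:
    with open(sidecar_path, encoding="utf-8") as fh:
        return SimConfig.from_json_dict(json.load(fh))
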