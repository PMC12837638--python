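import numpy as np
import pytest

from fishmot.boxes import BoundingBox, Detection
from fishmot.tracker import CascadeTracker, TrackerConfig, decay_score, run_sequence


def det(frame, left, top, w=20.0, h=30.0, score=0.9):
    return Detection(frame, BoundingBox(left, top, w, h), score)


def test_confident_detection_spawns_track():
    trk = CascadeTracker(TrackerConfig())
    out = trk.step(1, [det(1, 10, 10, score=0.9)])
    assert len(out) == 1
    assert out[0].identity == 1
    assert not out[0].coasted


def test_weak_detection_below_theta_ignored():
    trk = CascadeTracker(TrackerConfig(pre_thresh=0.0))
    out = trk.step(1, [det(1, 10, 10, score=0.3)])
    assert out == []
    assert trk.tracks == []


def test_pre_thresh_floors_detections_before_matching():
    trk = CascadeTracker(TrackerConfig(pre_thresh=0.4))
    trk.step(1, [det(1, 10, 10, score=0.9)])
    # a weak detection at the track position is invisible: track coasts
    out = trk.step(2, [det(2, 10, 10, score=0.2)])
    assert all(r.coasted for r in out)


def test_track_survives_exactly_three_misses_and_rematches():
    trk = CascadeTracker(TrackerConfig(max_age=3))
    trk.step(1, [det(1, 100, 100)])
    for f in (2, 3, 4):
        out = trk.step(f, [])
        assert [r.identity for r in out if r.coasted] == [1]
    out = trk.step(5, [det(5, 100, 100)])
    assert [r.identity for r in out] == [1]
    assert not out[0].coasted


def test_track_purged_after_four_misses_identity_never_reused():
    trk = CascadeTracker(TrackerConfig(max_age=3))
    trk.step(1, [det(1, 100, 100)])
    for f in (2, 3, 4):
        trk.step(f, [])
    out = trk.step(5, [])  # fourth consecutive miss: purged
    assert out == []
    assert trk.tracks == []
    out = trk.step(6, [det(6, 100, 100)])
    assert [r.identity for r in out] == [2]  # fresh identity, never 1 again


def test_decay_score_closed_form():
    cfg = TrackerConfig(decay_factor=0.9)
    trk = CascadeTracker(cfg)
    trk.step(1, [det(1, 10, 10, score=0.8)])
    tr = trk.tracks[0]
    decay_score(tr, cfg)
    assert tr.score == pytest.approx(0.72)
    assert tr.misses == 1


def test_decay_factor_one_keeps_score():
    cfg = TrackerConfig(decay_factor=1.0)
    trk = CascadeTracker(cfg)
    trk.step(1, [det(1, 10, 10, score=0.8)])
    decay_score(trk.tracks[0], cfg)
    assert trk.tracks[0].score == 0.8


def test_k_misses_give_geometric_decay():
    cfg = TrackerConfig(decay_factor=0.85, max_age=10)
    trk = CascadeTracker(cfg)
    trk.step(1, [det(1, 100, 100, score=1.0)])
    for f in range(2, 8):
        trk.step(f, [])
    assert trk.tracks[0].score == pytest.approx(0.85 ** 6)


def test_two_separated_constant_velocity_targets_tracked_exactly():
    frames = []
    for f in range(1, 11):
        a = det(f, 100 + 5 * (f - 1), 100, score=1.0)
        b = det(f, 800, 500 + 4 * (f - 1), score=1.0)
        frames.append((f, [a, b]))
    records = run_sequence(frames, TrackerConfig())
    ids = {r.identity for r in records}
    assert len(ids) == 2
    # output boxes equal the detections exactly (matched boxes are emitted)
    by_frame = {}
    for r in records:
        by_frame.setdefault(r.frame, []).append(r)
    for f, dets in frames:
        got = sorted((r.box.left, r.box.top) for r in by_frame[f])
        want = sorted((d.box.left, d.box.top) for d in dets)
        assert got == pytest.approx(want, abs=1e-6)
    # identities are stable over time
    first = {r.identity: r.box.left for r in by_frame[1]}
    last = {r.identity: r.box.left for r in by_frame[10]}
    moving = min(first, key=first.get)
    assert last[moving] == pytest.approx(100 + 45)


def test_cascade_second_stage_recovers_motion_failure():
    """A detection far in Mahalanobis terms but overlapping in IoU is caught
    by the second stage, yielding one match overall."""
    cfg = TrackerConfig(motion_gate=1e-6, pre_thresh=0.0)  # motion stage can't match
    trk = CascadeTracker(cfg)
    trk.step(1, [det(1, 100, 100, 40, 40, score=0.9)])
    out = trk.step(2, [det(2, 110, 110, 40, 40, score=0.9)])  # IoU ~ 0.39
    assert [r.identity for r in out] == [1]
    assert not out[0].coasted


def test_stage_match_respects_accumulated_matched_sets():
    from fishmot.affinity import Stage

    trk = CascadeTracker(TrackerConfig())
    trk.step(1, [det(1, 100, 100), det(1, 500, 500)])
    dets = [det(2, 100, 100), det(2, 500, 500)]
    # with every track already claimed by earlier stages, nothing can match
    assert trk.match(Stage.MOTION, dets, {0, 1}, set()) == []


def test_partition_property_every_frame(rng):
    cfg = TrackerConfig(pre_thresh=0.0, theta_new=0.4)
    trk = CascadeTracker(cfg)
    for f in range(1, 30):
        n = int(rng.integers(0, 6))
        dets = [
            det(f, rng.uniform(0, 800), rng.uniform(0, 500), score=float(rng.uniform(0.2, 1.0)))
            for _ in range(n)
        ]
        live_before = {t.identity for t in trk.tracks}
        out = trk.step(f, dets)
        live_after = {t.identity for t in trk.tracks}
        emitted = [r.identity for r in out]
        # no identity appears twice in one frame's output
        assert len(emitted) == len(set(emitted))
        # every surviving previous track is emitted (matched or coasted) or purged
        for ident in live_before:
            assert ident in emitted or ident not in live_after
        # identities strictly increase; never reused
        assert max(live_after, default=0) <= trk._next_identity - 1


def test_out_of_order_frame_rejected():
    trk = CascadeTracker(TrackerConfig())
    trk.step(5, [])
    with pytest.raises(ValueError, match="increasing"):
        trk.step(5, [])


def test_run_sequence_empty_and_deterministic():
    assert run_sequence([], TrackerConfig()) == []
    frames = [(f, [det(f, 50 + f, 60, score=1.0)]) for f in range(1, 6)]
    a = run_sequence(frames, TrackerConfig())
    b = run_sequence(frames, TrackerConfig())
    assert a == b


def test_perfect_scene_recovered_up_to_relabeling():
    from fishmot.metrics import evaluate_trajectories
    from fishmot.motchallenge import records_to_trajectories
    from fishmot.sim import make_scene, preset_config

    cfg = preset_config("zero-corruption", seed=5, n_fish=15)
    scene = make_scene(cfg)
    frames = [(f, scene.detections.get(f, [])) for f in range(1, cfg.n_frames + 1)]
    records = run_sequence(frames, TrackerConfig())
    report = evaluate_trajectories(scene.gt, records_to_trajectories(records))
    assert report["mota"] == 1.0
    assert report["idf1"] == 1.0
    assert report["idsw"] == 0
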