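import warnings

import numpy as np
import pytest

from fishmot.boxes import BoundingBox, Trajectory
from fishmot.metrics import (
    MetricCounts,
    clear_match,
    evaluate_trajectories,
    hota,
    id_global_assignment,
    idf1_idp_idr,
    mota,
    motp,
    mt_ml,
)

from oracles import clear_oracle, id_counts_oracle, random_micro_scene


def traj(ident, frame_boxes):
    return Trajectory(ident, {f: BoundingBox(*b) for f, b in frame_boxes.items()})


def straight(ident, n_frames, x0=0.0, y0=0.0, dx=5.0, w=10.0, h=10.0):
    return traj(ident, {f: (x0 + dx * (f - 1), y0, w, h) for f in range(1, n_frames + 1)})


def test_clear_perfect_prediction():
    gt = [straight(1, 5), straight(2, 5, y0=100)]
    res = clear_match(gt, gt)
    c = res.counts
    assert (c.FP, c.FN, c.IDSW) == (0, 0, 0)
    assert c.TP == c.GT == 10


def test_clear_empty_prediction():
    gt = [straight(1, 4)]
    res = clear_match(gt, [])
    c = res.counts
    assert c.FN == c.GT == 4
    assert c.FP == 0 and c.IDSW == 0


def test_clear_identity_switch_hand_trace():
    gt = [straight(1, 4)]
    pred = [
        traj(10, {f: (5.0 * (f - 1), 0, 10, 10) for f in (1, 2)}),
        traj(20, {f: (5.0 * (f - 1), 0, 10, 10) for f in (3, 4)}),
    ]
    res = clear_match(gt, pred)
    assert res.counts.IDSW == 1
    assert res.counts.FN == 0 and res.counts.FP == 0


def test_clear_continuity_keeps_previous_pairing():
    # two predictions both overlap the gt; the one matched first persists
    gt = [straight(1, 3, w=20, h=20)]
    good = traj(5, {f: (5.0 * (f - 1), 0, 20, 20) for f in (1, 2, 3)})
    rival = traj(6, {f: (5.0 * (f - 1) + 2, 1, 20, 20) for f in (2, 3)})
    res = clear_match(gt, [good, rival])
    assert res.counts.IDSW == 0
    for f in (2, 3):
        assert res.matches_per_frame[f] == [(1, 5)]


def test_mota_arithmetic():
    assert mota(MetricCounts(FP=1, FN=1, IDSW=0, GT=10)) == pytest.approx(0.8)
    assert mota(MetricCounts(FP=0, FN=0, IDSW=0, GT=10)) == 1.0
    assert mota(MetricCounts(FP=20, FN=0, IDSW=0, GT=10)) == pytest.approx(-1.0)


def test_mota_undefined_for_zero_gt():
    with pytest.raises(ValueError):
        mota(MetricCounts(GT=0))


def test_motp_perfect_and_single_match():
    assert motp([0.0, 0.0, 0.0]) == 0.0
    assert motp([6 / 7]) == pytest.approx(6 / 7)
    with pytest.raises(ValueError):
        motp([])


def test_motp_order_invariant(rng):
    d = list(rng.uniform(0, 1, 20))
    assert motp(d) == pytest.approx(motp(sorted(d)))


def test_id_assignment_relabeled_prediction_is_perfect():
    gt = [straight(1, 5), straight(2, 5, y0=50)]
    pred = [straight(9, 5), straight(4, 5, y0=50)]
    idtp, idfp, idfn = id_global_assignment(gt, pred)
    assert (idtp, idfp, idfn) == (10, 0, 0)


def test_id_assignment_empty_prediction():
    gt = [straight(1, 5)]
    idtp, idfp, idfn = id_global_assignment(gt, [])
    assert (idtp, idfp, idfn) == (0, 0, 5)


def test_id_assignment_matches_bijection_oracle_toy():
    # 2 gt x 2 pred over 4 frames; one pred covers half of each gt
    gt = [straight(1, 4), straight(2, 4, y0=100)]
    pred = [
        traj(7, {1: (0, 0, 10, 10), 2: (5, 0, 10, 10), 3: (10, 100, 10, 10), 4: (15, 100, 10, 10)}),
        traj(8, {1: (0, 100, 10, 10), 2: (5, 100, 10, 10), 3: (10, 0, 10, 10), 4: (15, 0, 10, 10)}),
    ]
    got = id_global_assignment(gt, pred)
    assert got == id_counts_oracle(gt, pred)


def test_idf1_arithmetic_and_harmonic_identity(rng):
    idf1, idp, idr = idf1_idp_idr(8, 2, 2)
    assert (idf1, idp, idr) == (0.8, 0.8, 0.8)
    assert idf1_idp_idr(5, 0, 0) == (1.0, 1.0, 1.0)
    for _ in range(50):
        idtp = int(rng.integers(1, 50))
        idfp = int(rng.integers(0, 50))
        idfn = int(rng.integers(0, 50))
        idf1, idp, idr = idf1_idp_idr(idtp, idfp, idfn)
        assert idf1 == pytest.approx(2 * idp * idr / (idp + idr), abs=1e-12)


def test_idf1_zero_denominator_warns_and_returns_zero():
    with pytest.warns(UserWarning):
        idf1, idp, idr = idf1_idp_idr(0, 0, 0)
    assert idf1 == idp == idr == 0.0


def test_mt_ml_threshold_counts():
    mt, ml = mt_ml({1: 1.0, 2: 0.5, 3: 0.1})
    assert mt == pytest.approx(1 / 3)
    assert ml == pytest.approx(1 / 3)
    assert mt_ml({1: 1.0, 2: 1.0}) == (1.0, 0.0)


def test_mt_ml_boundaries():
    mt, ml = mt_ml({1: 0.8, 2: 0.2})
    assert mt == 0.5  # exactly 0.8 counts as mostly tracked
    assert ml == 0.0  # exactly 0.2 is not mostly lost


def test_hota_perfect_prediction():
    gt = [straight(1, 6), straight(2, 6, y0=60)]
    h = hota(gt, gt)
    assert h.DetA == 1.0 and h.AssA == 1.0 and h.HOTA == 1.0


def test_hota_split_identity_halves_association():
    gt = [straight(1, 8)]
    pred = [
        traj(5, {f: (5.0 * (f - 1), 0, 10, 10) for f in range(1, 5)}),
        traj(6, {f: (5.0 * (f - 1), 0, 10, 10) for f in range(5, 9)}),
    ]
    h = hota(gt, pred)
    assert h.DetA == 1.0
    assert h.AssA == pytest.approx(0.5)
    assert h.HOTA == pytest.approx(np.sqrt(0.5))


def test_hota_geometric_mean_identity(rng):
    gt, pred = random_micro_scene(rng)
    h = hota(gt, pred)
    assert h.HOTA**2 == pytest.approx(h.DetA * h.AssA, abs=1e-12)


def test_metrics_match_oracles_on_micro_scenes(rng):
    for _ in range(30):
        gt, pred = random_micro_scene(rng)
        got = id_global_assignment(gt, pred)
        assert got == id_counts_oracle(gt, pred)
        res = clear_match(gt, pred)
        _, oc = clear_oracle(gt, pred)
        assert res.counts.TP == oc["TP"]
        assert res.counts.FP == oc["FP"]
        assert res.counts.FN == oc["FN"]
        assert res.counts.IDSW == oc["IDSW"]
        assert sum(res.distances) == pytest.approx(oc["dist"], abs=1e-9)


def test_pure_false_positive_trajectory_never_helps(rng):
    for _ in range(10):
        gt, pred = random_micro_scene(rng)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            before = evaluate_trajectories(gt, pred)
            junk = Trajectory(999, {f: BoundingBox(5000, 5000, 10, 10) for f in range(1, 4)})
            after = evaluate_trajectories(gt, pred + [junk])
        assert after["mota"] <= before["mota"] + 1e-12
        assert after["idf1"] <= before["idf1"] + 1e-12
        assert after["hota"] <= before["hota"] + 1e-12


def test_metrics_invariant_to_prediction_relabeling(rng):
    for _ in range(10):
        gt, pred = random_micro_scene(rng)
        relabeled = [Trajectory(1000 + i, dict(t.boxes)) for i, t in enumerate(pred)]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = evaluate_trajectories(gt, pred)
            b = evaluate_trajectories(gt, relabeled)
        for key in ("mota", "motp", "idf1", "idp", "idr", "hota", "deta", "assa", "mt", "ml"):
            assert a[key] == pytest.approx(b[key], abs=1e-12)


def test_evaluate_bounds(rng):
    for _ in range(10):
        gt, pred = random_micro_scene(rng)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r = evaluate_trajectories(gt, pred)
        for key in ("idf1", "idp", "idr", "deta", "assa", "hota", "mt", "ml"):
            assert 0.0 <= r[key] <= 1.0
        assert r["mota"] <= 1.0
        assert 0.0 <= r["motp"] <= 1.0


def test_evaluate_files_round_trip(tmp_path):
    from fishmot.motchallenge import TrackRecord, write_tracks, write_trajectories
    from fishmot.metrics import evaluate

    gt = [straight(1, 5), straight(2, 5, y0=200)]
    write_trajectories(gt, tmp_path / "gt.txt")
    records = [
        TrackRecord(f, 30 + i, t.boxes[f], 1.0)
        for i, t in enumerate(gt)
        for f in t.boxes
    ]
    write_tracks(records, tmp_path / "res.txt")
    report = evaluate(tmp_path / "gt.txt", tmp_path / "res.txt")
    assert report["mota"] == 1.0
    assert report["idf1"] == 1.0
    assert report["hota"] == 1.0
    assert report["motp"] == 0.0
    # determinism of the full report
    assert report == evaluate(tmp_path / "gt.txt", tmp_path / "res.txt")
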