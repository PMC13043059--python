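"""Forward model: determinism, ranges, exact VPs, independent render oracle."""

import math

import numpy as np
import pytest

import roomlayout as rl
from roomlayout.calibration import rotation_from_angles
from roomlayout.geometry import ImageFrame
from roomlayout.synthetic import CameraSpec, RoomSpec, SceneRanges, _room_to_world


def pinned_ranges(**overrides):
    base = dict(
        f_px=(420.0, 420.0), pitch_deg=(6.0, 6.0), roll_deg=(2.0, 2.0),
        room_yaw_deg=(12.0, 12.0), frame=(120, 96), width_m=(4.0, 4.0),
        depth_m=(5.0, 5.0), height_m=(2.7, 2.7), cam_x_frac=(0.5, 0.5),
        cam_height_m=(1.5, 1.5), cam_back_dist_m=(3.0, 3.0),
    )
    base.update(overrides)
    return SceneRanges(**base)


def test_same_seed_same_specs():
    r1 = rl.sample_room(123)
    r2 = rl.sample_room(123)
    assert r1[0] == r2[0]
    assert np.array_equal(r1[1].position_m, r2[1].position_m)
    assert (r1[1].pitch_deg, r1[1].roll_deg, r1[1].f_px) == (
        r2[1].pitch_deg, r2[1].roll_deg, r2[1].f_px
    )


def test_samples_respect_declared_ranges():
    ranges = SceneRanges()
    for seed in range(150):
        room, cam = rl.sample_room(seed, ranges)
        assert ranges.width_m[0] <= room.width_m <= ranges.width_m[1]
        assert ranges.depth_m[0] <= room.depth_m <= ranges.depth_m[1]
        assert ranges.min_abs_yaw_deg <= abs(room.room_yaw_deg) <= 30.0
        assert ranges.f_px[0] <= cam.f_px <= ranges.f_px[1]
        assert abs(cam.pitch_deg) <= 30.0 and abs(cam.roll_deg) <= 10.0
        assert np.all(cam.position_m > 0)
        assert cam.position_m[0] < room.width_m
        assert cam.position_m[1] < room.height_m
        assert cam.position_m[2] < room.depth_m


def test_pinned_ranges_give_exact_camera():
    room, cam = rl.sample_room(0, pinned_ranges())
    assert (room.width_m, room.depth_m, room.height_m) == (4.0, 5.0, 2.7)
    assert room.room_yaw_deg == 12.0
    assert (cam.f_px, cam.pitch_deg, cam.roll_deg) == (420.0, 6.0, 2.0)
    assert np.allclose(cam.position_m, [2.0, 1.2, 2.0])


def test_truth_vps_match_annotation_intersections():
    """Recorded axis VPs equal intersect_lines of the jitter-0 annotations."""
    for i in range(6):
        scene = rl.make_scene([77, i], 0.0)
        frame = scene.camera.frame
        v1 = rl.intersect_lines(*scene.annotation.pair_u)
        v2 = rl.intersect_lines(*scene.annotation.pair_v)
        for est, true in ((v1, scene.truth_vps["v1"]), (v2, scene.truth_vps["v2"])):
            if est.is_infinite or true.is_infinite:
                continue
            est_centered = frame.to_centered(est.xy)
            tol = 1e-6 * (1 + np.linalg.norm(true.xy))
            assert np.allclose(est_centered, true.xy, atol=tol)


def test_render_against_independent_ray_caster():
    """Pixel labels agree with a scalar per-pixel ray/face intersection test."""
    room = RoomSpec(4.0, 5.0, 2.7, 14.0)
    cam = CameraSpec(np.array([3.0, 1.1, 2.0]), 8.0, 3.0, 18.0, ImageFrame(40, 32))
    scene = rl.render_ground_truth(room, cam)
    assert scene.n_side_walls == 3

    R_wc = rotation_from_angles(cam.pitch_deg, cam.roll_deg)
    R_rw = _room_to_world(room.room_yaw_deg)
    faces = {  # axis, bound, (name used only for grouping)
        "ceiling": (1, 0.0), "floor": (1, room.height_m),
        "left_wall": (0, 0.0), "right_wall": (0, room.width_m),
        "back_wall": (2, room.depth_m), "front_wall": (2, 0.0),
    }
    hi = np.array([room.width_m, room.height_m, room.depth_m])
    expected_surface = np.empty((32, 40), dtype=object)
    for y in range(32):
        for x in range(40):
            d_cam = np.array([(x - 19.5) / cam.f_px, (y - 15.5) / cam.f_px, 1.0])
            d_room = R_rw.T @ (R_wc.T @ d_cam)
            best, best_t = None, np.inf
            for name, (axis, bound) in faces.items():
                if d_room[axis] == 0:
                    continue
                t = (bound - cam.position_m[axis]) / d_room[axis]
                if t <= 0 or t >= best_t:
                    continue
                p = cam.position_m + t * d_room
                others = [a for a in range(3) if a != axis]
                if all(-1e-9 <= p[a] <= hi[a] + 1e-9 for a in others):
                    best, best_t = name, t
            expected_surface[y, x] = best

    slot_of = {"left_wall": "left", "back_wall": "middle", "right_wall": "right"}
    label_of_slot = {v: k for k, v in scene.truth_segmentation.wall_slots.items()}
    for y in range(32):
        for x in range(40):
            name = expected_surface[y, x]
            got = int(scene.truth_segmentation.labels[y, x])
            if name == "ceiling":
                assert got == 1
            elif name == "floor":
                assert got == 2
            else:
                assert got == label_of_slot[slot_of[name]]


def test_zero_pose_puts_horizon_on_center_row():
    ranges = pinned_ranges(pitch_deg=(0.0, 0.0), roll_deg=(0.0, 0.0), frame=(130, 104))
    room, cam = rl.sample_room(0, ranges)
    scene = rl.render_ground_truth(room, cam)
    labels = scene.truth_segmentation.labels
    center_row = (104 - 1) / 2
    above = labels[: int(math.floor(center_row)) + 1]
    below = labels[int(math.ceil(center_row)):]
    assert not np.any(above == 2)  # no floor above the horizon
    assert not np.any(below == 1)  # no ceiling below it
    vs = cam.camera_model().project_direction([0, 0, 1])
    assert np.allclose(vs.xy, [0, 0], atol=1e-12)


def test_symmetric_frontal_room_balances_walls():
    ranges = pinned_ranges(
        pitch_deg=(0.0, 0.0), roll_deg=(0.0, 0.0), room_yaw_deg=(0.0, 0.0),
        f_px=(61.0, 61.0), frame=(131, 105), width_m=(4.0, 4.0),
    )
    room, cam = rl.sample_room(0, ranges)
    scene = rl.render_ground_truth(room, cam)
    labels = scene.truth_segmentation.labels
    slots = scene.truth_segmentation.wall_slots
    lefts = [k for k, v in slots.items() if v == "left"]
    rights = [k for k, v in slots.items() if v == "right"]
    assert lefts and rights
    assert np.sum(labels == lefts[0]) == np.sum(labels == rights[0])


def test_jitter_scale_matches_noise_model():
    scene = rl.make_scene([31, 0], 0.0)
    clean, _ = rl.synth_annotations(scene, 0.0, 0)
    offsets = []
    for rep in range(80):
        noisy, wall = rl.synth_annotations(scene, 2.0, 1000 + rep)
        for sc, sn in zip(clean.pair_u + clean.pair_v, noisy.pair_u + noisy.pair_v):
            offsets.extend((sn.a - sc.a).tolist())
            offsets.extend((sn.b - sc.b).tolist())
    offsets = np.asarray(offsets)
    assert len(offsets) >= 1000
    assert np.std(offsets) == pytest.approx(2.0, rel=0.1)


def test_jitter_zero_endpoints_exact():
    scene = rl.make_scene([32, 0], 0.0)
    a1, _ = rl.synth_annotations(scene, 0.0, 5)
    a2, _ = rl.synth_annotations(scene, 0.0, 99)
    for s1, s2 in zip(a1.pair_u + a1.pair_v, a2.pair_u + a2.pair_v):
        assert np.array_equal(s1.a, s2.a) and np.array_equal(s1.b, s2.b)


def test_recovery_experiment_deterministic_and_complete():
    t1 = rl.recovery_experiment(4, 0.5, 9)
    t2 = rl.recovery_experiment(4, 0.5, 9)
    assert t1.equals(t2)
    assert len(t1) == 4
    assert t1["ok"].all()


def test_degenerate_side_wall_count_enforced():
    room = RoomSpec(4.0, 5.0, 2.7, 10.0, n_side_walls=2)
    cam = CameraSpec(np.array([2.0, 1.3, 1.0]), 0.0, 0.0, 300.0, ImageFrame(130, 104))
    scene_walls = rl.render_ground_truth(
        RoomSpec(4.0, 5.0, 2.7, 10.0), cam
    ).n_side_walls
    if scene_walls != 2:
        with pytest.raises(rl.synthetic.DegenerateSceneError):
            rl.render_ground_truth(room, cam)
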