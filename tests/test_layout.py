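"""Wall outlining, rasterization, orientation angles and the aerial view."""

import math

import numpy as np
import pytest
from shapely.geometry import Point, Polygon, box

import roomlayout as rl
from roomlayout.calibration import geometry_from_vps
from roomlayout.layout import LABEL_CEILING, LABEL_FLOOR, segmentation_from_labels


def _frontal_setup():
    """Frontal middle wall, zero-pitch camera: bilateral symmetry by hand."""
    frame = rl.ImageFrame(201, 201)  # center at (100, 100)
    geom = geometry_from_vps(
        rl.HomoPoint2D.finite(-600, 0), rl.HomoPoint2D.finite(600, 0), frame
    )
    wall = rl.WallAnnotation(
        rl.LineSegment2D((40, 150), (160, 150)),  # floor edge, horizontal
        rl.LineSegment2D((100, 60), (100, 150)),  # vertical extent
        rl.WallPosition.MIDDLE,
    )
    return frame, geom, wall


def test_frontal_wall_symmetric_corners():
    _, geom, wall = _frontal_setup()
    corners = rl.outline_walls(wall, geom)
    assert corners.va.is_infinite  # frontal wall: Va at infinity, handled homogeneously
    assert np.allclose(corners.vo.xy, geom.oh)
    assert corners.p2.xy[0] == pytest.approx(-corners.p3.xy[0])
    assert corners.p2.xy[1] == pytest.approx(corners.p3.xy[1])
    assert np.allclose(corners.p6.xy, [-60, 50])
    assert np.allclose(corners.p7.xy, [60, 50])


def test_corners_collinear_with_v3(pipeline_bank):
    """Each inner corner lies on the line from V3 through its L1 endpoint."""
    for scene, result in pipeline_bank:
        corners = result["corners"]
        for line_name, pts in (("left_sep", ("p2", "p6")), ("right_sep", ("p3", "p7"))):
            line = corners.lines[line_name]
            for name in pts:
                p = getattr(corners, name)
                if p.is_infinite:
                    continue
                scale = np.linalg.norm(line[:2]) * (1 + np.linalg.norm(p.xy))
                assert abs(line @ np.append(p.xy, 1.0)) < 1e-6 * scale


def test_corners_match_forward_projected_truth(pipeline_bank):
    """p2, p3, p6, p7 equal the projected 3D wall corners at jitter zero."""
    for scene, result in pipeline_bank:
        frame = scene.camera.frame
        for name in ("p2", "p3", "p6", "p7"):
            est = frame.from_centered(getattr(result["corners"], name).xy)
            assert np.allclose(est, scene.truth_corners[name], atol=1e-4)


def test_reconstruction_matches_rendered_truth(pipeline_bank):
    """Noise-free pixel error is rasterization boundary only (here: zero)."""
    for scene, result in pipeline_bank:
        err = rl.pixel_error(result["segmentation"], scene.truth_segmentation)
        assert err < 1.5


def test_middle_wall_region_against_point_in_polygon(pipeline_bank):
    """Rasterized middle wall agrees with an independent polygon-membership test."""
    checked = 0
    for scene, result in pipeline_bank[:4]:
        corners, seg = result["corners"], result["segmentation"]
        frame = corners.frame
        quad_pts = [corners.p2.xy, corners.p3.xy, corners.p7.xy, corners.p6.xy]
        poly = Polygon([tuple(frame.from_centered(p)) for p in quad_pts])
        if not poly.is_valid:
            continue
        poly = poly.intersection(box(-0.5, -0.5, frame.width_px - 0.5, frame.height_px - 0.5))
        middle_labels = [k for k, v in seg.wall_slots.items() if v == "middle"]
        if not middle_labels:
            continue
        mask = seg.labels == middle_labels[0]
        ys, xs = np.nonzero(mask)
        # subsample for speed; include pixels just outside the wall as negatives
        idx = np.arange(0, len(xs), max(1, len(xs) // 400))
        for x, y in zip(xs[idx], ys[idx]):
            assert poly.buffer(1e-6).contains(Point(float(x), float(y)))
        neg = np.argwhere(~mask)[:: max(1, (~mask).sum() // 400)]
        for y, x in neg:
            assert not poly.buffer(-1e-6).contains(Point(float(x), float(y)))
        checked += 1
    assert checked >= 2


def test_mirrored_annotation_mirrors_segmentation(scene_bank):
    scene = scene_bank[1]
    w = scene.camera.frame.width_px

    def mirror_seg(s):
        return rl.LineSegment2D(
            (w - 1 - s.a[0], s.a[1]), (w - 1 - s.b[0], s.b[1])
        )

    annot_m = rl.CalibrationAnnotation(
        tuple(mirror_seg(s) for s in scene.annotation.pair_u),
        tuple(mirror_seg(s) for s in scene.annotation.pair_v),
        scene.annotation.frame,
    )
    wall_m = rl.WallAnnotation(mirror_seg(scene.wall.l1), mirror_seg(scene.wall.l2))
    geom_m, _ = rl.calibrate(annot_m)
    seg_m = rl.rasterize_segmentation(rl.outline_walls(wall_m, geom_m))

    geom, _ = rl.calibrate(scene.annotation)
    seg = rl.rasterize_segmentation(rl.outline_walls(scene.wall, geom))
    expected = seg.mirrored()
    mismatch = np.mean(seg_m.labels != expected.labels)
    assert mismatch == 0.0
    assert rl.pixel_error(seg_m, expected) == rl.pixel_error(seg, seg)


class TestPixelError:
    def test_identical_maps(self):
        a = segmentation_from_labels(np.full((10, 10), LABEL_FLOOR, dtype=np.uint8))
        assert rl.pixel_error(a, a) == 0.0

    def test_fully_different_maps(self):
        a = segmentation_from_labels(np.full((10, 10), LABEL_FLOOR, dtype=np.uint8))
        b = segmentation_from_labels(np.full((10, 10), LABEL_CEILING, dtype=np.uint8))
        assert rl.pixel_error(a, b) == 100.0

    def test_half_different(self):
        lab = np.full((10, 10), LABEL_FLOOR, dtype=np.uint8)
        lab2 = lab.copy()
        lab2[:, :5] = LABEL_CEILING
        assert rl.pixel_error(
            segmentation_from_labels(lab), segmentation_from_labels(lab2)
        ) == 50.0

    def test_dimension_mismatch(self):
        a = segmentation_from_labels(np.zeros((10, 10), dtype=np.uint8))
        b = segmentation_from_labels(np.zeros((10, 12), dtype=np.uint8))
        with pytest.raises(ValueError):
            rl.pixel_error(a, b)


class TestWallOrientations:
    def test_equal_offsets_give_45_degrees(self, micro_geom):
        va = micro_geom.point_on_horizon(micro_geom.h)
        theta_a, theta_o = rl.wall_orientations(micro_geom, va)
        assert theta_a == pytest.approx(45.0)
        assert theta_o == pytest.approx(45.0)

    def test_worked_30_60_split(self, micro_geom):
        va = micro_geom.point_on_horizon(micro_geom.h * math.tan(math.radians(30.0)))
        theta_a, theta_o = rl.wall_orientations(micro_geom, va)
        assert theta_a == pytest.approx(30.0, abs=1e-9)
        assert theta_o == pytest.approx(60.0, abs=1e-9)

    def test_complementarity_on_synthetic_scenes(self, pipeline_bank):
        for _, result in pipeline_bank:
            assert result["theta_a_deg"] + result["theta_o_deg"] == pytest.approx(90.0, abs=1e-9)

    def test_frontal_wall_limit(self, micro_geom):
        theta_a, theta_o = rl.wall_orientations(micro_geom, rl.HomoPoint2D.at_infinity(1, 0))
        assert (theta_a, theta_o) == (90.0, 0.0)


class TestAerialView:
    def test_annotated_wall_orientation_recovers_room_yaw(self, pipeline_bank):
        for scene, result in pipeline_bank:
            mids = [
                spec for spec in result["aerial"]
                if result["segmentation"].wall_slots.get(spec.label) == "middle"
            ]
            assert mids
            assert mids[0].orientation_deg == pytest.approx(abs(scene.room.room_yaw_deg), abs=1e-6)

    def test_spans_match_true_corner_azimuths(self, pipeline_bank):
        from roomlayout.synthetic import _room_to_world

        for scene, result in pipeline_bank:
            mids = [
                spec for spec in result["aerial"]
                if result["segmentation"].wall_slots.get(spec.label) == "middle"
            ]
            spec = mids[0]
            room, cam = scene.room, scene.camera
            R = _room_to_world(room.room_yaw_deg)
            half_fov = cam.camera_model().fov_h_deg / 2
            expected = []
            for corner in ([0.0, 0.0, room.depth_m], [room.width_m, 0.0, room.depth_m]):
                d = R @ (np.array(corner) - cam.position_m)
                expected.append(math.degrees(math.atan2(d[0], d[2])))
            expected = sorted(expected)
            for est, true_az in zip((spec.phi_start_deg, spec.phi_end_deg), expected):
                if abs(true_az) < half_fov - 1e-9:  # unclipped endpoints only
                    assert est == pytest.approx(true_az, abs=1e-4)

    def test_spans_partition_the_fov(self, pipeline_bank):
        for _, result in pipeline_bank:
            spans = sorted(
                (s.phi_start_deg, s.phi_end_deg) for s in result["aerial"]
            )
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                assert e1 <= s2 + 1e-9  # disjoint up to shared endpoints
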