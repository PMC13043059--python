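"""Synthetic Manhattan rooms: forward projection, rendering, annotation emulation.

This module is the ground-truth oracle for the whole pipeline.  It samples
a rectangular room and a camera inside it, renders the exact layout
segmentation by ray-casting the projection model m = K [R | t] X, records
the exact vanishing points of the three room axes, and simulates the
human line annotations (optionally with Gaussian endpoint jitter).  The
parameter-recovery experiment then runs the full
calibrate -> pose -> outline -> rasterize pipeline against this truth.

Coordinates: the room is the box [0, W] x [0, H] x [0, D] in room frame
(x rightward, y downward with the ceiling at y = 0, z toward the back
wall); the camera sits strictly inside, heading toward the back wall,
with the room rotated by ``room_yaw_deg`` about the vertical axis
relative to the camera's heading.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .calibration import (
    CalibrationAnnotation,
    CameraModel,
    calibrate,
    rotation_from_angles,
)
from .geometry import HomoPoint2D, ImageFrame, LineSegment2D
from .layout import (
    LayoutSegmentation,
    WallAnnotation,
    WallPosition,
    build_aerial_view,
    outline_walls,
    pixel_error,
    rasterize_segmentation,
    segmentation_from_labels,
    wall_orientations,
)

__all__ = [
    "RoomSpec",
    "CameraSpec",
    "SceneRanges",
    "SyntheticScene",
    "DegenerateSceneError",
    "sample_room",
    "render_ground_truth",
    "synth_annotations",
    "make_scene",
    "recovery_experiment",
    "summarize_recovery",
    "jitter_protocol",
]


class DegenerateSceneError(ValueError):
    """Sampled scene violates a visibility or conditioning requirement."""


@dataclass(frozen=True)
class RoomSpec:
    """A Manhattan room: box dimensions plus heading relative to the camera."""

    width_m: float
    depth_m: float
    height_m: float
    room_yaw_deg: float
    n_side_walls: int | None = None  # if set, renderer enforces this visible count

    def __post_init__(self) -> None:
        if min(self.width_m, self.depth_m, self.height_m) <= 0:
            raise ValueError("room dimensions must be positive")
        if self.n_side_walls is not None and self.n_side_walls not in (1, 2, 3):
            raise ValueError("n_side_walls must be 1, 2 or 3")


@dataclass(frozen=True)
class CameraSpec:
    """Camera inside the room; yaw is fixed to zero (room_yaw carries heading)."""

    position_m: np.ndarray  # room-frame (x, y, z); y downward from the ceiling
    pitch_deg: float
    roll_deg: float
    f_px: float
    frame: ImageFrame

    def __post_init__(self) -> None:
        p = np.asarray(self.position_m, dtype=float)
        object.__setattr__(self, "position_m", p)
        if p.shape != (3,):
            raise ValueError("camera position must be a 3-vector")
        if self.f_px <= 0:
            raise ValueError("focal length must be positive")
        if not (abs(self.pitch_deg) < 45 and abs(self.roll_deg) < 30):
            raise ValueError("pose outside sampling bounds (|pitch|<45, |roll|<30)")

    def camera_model(self) -> CameraModel:
        return CameraModel(
            self.frame,
            self.f_px,
            self.pitch_deg,
            self.roll_deg,
            rotation_from_angles(self.pitch_deg, self.roll_deg),
        )


@dataclass(frozen=True)
class SceneRanges:
    """Sampling ranges for rooms and cameras (uniform within each interval).

    Defaults reflect a hand-held indoor photograph: a 650 x 520 frame,
    focal lengths 300-1200 px, modest pitch/roll, and headings within 30
    degrees of facing the back wall.  ``min_abs_yaw_deg`` excludes
    near-zero headings, where one annotated vanishing point recedes to
    infinity and the focal length becomes unidentifiable.
    """

    f_px: tuple[float, float] = (300.0, 1200.0)
    pitch_deg: tuple[float, float] = (-30.0, 30.0)
    roll_deg: tuple[float, float] = (-10.0, 10.0)
    room_yaw_deg: tuple[float, float] = (-30.0, 30.0)
    frame: tuple[int, int] = (650, 520)
    width_m: tuple[float, float] = (3.0, 6.0)
    depth_m: tuple[float, float] = (3.0, 8.0)
    height_m: tuple[float, float] = (2.4, 3.2)
    cam_x_frac: tuple[float, float] = (0.25, 0.75)
    cam_height_m: tuple[float, float] = (1.2, 1.8)
    cam_back_dist_m: tuple[float, float] = (2.0, 6.0)
    min_abs_yaw_deg: float = 0.5

    def __post_init__(self) -> None:
        for name in (
            "f_px", "pitch_deg", "roll_deg", "room_yaw_deg", "width_m",
            "depth_m", "height_m", "cam_x_frac", "cam_height_m", "cam_back_dist_m",
        ):
            lo, hi = getattr(self, name)
            if hi < lo:
                raise ValueError(f"empty range for {name}")


def _uniform(rng: np.random.Generator, lohi: tuple[float, float]) -> float:
    lo, hi = lohi
    return float(lo) if lo == hi else float(rng.uniform(lo, hi))


def sample_room(rng_seed, ranges: SceneRanges | None = None) -> tuple[RoomSpec, CameraSpec]:
    """Draw one room/camera pair; deterministic given the seed."""
    ranges = ranges or SceneRanges()
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    width = _uniform(rng, ranges.width_m)
    depth = _uniform(rng, ranges.depth_m)
    height = _uniform(rng, ranges.height_m)
    yaw = _uniform(rng, ranges.room_yaw_deg)
    if abs(yaw) < ranges.min_abs_yaw_deg and ranges.room_yaw_deg[0] != ranges.room_yaw_deg[1]:
        yaw = math.copysign(ranges.min_abs_yaw_deg, yaw if yaw != 0 else 1.0)
    f = _uniform(rng, ranges.f_px)
    pitch = _uniform(rng, ranges.pitch_deg)
    roll = _uniform(rng, ranges.roll_deg)
    x = width * _uniform(rng, ranges.cam_x_frac)
    y = float(np.clip(height - _uniform(rng, ranges.cam_height_m), 0.1, height - 0.1))
    z = float(np.clip(depth - _uniform(rng, ranges.cam_back_dist_m), 0.2, depth - 0.3))
    room = RoomSpec(width, depth, height, yaw)
    camera = CameraSpec(
        np.array([x, y, z]), pitch, roll, f, ImageFrame(*ranges.frame)
    )
    return room, camera


def _room_to_world(yaw_deg: float) -> np.ndarray:
    """Rotation taking room-frame directions to the gravity-aligned camera-heading frame."""
    g = math.radians(yaw_deg)
    return np.array(
        [[math.cos(g), 0.0, math.sin(g)], [0.0, 1.0, 0.0], [-math.sin(g), 0.0, math.cos(g)]]
    )


@dataclass(frozen=True)
class SyntheticScene:
    """A fully rendered synthetic room with exact truth and simulated annotations."""

    room: RoomSpec
    camera: CameraSpec
    truth_segmentation: LayoutSegmentation
    truth_corners: dict[str, np.ndarray]
    truth_vps: dict[str, HomoPoint2D]
    n_side_walls: int
    annotation: CalibrationAnnotation | None = None
    wall: WallAnnotation | None = None
    jitter_px: float = 0.0
    seed: int | None = None

    @property
    def camera_model(self) -> CameraModel:
        return self.camera.camera_model()


class _Projector:
    def __init__(self, room: RoomSpec, camera: CameraSpec) -> None:
        self.room, self.camera = room, camera
        self.R_wc = rotation_from_angles(camera.pitch_deg, camera.roll_deg)
        self.R_rw = _room_to_world(room.room_yaw_deg)

    def to_pixel(self, point_room) -> np.ndarray:
        """Project a room-frame point to 0-based pixel coordinates."""
        cam = self.camera
        xc = self.R_wc @ (self.R_rw @ (np.asarray(point_room, float) - cam.position_m))
        if xc[2] <= 1e-9:
            raise DegenerateSceneError("annotation point at or behind the camera plane")
        centered = cam.f_px * xc[:2] / xc[2]
        return cam.frame.from_centered(centered)

    def axis_vp(self, d_room) -> HomoPoint2D:
        return self.camera.camera_model().project_direction(self.R_rw @ np.asarray(d_room, float))


# Ray-cast surface codes, in left-to-right image order for the walls.
_SURFACES = ("ceiling", "floor", "left_wall", "back_wall", "right_wall", "front_wall")


def render_ground_truth(room: RoomSpec, camera: CameraSpec) -> SyntheticScene:
    """Render the exact layout segmentation and record corners and VPs.

    Every pixel-center ray is intersected with the six planes of the room
    box; the camera is inside, so the nearest positive hit is the visible
    surface.  Scenes where the wall behind the camera enters the frame,
    the back wall nearly vanishes, or a visible side wall is a sliver
    (< 8 px of horizontal extent) raise :class:`DegenerateSceneError` —
    callers resample.
    """
    proj = _Projector(room, camera)
    frame = camera.frame
    w, h = frame.width_px, frame.height_px
    cx, cy = frame.center
    xs = (np.arange(w) - cx) / camera.f_px
    ys = (np.arange(h) - cy) / camera.f_px
    dx_c, dy_c = np.meshgrid(xs, ys)
    d_cam = np.stack([dx_c, dy_c, np.ones_like(dx_c)], axis=-1)
    # d_room = R_rw^T R_wc^T d_cam, applied to rows: row @ (R_wc R_rw)
    d_room = d_cam @ (proj.R_wc @ proj.R_rw)
    pos = camera.position_m
    box_hi = np.array([room.width_m, room.height_m, room.depth_m])

    t_hit = np.full((h, w), np.inf)
    surf = np.full((h, w), -1, dtype=np.int8)
    surface_codes = {
        "ceiling": (1, 0.0, -1), "floor": (1, box_hi[1], +1),
        "left_wall": (0, 0.0, -1), "right_wall": (0, box_hi[0], +1),
        "front_wall": (2, 0.0, -1), "back_wall": (2, box_hi[2], +1),
    }
    for idx, name in enumerate(_SURFACES):
        axis, bound, sign = surface_codes[name]
        d = d_room[..., axis]
        with np.errstate(divide="ignore", invalid="ignore"):
            t = (bound - pos[axis]) / d
        valid = (np.sign(d) == sign) & (t > 0)
        closer = valid & (t < t_hit)
        t_hit[closer] = t[closer]
        surf[closer] = idx
    if np.any(surf == _SURFACES.index("front_wall")):
        raise DegenerateSceneError("wall behind the camera is visible")

    n_px = w * h
    counts = {name: int(np.sum(surf == i)) for i, name in enumerate(_SURFACES)}
    if counts["back_wall"] < 0.01 * n_px:
        raise DegenerateSceneError("back wall nearly invisible")
    for name in ("left_wall", "right_wall"):
        mask = surf == _SURFACES.index(name)
        if counts[name] and int(np.sum(mask.any(axis=0))) < 8:
            raise DegenerateSceneError(f"{name} is a sliver")

    labels = np.zeros((h, w), dtype=np.uint8)
    labels[surf == _SURFACES.index("ceiling")] = 1
    labels[surf == _SURFACES.index("floor")] = 2
    slot_names = {"left_wall": "left", "back_wall": "middle", "right_wall": "right"}
    wall_slots: dict[int, str] = {}
    next_label = 3
    for name in ("left_wall", "back_wall", "right_wall"):
        if counts[name]:
            labels[surf == _SURFACES.index(name)] = next_label
            wall_slots[next_label] = slot_names[name]
            next_label += 1
    seg = segmentation_from_labels(labels, wall_slots)

    n_walls = sum(1 for name in ("left_wall", "back_wall", "right_wall") if counts[name])
    if room.n_side_walls is not None and n_walls != room.n_side_walls:
        raise DegenerateSceneError(f"{n_walls} side walls visible, wanted {room.n_side_walls}")

    wm, hm, dm = room.width_m, room.height_m, room.depth_m
    truth_corners = {
        "p2": proj.to_pixel([0.0, 0.0, dm]),
        "p3": proj.to_pixel([wm, 0.0, dm]),
        "p6": proj.to_pixel([0.0, hm, dm]),
        "p7": proj.to_pixel([wm, hm, dm]),
    }
    truth_vps = {
        "v1": proj.axis_vp([1.0, 0.0, 0.0]),
        "v2": proj.axis_vp([0.0, 0.0, 1.0]),
        "v3": proj.axis_vp([0.0, 1.0, 0.0]),
    }
    return SyntheticScene(room, camera, seg, truth_corners, truth_vps, n_walls)


def synth_annotations(
    scene: SyntheticScene, jitter_px: float, rng_seed
) -> tuple[CalibrationAnnotation, WallAnnotation]:
    """Simulate the six annotated key edges, with Gaussian endpoint jitter.

    pair_u follows the back wall's ceiling and floor junctions (the room's
    left-right axis); pair_v follows the left and right walls' floor
    junctions (the depth axis); L1 is the back wall's floor edge with
    endpoints at the true corners and L2 spans the wall vertically at its
    midline.  Standard-normal offsets are drawn for every endpoint and
    scaled by ``jitter_px``, so different jitter levels with the same seed
    share noise directions.
    """
    if jitter_px < 0:
        raise ValueError("jitter must be non-negative")
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    room, cam = scene.room, scene.camera
    proj = _Projector(room, cam)
    wm, hm, dm = room.width_m, room.height_m, room.depth_m
    z_mid = cam.position_m[2] + 0.5 * (dm - cam.position_m[2])
    points_room = [
        [0.0, 0.0, dm], [wm, 0.0, dm],          # pair_u top (ceiling junction)
        [0.0, hm, dm], [wm, hm, dm],            # pair_u bottom (floor junction)
        [0.0, hm, z_mid], [0.0, hm, dm],        # pair_v left floor junction
        [wm, hm, z_mid], [wm, hm, dm],          # pair_v right floor junction
        [0.0, hm, dm], [wm, hm, dm],            # L1: floor edge, corner to corner
        [wm / 2.0, 0.0, dm], [wm / 2.0, hm, dm],  # L2: vertical midline of the wall
    ]
    pts = np.array([proj.to_pixel(p) for p in points_room])
    pts = pts + jitter_px * rng.standard_normal(pts.shape)

    def seg(i: int) -> LineSegment2D:
        return LineSegment2D(pts[2 * i], pts[2 * i + 1])

    slots = set(scene.truth_segmentation.wall_slots.values())
    if "left" in slots and "right" in slots:
        position = WallPosition.MIDDLE
    elif "left" in slots:
        position = WallPosition.RIGHT  # back wall is the rightmost visible wall
    elif "right" in slots:
        position = WallPosition.LEFT
    else:
        position = WallPosition.MIDDLE
    annot = CalibrationAnnotation((seg(0), seg(1)), (seg(2), seg(3)), cam.frame)
    wall = WallAnnotation(seg(4), seg(5), position)
    return annot, wall


def make_scene(
    scene_seed, jitter_px: float = 0.0, ranges: SceneRanges | None = None, max_resamples: int = 100
) -> SyntheticScene:
    """Sample until non-degenerate, render, and attach annotations."""
    base = scene_seed if isinstance(scene_seed, (list, tuple)) else [scene_seed]
    for attempt in range(max_resamples):
        rng = np.random.default_rng(np.random.SeedSequence(list(base) + [attempt]))
        room, camera = sample_room(rng, ranges)
        try:
            scene = render_ground_truth(room, camera)
            annot_rng = np.random.default_rng(np.random.SeedSequence(list(base) + [attempt, 1]))
            annot, wall = synth_annotations(scene, jitter_px, annot_rng)
        except DegenerateSceneError:
            continue
        return replace(scene, annotation=annot, wall=wall, jitter_px=jitter_px)
    raise DegenerateSceneError(f"no valid scene after {max_resamples} attempts")


_ROW_FIELDS = [
    "scene", "ok", "error", "f_true", "pitch_true", "roll_true", "yaw_true",
    "f_est", "pitch_est", "roll_est", "abs_pitch_err_deg", "abs_roll_err_deg",
    "rel_f_err", "wall_orient_err_deg", "pixel_err_pct", "n_walls",
]


def run_pipeline(scene: SyntheticScene) -> dict:
    """Run calibrate -> pose -> outline -> rasterize on a scene's annotations."""
    if scene.annotation is None or scene.wall is None:
        raise ValueError("scene carries no annotations; call synth_annotations/make_scene")
    geom, camera = calibrate(scene.annotation)
    corners = outline_walls(scene.wall, geom)
    seg = rasterize_segmentation(corners)
    theta_a, theta_o = wall_orientations(geom, corners.va)
    aerial = build_aerial_view(seg, corners, theta_a, theta_o, camera)
    return {
        "geom": geom, "camera": camera, "corners": corners,
        "segmentation": seg, "aerial": aerial,
        "theta_a_deg": theta_a, "theta_o_deg": theta_o,
    }


def _scene_errors(scene: SyntheticScene, result: dict) -> dict:
    cam_true, cam_est = scene.camera, result["camera"]
    err_pix = pixel_error(result["segmentation"], scene.truth_segmentation)
    orient_err = math.nan
    slots = {spec.label: spec for spec in result["aerial"]}
    for label, slot in result["segmentation"].wall_slots.items():
        if slot == "middle" and label in slots:
            orient_err = abs(slots[label].orientation_deg - abs(scene.room.room_yaw_deg))
    return {
        "f_est": cam_est.focal_length_px,
        "pitch_est": cam_est.pitch_deg,
        "roll_est": cam_est.roll_deg,
        "abs_pitch_err_deg": abs(cam_est.pitch_deg - cam_true.pitch_deg),
        "abs_roll_err_deg": abs(cam_est.roll_deg - cam_true.roll_deg),
        "rel_f_err": abs(cam_est.focal_length_px - cam_true.f_px) / cam_true.f_px,
        "wall_orient_err_deg": orient_err,
        "pixel_err_pct": err_pix,
        "n_walls": scene.n_side_walls,
    }


def recovery_experiment(
    n_scenes: int, jitter_px: float, seed: int, ranges: SceneRanges | None = None
) -> pd.DataFrame:
    """Per-scene parameter-recovery errors for the full pipeline.

    Pipeline failures are recorded as rows with ``ok = False`` rather than
    dropped; the same (n, jitter, seed) always yields an identical table.
    """
    if n_scenes < 1:
        raise ValueError("need at least one scene")
    rows = []
    for i in range(n_scenes):
        scene = make_scene([seed, i], jitter_px, ranges)
        row = {
            "scene": i, "ok": True, "error": "",
            "f_true": scene.camera.f_px, "pitch_true": scene.camera.pitch_deg,
            "roll_true": scene.camera.roll_deg, "yaw_true": scene.room.room_yaw_deg,
        }
        try:
            result = run_pipeline(scene)
            row.update(_scene_errors(scene, result))
        except Exception as exc:  # failure rows are data, not crashes
            row.update({"ok": False, "error": f"{type(exc).__name__}: {exc}"})
        rows.append(row)
    return pd.DataFrame(rows, columns=_ROW_FIELDS)


def summarize_recovery(table: pd.DataFrame) -> dict[str, float]:
    ok = table[table["ok"]]
    out = {"n": int(len(table)), "n_ok": int(len(ok))}
    for col in ("abs_pitch_err_deg", "abs_roll_err_deg", "rel_f_err",
                "wall_orient_err_deg", "pixel_err_pct"):
        out[f"mean_{col}"] = float(ok[col].mean())
        out[f"max_{col}"] = float(ok[col].max())
    return out


def jitter_protocol(
    jitter_levels, n_scenes: int, seed: int, ranges: SceneRanges | None = None
) -> pd.DataFrame:
    """Mean recovery errors across jitter levels (same rooms and noise directions)."""
    rows = []
    for jitter in jitter_levels:
        table = recovery_experiment(n_scenes, float(jitter), seed, ranges)
        summary = summarize_recovery(table)
        summary["jitter_px"] = float(jitter)
        rows.append(summary)
    cols = ["jitter_px", "n", "n_ok"] + [k for k in rows[0] if k.startswith(("mean_", "max_"))]
    return pd.DataFrame(rows)[cols]
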