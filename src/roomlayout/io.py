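"""Readers and writers for the package's file formats.

* Annotation JSON — one object per image (or a list of them):
  ``{"image": {"id", "width", "height"},
     "calibration": {"pair_u": [[[x,y],[x,y]],[[x,y],[x,y]]], "pair_v": [...]},
     "wall": {"L1": [[x,y],[x,y]], "L2": [[x,y],[x,y]], "position": "left|middle|right"}}``
  with coordinates as floats in 0-based pixel units.
* Camera JSON — ``{"f_px", "pitch_deg", "roll_deg", "fov_h_deg", "h_px"}``
  (keyed by image id when several images are calibrated together).
* Segmentation maps — 8-bit paletted PNG with the fixed label palette
  (0 unknown, 1 ceiling, 2 floor, 3+ walls) or CSV of integers.
* Feature and RDM tables — CSV with 17-significant-digit floats, which
  round-trip ``float64`` exactly.

Floats written to JSON use Python ``repr`` semantics (shortest exact
round trip); rerunning a command on identical inputs yields
byte-identical primary outputs.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .calibration import CalibrationAnnotation, CameraModel
from .geometry import ImageFrame, LineSegment2D
from .layout import AerialWallSpec, LayoutSegmentation, WallAnnotation, WallPosition, segmentation_from_labels

__all__ = [
    "AnnotationFormatError",
    "read_annotation_records",
    "write_annotation_records",
    "camera_to_dict",
    "write_cameras",
    "read_cameras",
    "write_segmentation_png",
    "read_segmentation_png",
    "write_segmentation_csv",
    "read_segmentation_csv",
    "write_aerial_json",
    "read_aerial_json",
    "write_feature_csv",
    "read_feature_csv",
    "write_rdm_csv",
    "read_rdm_csv",
]

FLOAT_FMT = "%.17g"

# Fixed palette so label images diff cleanly: unknown, ceiling, floor, walls.
_PALETTE = [
    (0, 0, 0), (135, 206, 235), (139, 90, 43), (204, 51, 51),
    (51, 153, 51), (51, 102, 204), (204, 153, 51), (153, 51, 204),
]


class AnnotationFormatError(ValueError):
    """Malformed annotation JSON; carries the offending field path."""

    def __init__(self, field_path: str, message: str) -> None:
        self.field_path = field_path
        super().__init__(f"{field_path}: {message}")


def _as_segment(obj, path: str) -> LineSegment2D:
    try:
        (ax, ay), (bx, by) = obj
        return LineSegment2D((float(ax), float(ay)), (float(bx), float(by)))
    except (TypeError, ValueError) as exc:
        raise AnnotationFormatError(path, f"expected [[x,y],[x,y]] ({exc})") from None


def _parse_record(obj: dict, path: str) -> dict:
    if not isinstance(obj, dict):
        raise AnnotationFormatError(path, "expected an object")
    img = obj.get("image")
    if not isinstance(img, dict):
        raise AnnotationFormatError(f"{path}.image", "missing image block")
    try:
        frame = ImageFrame(int(img["width"]), int(img["height"]))
    except (KeyError, TypeError, ValueError) as exc:
        raise AnnotationFormatError(f"{path}.image", f"bad width/height ({exc})") from None
    image_id = str(img.get("id", ""))

    calib = obj.get("calibration")
    annotation = None
    if calib is not None:
        if not isinstance(calib, dict):
            raise AnnotationFormatError(f"{path}.calibration", "expected an object")
        pairs = {}
        for key in ("pair_u", "pair_v"):
            raw = calib.get(key)
            if not isinstance(raw, list) or len(raw) != 2:
                raise AnnotationFormatError(f"{path}.calibration.{key}", "expected two segments")
            pairs[key] = tuple(
                _as_segment(seg, f"{path}.calibration.{key}[{i}]") for i, seg in enumerate(raw)
            )
        annotation = CalibrationAnnotation(pairs["pair_u"], pairs["pair_v"], frame)

    wall_obj = obj.get("wall")
    wall = None
    if wall_obj is not None:
        if not isinstance(wall_obj, dict):
            raise AnnotationFormatError(f"{path}.wall", "expected an object")
        l1 = _as_segment(wall_obj.get("L1"), f"{path}.wall.L1")
        l2 = _as_segment(wall_obj.get("L2"), f"{path}.wall.L2")
        pos_raw = wall_obj.get("position", "middle")
        try:
            position = WallPosition(pos_raw)
        except ValueError:
            raise AnnotationFormatError(
                f"{path}.wall.position", f"unknown position {pos_raw!r}"
            ) from None
        wall = WallAnnotation(l1, l2, position)

    return {"id": image_id, "frame": frame, "calibration": annotation, "wall": wall}


def read_annotation_records(path) -> list[dict]:
    """Parse an annotation JSON file into calibration/wall annotation objects."""
    try:
        data = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise AnnotationFormatError("$", f"invalid JSON: {exc}") from None
    if isinstance(data, dict):
        return [_parse_record(data, "$")]
    if isinstance(data, list):
        return [_parse_record(obj, f"$[{i}]") for i, obj in enumerate(data)]
    raise AnnotationFormatError("$", "expected an object or a list of objects")


def _segment_json(seg: LineSegment2D) -> list:
    return [[float(seg.a[0]), float(seg.a[1])], [float(seg.b[0]), float(seg.b[1])]]


def annotation_record_json(
    image_id: str,
    frame: ImageFrame,
    calibration: CalibrationAnnotation | None,
    wall: WallAnnotation | None,
) -> dict:
    rec: dict = {
        "image": {"id": image_id, "width": frame.width_px, "height": frame.height_px}
    }
    if calibration is not None:
        rec["calibration"] = {
            "pair_u": [_segment_json(s) for s in calibration.pair_u],
            "pair_v": [_segment_json(s) for s in calibration.pair_v],
        }
    if wall is not None:
        rec["wall"] = {
            "L1": _segment_json(wall.l1),
            "L2": _segment_json(wall.l2),
            "position": wall.position.value,
        }
    return rec


def write_annotation_records(records: list[dict], path) -> None:
    payload = [
        annotation_record_json(r["id"], r["frame"], r.get("calibration"), r.get("wall"))
        for r in records
    ]
    Path(path).write_text(json.dumps(payload[0] if len(payload) == 1 else payload, indent=1))


def camera_to_dict(camera: CameraModel, h_px: float) -> dict:
    return {
        "f_px": float(camera.focal_length_px),
        "pitch_deg": float(camera.pitch_deg),
        "roll_deg": float(camera.roll_deg),
        "fov_h_deg": float(camera.fov_h_deg),
        "h_px": float(h_px),
    }


def write_cameras(cameras: dict[str, dict], path) -> None:
    payload = next(iter(cameras.values())) if len(cameras) == 1 else cameras
    Path(path).write_text(json.dumps(payload, indent=1))


def read_cameras(path) -> dict[str, dict]:
    data = json.loads(Path(path).read_text())
    if "f_px" in data:
        return {"": data}
    return data


def write_segmentation_png(seg: LayoutSegmentation, path) -> None:
    img = Image.fromarray(seg.labels, mode="P")
    palette = list(_PALETTE) + [(0, 0, 0)] * (256 - len(_PALETTE))
    img.putpalette([c for rgb in palette for c in rgb])
    img.save(path, format="PNG")


def read_segmentation_png(path) -> LayoutSegmentation:
    labels = np.asarray(Image.open(path).convert("P"), dtype=np.uint8)
    return segmentation_from_labels(labels)


def write_segmentation_csv(seg: LayoutSegmentation, path) -> None:
    np.savetxt(path, seg.labels, fmt="%d", delimiter=",")


def read_segmentation_csv(path) -> LayoutSegmentation:
    labels = np.loadtxt(path, dtype=np.uint8, delimiter=",", ndmin=2)
    return segmentation_from_labels(labels)


def write_aerial_json(walls: list[AerialWallSpec], path) -> None:
    payload = [
        {
            "orientation_deg": float(w.orientation_deg),
            "phi_start_deg": float(w.phi_start_deg),
            "phi_end_deg": float(w.phi_end_deg),
            "label": int(w.label),
        }
        for w in walls
    ]
    Path(path).write_text(json.dumps(payload, indent=1))


def read_aerial_json(path) -> list[AerialWallSpec]:
    data = json.loads(Path(path).read_text())
    return [
        AerialWallSpec(d["orientation_deg"], d["phi_start_deg"], d["phi_end_deg"], int(d["label"]))
        for d in data
    ]


def write_feature_csv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index_label="condition", float_format=FLOAT_FMT)


def read_feature_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="condition", float_precision="round_trip")


def write_rdm_csv(rdm, path) -> None:
    df = pd.DataFrame(rdm.matrix, index=rdm.condition_ids, columns=rdm.condition_ids)
    df.to_csv(path, index_label="condition", float_format=FLOAT_FMT)


def read_rdm_csv(path):
    from .features import RDM

    df = pd.read_csv(path, index_col="condition", float_precision="round_trip")
    return RDM(df.to_numpy(dtype=float), tuple(str(c) for c in df.columns))
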