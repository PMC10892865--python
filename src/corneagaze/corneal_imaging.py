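"""Corneal image extraction.

The tear film turns the cornea into a convex mirror, so the RGB eye image
contains a small reflected copy of the world around the pupil.  This module
transforms the IR pupil bounding box into the RGB eye image through the 3D
eyeball mapping, crops the corneal patch, and mirrors it horizontally so its
content reads in world orientation.  The pupil centre carried through the
same mapping becomes the gaze point inside the (flipped) crop.

Coordinate note: all downstream matching happens in flipped-crop-local
coordinates; :func:`corneal_gaze_point` is the single place that converts a
full-image RGB pixel into that frame, and it is its own inverse under the
same crop width.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .camera_geometry import CameraIntrinsics, RigidTransform
from .eye_model import EyeballModel, NoIntersectionError, map_ir_to_rgb
from .pupil_detection import PupilDetection

__all__ = [
    "CornealImage",
    "ExtractionError",
    "transform_bbox",
    "corneal_gaze_point",
    "extract_corneal_image",
]


class ExtractionError(ValueError):
    """Corneal patch could not be extracted for this frame."""


@dataclass(frozen=True)
class CornealImage:
    """A mirrored corneal crop with its gaze point in crop coordinates.

    ``bbox_rgb`` locates the crop in the full RGB eye image; ``gaze_point``
    is the pupil centre after the horizontal flip; ``flipped`` is always True
    once extraction has run.
    """

    pixels: np.ndarray
    bbox_rgb: tuple[float, float, float, float]
    gaze_point: tuple[float, float]
    flipped: bool = True

    def __post_init__(self) -> None:
        w, h = self.bbox_rgb[2], self.bbox_rgb[3]
        gu, gv = self.gaze_point
        if not (-1e-6 <= gu <= w + 1e-6 and -1e-6 <= gv <= h + 1e-6):
            raise ExtractionError("gaze point falls outside the crop")

    def save(self, path: str | Path) -> None:
        path = Path(path)
        iio.imwrite(path, np.ascontiguousarray(self.pixels))
        sidecar = {"bbox_rgb": list(self.bbox_rgb),
                   "gaze_point": list(self.gaze_point),
                   "flipped": self.flipped}
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "CornealImage":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        return cls(pixels=iio.imread(path), bbox_rgb=tuple(meta["bbox_rgb"]),
                   gaze_point=tuple(meta["gaze_point"]),
                   flipped=bool(meta["flipped"]))


def transform_bbox(
    det: PupilDetection,
    model: EyeballModel,
    K_ir: CameraIntrinsics,
    K_rgb: CameraIntrinsics,
    rig: RigidTransform,
    margin_frac: float = 0.1,
) -> tuple[float, float, float, float]:
    """Map the IR pupil bbox into the RGB eye image.

    The four bbox corners travel through the eyeball-surface mapping; their
    axis-aligned hull, enlarged by ``margin_frac`` per side so that features
    just outside the pupil boundary survive, is clipped to the RGB frame.
    """
    try:
        corners = map_ir_to_rgb(det.bbox_corners, model, K_ir, K_rgb, rig)
    except NoIntersectionError as exc:
        raise ExtractionError(f"bbox corner misses the eyeball: {exc}") from exc
    u0, v0 = corners.min(axis=0)
    u1, v1 = corners.max(axis=0)
    mu, mv = margin_frac * (u1 - u0), margin_frac * (v1 - v0)
    u0, v0, u1, v1 = u0 - mu, v0 - mv, u1 + mu, v1 + mv
    u0, v0 = max(u0, 0.0), max(v0, 0.0)
    u1, v1 = min(u1, K_rgb.width - 1.0), min(v1, K_rgb.height - 1.0)
    if u1 <= u0 or v1 <= v0:
        raise ExtractionError("transformed bbox has no area inside the image")
    return (float(u0), float(v0), float(u1 - u0), float(v1 - v0))


def corneal_gaze_point(
    bbox_rgb: tuple[float, float, float, float],
    pupil_center_rgb: np.ndarray,
) -> tuple[float, float]:
    """Pupil centre in flipped-crop-local coordinates.

    With crop width w, the horizontal mirror sends crop-local u to
    ``w - 1 - u``; v is unchanged.
    """
    u0, v0, w, h = bbox_rgb
    uc, vc = float(pupil_center_rgb[0]), float(pupil_center_rgb[1])
    return (w - 1.0 - (uc - u0), vc - v0)


def extract_corneal_image(
    rgb_image: np.ndarray,
    bbox_rgb: tuple[float, float, float, float],
    pupil_center_rgb: np.ndarray,
) -> CornealImage:
    """Crop the corneal patch and mirror it to world orientation.

    The crop is the full image restricted to the (integer-snapped) bbox with
    no resampling; the flip is a pure horizontal mirror, an involution.
    """
    H, W = rgb_image.shape[:2]
    u0f, v0f, wf, hf = bbox_rgb
    u0 = int(np.floor(max(u0f, 0.0)))
    v0 = int(np.floor(max(v0f, 0.0)))
    u1 = int(np.ceil(min(u0f + wf, W - 1.0))) + 1
    v1 = int(np.ceil(min(v0f + hf, H - 1.0))) + 1
    if u1 <= u0 or v1 <= v0:
        raise ExtractionError("empty bounding box after clipping")
    crop = rgb_image[v0:v1, u0:u1]
    flipped = crop[:, ::-1].copy()
    bbox_int = (float(u0), float(v0), float(u1 - u0), float(v1 - v0))
    gaze = corneal_gaze_point(bbox_int, pupil_center_rgb)
    return CornealImage(pixels=flipped, bbox_rgb=bbox_int,
                        gaze_point=gaze, flipped=True)
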