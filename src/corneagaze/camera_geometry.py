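"""Pinhole camera geometry: projection, backprojection, rigid transforms,
and two-ray triangulation.

Conventions
-----------
Pixel coordinates are 0-based, x (``u``) to the right, y (``v``) down, with
sub-pixel precision.  A camera looks down its own +z axis.  The IR eye camera
frame is the world frame for all eye-side geometry; the pose of the RGB eye
camera is given relative to it.  Translations are in millimetres, intrinsics
in pixels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

__all__ = [
    "CameraIntrinsics",
    "RigidTransform",
    "Ray",
    "Rig",
    "GeometryError",
    "BehindCameraError",
    "DegenerateGeometryError",
    "project",
    "backproject",
    "triangulate",
    "load_rig",
    "save_rig",
]


class GeometryError(ValueError):
    """Base class for geometric failures."""


class BehindCameraError(GeometryError):
    """A 3D point has non-positive depth and cannot be projected."""


class DegenerateGeometryError(GeometryError):
    """Rays are (near-)parallel; triangulation is ill-posed."""


@dataclass(frozen=True)
class CameraIntrinsics:
    """Pinhole parameters of one camera.

    ``dist`` holds optional radial distortion coefficients (k1, k2); the
    default zero tuple gives a plain pinhole model.
    """

    fx: float
    fy: float
    cx: float
    cy: float
    width: int
    height: int
    dist: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if not (self.fx > 0 and self.fy > 0):
            raise ValueError("focal lengths must be positive")
        if not (0 <= self.cx < self.width and 0 <= self.cy < self.height):
            raise ValueError("principal point must lie inside the image")

    @property
    def has_distortion(self) -> bool:
        return any(abs(k) > 0 for k in self.dist)

    def to_dict(self) -> dict:
        return {
            "fx": self.fx, "fy": self.fy, "cx": self.cx, "cy": self.cy,
            "width": self.width, "height": self.height, "dist": list(self.dist),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CameraIntrinsics":
        dist = tuple(d.get("dist", (0.0, 0.0))) or (0.0, 0.0)
        if len(dist) == 1:
            dist = (dist[0], 0.0)
        return cls(d["fx"], d["fy"], d["cx"], d["cy"],
                   int(d["width"]), int(d["height"]), dist)


@dataclass(frozen=True)
class RigidTransform:
    """Rigid motion ``p' = R p + t`` between two camera frames."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-9):
            raise ValueError("rotation is not orthonormal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-9):
            raise ValueError("rotation determinant must be +1")

    def apply(self, p: np.ndarray) -> np.ndarray:
        """Transform one point (3,) or a stack (N, 3)."""
        p = np.asarray(p, dtype=float)
        return p @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    @property
    def camera_center(self) -> np.ndarray:
        """Origin of the destination frame expressed in the source frame."""
        return -self.rotation.T @ self.translation

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def to_dict(self) -> dict:
        return {"R": self.rotation.ravel().tolist(),
                "t": self.translation.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        return cls(np.asarray(d["R"], dtype=float).reshape(3, 3),
                   np.asarray(d["t"], dtype=float))


@dataclass(frozen=True)
class Ray:
    """Half-line with unit direction; origin in mm."""

    origin: np.ndarray
    direction: np.ndarray

    def __post_init__(self) -> None:
        o = np.asarray(self.origin, dtype=float).reshape(3)
        d = np.asarray(self.direction, dtype=float).reshape(3)
        n = np.linalg.norm(d)
        if n < 1e-12:
            raise ValueError("ray direction must be nonzero")
        object.__setattr__(self, "origin", o)
        object.__setattr__(self, "direction", d / n)

    def point_at(self, t: float) -> np.ndarray:
        return self.origin + t * self.direction


@dataclass(frozen=True)
class Rig:
    """The three-camera headset: two eye cameras plus the front-scene camera,
    with the rigid pose of the RGB eye camera relative to the IR eye camera."""

    ir: CameraIntrinsics
    rgb: CameraIntrinsics
    front: CameraIntrinsics
    rgb_from_ir: RigidTransform

    def to_dict(self) -> dict:
        return {
            "ir": self.ir.to_dict(),
            "rgb": self.rgb.to_dict(),
            "front": self.front.to_dict(),
            "rgb_from_ir": self.rgb_from_ir.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Rig":
        return cls(
            ir=CameraIntrinsics.from_dict(d["ir"]),
            rgb=CameraIntrinsics.from_dict(d["rgb"]),
            front=CameraIntrinsics.from_dict(d["front"]),
            rgb_from_ir=RigidTransform.from_dict(d["rgb_from_ir"]),
        )


def _distort(x: np.ndarray, y: np.ndarray, dist: Sequence[float]):
    k1, k2 = dist
    r2 = x * x + y * y
    f = 1.0 + k1 * r2 + k2 * r2 * r2
    return x * f, y * f


def _undistort(x: np.ndarray, y: np.ndarray, dist: Sequence[float], iters: int = 8):
    # fixed-point inversion of the radial model; converges fast for mild k1, k2
    xu, yu = x.copy(), y.copy()
    k1, k2 = dist
    for _ in range(iters):
        r2 = xu * xu + yu * yu
        f = 1.0 + k1 * r2 + k2 * r2 * r2
        xu, yu = x / f, y / f
    return xu, yu


def project(p: np.ndarray, K: CameraIntrinsics) -> np.ndarray:
    """Project camera-frame point(s) (3,) or (N, 3) to pixel coordinates.

    Raises :class:`BehindCameraError` if any point has depth z <= 0.
    """
    p = np.asarray(p, dtype=float)
    single = p.ndim == 1
    pts = np.atleast_2d(p)
    z = pts[:, 2]
    if np.any(z <= 0):
        raise BehindCameraError("point(s) behind the camera (z <= 0)")
    x, y = pts[:, 0] / z, pts[:, 1] / z
    if K.has_distortion:
        x, y = _distort(x, y, K.dist)
    uv = np.stack([K.fx * x + K.cx, K.fy * y + K.cy], axis=1)
    return uv[0] if single else uv


def backproject(q: np.ndarray, K: CameraIntrinsics) -> Ray | np.ndarray:
    """Backproject pixel(s) to viewing ray(s) through the camera center.

    A single pixel (2,) returns a :class:`Ray`; a stack (N, 2) returns an
    (N, 3) array of unit directions (the shared origin is the camera center).
    """
    q = np.asarray(q, dtype=float)
    single = q.ndim == 1
    uv = np.atleast_2d(q)
    x = (uv[:, 0] - K.cx) / K.fx
    y = (uv[:, 1] - K.cy) / K.fy
    if K.has_distortion:
        x, y = _undistort(x, y, K.dist)
    d = np.stack([x, y, np.ones_like(x)], axis=1)
    d /= np.linalg.norm(d, axis=1, keepdims=True)
    if single:
        return Ray(np.zeros(3), d[0])
    return d


def triangulate(ray_a: Ray, ray_b: Ray) -> tuple[np.ndarray, float]:
    """Midpoint of the common perpendicular between two rays, and its length.

    Noisy corresponding rays are generically skew; the midpoint of the
    shortest connecting segment is the minimal-assumption intersection
    estimate, and the segment length (``gap``) is a match-quality diagnostic
    (zero iff the rays truly intersect).
    """
    da, db = ray_a.direction, ray_b.direction
    c = float(np.dot(da, db))
    if abs(c) > 1.0 - 1e-9:
        raise DegenerateGeometryError("rays are parallel")
    w = ray_a.origin - ray_b.origin
    # solve [1 -c; c -1] [ta tb]' = [-da.w, -db.w]'
    denom = 1.0 - c * c
    ta = (c * np.dot(db, w) - np.dot(da, w)) / denom
    tb = (np.dot(db, w) - c * np.dot(da, w)) / denom
    pa = ray_a.point_at(ta)
    pb = ray_b.point_at(tb)
    return 0.5 * (pa + pb), float(np.linalg.norm(pa - pb))


def triangulate_pixel_pairs(
    uv_ir: np.ndarray,
    uv_rgb: np.ndarray,
    K_ir: CameraIntrinsics,
    K_rgb: CameraIntrinsics,
    rgb_from_ir: RigidTransform,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised triangulation of pixel correspondences.

    Returns ``(points, gaps)`` with points (N, 3) in the IR camera frame and
    gaps (N,) in mm.  Near-parallel pairs get ``gap = inf`` rather than an
    exception so that callers can filter them out wholesale.
    """
    uv_ir = np.atleast_2d(np.asarray(uv_ir, dtype=float))
    uv_rgb = np.atleast_2d(np.asarray(uv_rgb, dtype=float))
    da = backproject(uv_ir, K_ir)                      # (N,3), origin 0
    d_rgb = backproject(uv_rgb, K_rgb)                 # in RGB frame
    Rt = rgb_from_ir.rotation.T
    db = d_rgb @ Rt.T                                  # rotate into IR frame
    ob = rgb_from_ir.camera_center
    c = np.einsum("ij,ij->i", da, db)
    denom = 1.0 - c * c
    w = -ob                                            # origin_a - origin_b
    daw = da @ w
    dbw = db @ w
    with np.errstate(divide="ignore", invalid="ignore"):
        ta = (c * dbw - daw) / denom
        tb = (dbw - c * daw) / denom
    pa = ta[:, None] * da
    pb = ob + tb[:, None] * db
    points = 0.5 * (pa + pb)
    gaps = np.linalg.norm(pa - pb, axis=1)
    bad = np.abs(c) > 1.0 - 1e-9
    gaps[bad] = np.inf
    return points, gaps


def load_rig(path: str | Path) -> Rig:
    """Read a camera parameter file (JSON or YAML)."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        d = yaml.safe_load(text)
    else:
        d = json.loads(text)
    return Rig.from_dict(d)


def save_rig(rig: Rig, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(rig.to_dict()))
    else:
        path.write_text(json.dumps(rig.to_dict(), indent=2))
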