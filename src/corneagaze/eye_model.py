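"""Per-user 3D eyeball model.

The eyeball is modelled as a sphere of fixed anatomical radius 12 mm.  Pupil
boundary points detected simultaneously in the two eye cameras are
triangulated to 3D surface points; the sphere centre is then the least-squares
solution of

    min_c  sum_i ( ||p_i - c|| - 12 )^2

solved by Gauss-Newton with an analytic Jacobian.  The fitted sphere turns the
two eye cameras into a point-to-point mapping: a pixel in the IR image
backprojects to a ray, the ray meets the sphere at the camera-facing surface
point, and that 3D point reprojects into the RGB eye camera.  The optical
axis (the gaze ray) runs from the sphere centre through the pupil-centre
surface point; the visual-axis offset (kappa) is not modelled.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.optimize import minimize

from .camera_geometry import (
    CameraIntrinsics,
    Ray,
    RigidTransform,
    backproject,
    project,
    triangulate_pixel_pairs,
)

__all__ = [
    "EYEBALL_RADIUS_MM",
    "EyeballModel",
    "CorrespondenceSet",
    "EyeModelError",
    "InsufficientDataError",
    "ConvergenceError",
    "NoIntersectionError",
    "build_eye_model",
    "ray_sphere_intersect",
    "map_ir_to_rgb",
    "gaze_ray",
]

EYEBALL_RADIUS_MM = 12.0


class EyeModelError(ValueError):
    pass


class InsufficientDataError(EyeModelError):
    """Fewer usable correspondences / frames than the method requires."""


class ConvergenceError(EyeModelError):
    """The sphere-centre optimisation did not converge."""


class NoIntersectionError(EyeModelError):
    """A backprojected ray misses the eyeball sphere."""


@dataclass(frozen=True)
class EyeballModel:
    """Sphere centre in the IR-camera frame (mm) with fixed 12 mm radius."""

    center: np.ndarray
    n_support_points: int
    rms_residual: float
    radius: float = EYEBALL_RADIUS_MM

    def __post_init__(self) -> None:
        object.__setattr__(self, "center",
                           np.asarray(self.center, dtype=float).reshape(3))
        if self.radius != EYEBALL_RADIUS_MM:
            raise ValueError("eyeball radius is fixed at 12 mm")
        if self.n_support_points < 4:
            raise ValueError("a sphere centre needs at least 4 support points")
        if self.rms_residual < 0:
            raise ValueError("rms_residual must be non-negative")

    def to_json(self, path: str | Path | None = None) -> dict:
        d = {
            "center_mm": self.center.tolist(),
            "radius_mm": self.radius,
            "n_support_points": int(self.n_support_points),
            "rms_residual_mm": float(self.rms_residual),
        }
        if path is not None:
            Path(path).write_text(json.dumps(d, indent=2))
        return d

    @classmethod
    def from_json(cls, src: str | Path | dict) -> "EyeballModel":
        if not isinstance(src, dict):
            src = json.loads(Path(src).read_text())
        return cls(center=np.asarray(src["center_mm"], dtype=float),
                   n_support_points=int(src["n_support_points"]),
                   rms_residual=float(src["rms_residual_mm"]))


@dataclass(frozen=True)
class CorrespondenceSet:
    """Paired pupil-boundary pixels from timestamp-paired IR/RGB frames."""

    ir: np.ndarray
    rgb: np.ndarray

    def __post_init__(self) -> None:
        ir = np.atleast_2d(np.asarray(self.ir, dtype=float))
        rgb = np.atleast_2d(np.asarray(self.rgb, dtype=float))
        if ir.shape != rgb.shape or ir.shape[1] != 2:
            raise ValueError("ir and rgb must both be (N, 2) pixel arrays")
        object.__setattr__(self, "ir", ir)
        object.__setattr__(self, "rgb", rgb)

    def __len__(self) -> int:
        return self.ir.shape[0]


def _fit_sphere_center(points: np.ndarray,
                       radius: float = EYEBALL_RADIUS_MM,
                       max_iter: int = 100,
                       tol: float = 1e-12) -> tuple[np.ndarray, float]:
    """Gauss-Newton fit of the sphere centre with the radius held fixed.

    Initialised at (mean of points) + radius * (unit mean viewing direction):
    the cameras see the near surface, so the centre lies one radius deeper
    along the mean line of sight.  Falls back to Nelder-Mead if Gauss-Newton
    stalls (near-degenerate point caps).
    """
    pbar = points.mean(axis=0)
    c = pbar + radius * pbar / np.linalg.norm(pbar)
    converged = False
    for _ in range(max_iter):
        diff = points - c
        dist = np.linalg.norm(diff, axis=1)
        r = dist - radius
        J = -diff / dist[:, None]
        JtJ = J.T @ J
        Jtr = J.T @ r
        try:
            delta = np.linalg.solve(JtJ, -Jtr)
        except np.linalg.LinAlgError:
            break
        c = c + delta
        if np.linalg.norm(delta) < tol:
            converged = True
            break
    if not converged:
        def cost(x):
            return float(np.sum((np.linalg.norm(points - x, axis=1) - radius) ** 2))
        res = minimize(cost, c, method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-18, "maxiter": 5000})
        if not res.success:
            raise ConvergenceError("sphere-centre fit did not converge")
        c = res.x
    rms = float(np.sqrt(np.mean((np.linalg.norm(points - c, axis=1) - radius) ** 2)))
    return c, rms


def build_eye_model(
    corr: CorrespondenceSet,
    K_ir: CameraIntrinsics,
    K_rgb: CameraIntrinsics,
    rig: RigidTransform,
    gap_max: float = 2.0,
) -> EyeballModel:
    """Fit the eyeball sphere from stereo pupil-boundary correspondences.

    Each pair is triangulated; pairs whose rays pass farther than ``gap_max``
    mm from each other are rejected as mismatches before the fixed-radius
    sphere fit.
    """
    if len(corr) < 4:
        raise InsufficientDataError(
            f"need at least 4 correspondences, got {len(corr)}")
    points, gaps = triangulate_pixel_pairs(corr.ir, corr.rgb, K_ir, K_rgb, rig)
    keep = gaps < gap_max
    if keep.sum() < 4:
        raise InsufficientDataError(
            f"only {int(keep.sum())} pairs survive the {gap_max} mm gap cut")
    points = points[keep]
    center, rms = _fit_sphere_center(points)
    return EyeballModel(center=center, n_support_points=int(keep.sum()),
                        rms_residual=rms)


def ray_sphere_intersect(ray: Ray, model: EyeballModel) -> np.ndarray:
    """Near intersection of a ray with the eyeball sphere.

    Solves ||o + t d - c||^2 = r^2 and returns the root closer to the ray
    origin: a visible pupil lies on the camera-facing hemisphere, so the far
    root is anatomically impossible.
    """
    oc = ray.origin - model.center
    if np.linalg.norm(oc) <= model.radius:
        raise EyeModelError("ray origin lies inside the sphere")
    b = 2.0 * float(np.dot(ray.direction, oc))
    cterm = float(np.dot(oc, oc)) - model.radius ** 2
    disc = b * b - 4.0 * cterm
    if disc < 0:
        raise NoIntersectionError("ray misses the eyeball sphere")
    t = (-b - np.sqrt(disc)) / 2.0
    if t < 0:
        raise NoIntersectionError("sphere lies behind the ray origin")
    return ray.point_at(float(t))


def _intersect_many(dirs: np.ndarray, origin: np.ndarray,
                    model: EyeballModel) -> np.ndarray:
    """Near ray-sphere roots for a stack of unit directions from one origin."""
    oc = origin - model.center
    b = 2.0 * dirs @ oc
    cterm = float(np.dot(oc, oc)) - model.radius ** 2
    disc = b * b - 4.0 * cterm
    if np.any(disc < 0):
        raise NoIntersectionError("a ray misses the eyeball sphere")
    t = (-b - np.sqrt(disc)) / 2.0
    if np.any(t < 0):
        raise NoIntersectionError("sphere lies behind the ray origin")
    return origin + t[:, None] * dirs


def map_ir_to_rgb(
    q: np.ndarray,
    model: EyeballModel,
    K_ir: CameraIntrinsics,
    K_rgb: CameraIntrinsics,
    rig: RigidTransform,
) -> np.ndarray:
    """Map IR-image pixel(s) to RGB-image pixel(s) through the eyeball surface.

    Backproject in the IR camera, intersect the sphere (near root), move the
    3D point into the RGB frame and project.  Accepts (2,) or (N, 2).
    """
    q = np.asarray(q, dtype=float)
    single = q.ndim == 1
    dirs = backproject(np.atleast_2d(q), K_ir)
    pts = _intersect_many(dirs, np.zeros(3), model)
    uv = project(rig.apply(pts), K_rgb)
    return uv[0] if single else uv


def gaze_ray(model: EyeballModel, pupil_center_ir: np.ndarray,
             K_ir: CameraIntrinsics) -> Ray:
    """Optical axis: from the eyeball centre through the pupil-centre surface
    point, pointing out of the eye (towards the cameras/world)."""
    ray = backproject(np.asarray(pupil_center_ir, dtype=float), K_ir)
    surface = ray_sphere_intersect(ray, model)
    return Ray(origin=model.center, direction=surface - model.center)
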