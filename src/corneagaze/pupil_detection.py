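"""Pupil detection in IR eye images.

A classical detector (dark-region segmentation + least-squares ellipse fit)
standing behind the same output contract as a learned detector: pupil centre,
bounding box, fitted ellipse and a confidence score.  The module boundary is
deliberately narrow so a trained network can be dropped in without touching
downstream stages.

Detection on RGB eye images is not attempted: real-world reflections make the
pupil boundary unreliable there, which is exactly why the pipeline maps IR
detections into the RGB image through the 3D eyeball model instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import binary_fill_holes
from skimage.filters import threshold_otsu
from skimage.measure import find_contours, label, regionprops

__all__ = [
    "DetectionConfig",
    "PupilDetection",
    "PupilNotFoundError",
    "detect_pupil_ir",
    "sample_boundary_points",
    "fit_ellipse",
    "detection_from_boundary",
]


class PupilNotFoundError(ValueError):
    """No plausible pupil component in the image; caller skips the frame."""


@dataclass(frozen=True)
class DetectionConfig:
    min_area_frac: float = 0.001
    max_area_frac: float = 0.05
    n_boundary_points: int = 32
    dark_quantile: float = 0.20


@dataclass(frozen=True)
class PupilDetection:
    """Pupil centre, axis-aligned bbox (u_min, v_min, w, h), fitted ellipse
    (xc, yc, a, b, theta) with semi-axes a >= b > 0, and a score in [0, 1]."""

    center: tuple[float, float]
    bbox: tuple[float, float, float, float]
    ellipse: tuple[float, float, float, float, float]
    score: float = 1.0

    def __post_init__(self) -> None:
        u, v = self.center
        u0, v0, w, h = self.bbox
        a, b = self.ellipse[2], self.ellipse[3]
        if not (a >= b > 0):
            raise ValueError("ellipse semi-axes must satisfy a >= b > 0")
        if not (u0 - 1e-6 <= u <= u0 + w + 1e-6 and
                v0 - 1e-6 <= v <= v0 + h + 1e-6):
            raise ValueError("centre must lie inside the bounding box")
        if not 0.0 <= self.score <= 1.0:
            raise ValueError("score must be in [0, 1]")

    @property
    def bbox_corners(self) -> np.ndarray:
        u0, v0, w, h = self.bbox
        return np.array([[u0, v0], [u0 + w, v0], [u0 + w, v0 + h], [u0, v0 + h]])


def _normalize_ellipse(xc, yc, a, b, theta):
    if b > a:
        a, b = b, a
        theta = theta + np.pi / 2
    theta = (theta + np.pi / 2) % np.pi - np.pi / 2
    return float(xc), float(yc), float(a), float(b), float(theta)


def _conic_to_params(A, B, C, D, E, F):
    M = np.array([[2 * A, B], [B, 2 * C]])
    try:
        xc, yc = np.linalg.solve(M, [-D, -E])
    except np.linalg.LinAlgError as exc:
        raise PupilNotFoundError("degenerate conic (no centre)") from exc
    F0 = A * xc * xc + B * xc * yc + C * yc * yc + D * xc + E * yc + F
    lam, vec = np.linalg.eigh(np.array([[A, B / 2], [B / 2, C]]))
    with np.errstate(divide="ignore", invalid="ignore"):
        axes2 = -F0 / lam
    if np.any(axes2 <= 0) or not np.all(np.isfinite(axes2)):
        raise PupilNotFoundError("conic is not an ellipse")
    axes = np.sqrt(axes2)
    i_major = int(np.argmax(axes))
    a, b = axes[i_major], axes[1 - i_major]
    theta = float(np.arctan2(vec[1, i_major], vec[0, i_major]))
    return xc, yc, a, b, theta


def fit_ellipse(points_uv: np.ndarray) -> tuple[tuple, float]:
    """Least-squares ellipse through boundary points (N, 2) in (u, v).

    Numerically stable direct fit (the Halir-Flusser partitioning of the
    Fitzgibbon ellipse-specific scatter problem), which stays well-behaved
    for the near-circular contours a frontal pupil produces.  Returns
    ``((xc, yc, a, b, theta), rms_residual)`` with semi-axes a >= b; the
    residual is the Sampson (gradient-normalised algebraic) distance.
    """
    pts = np.asarray(points_uv, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 5:
        raise PupilNotFoundError("need at least 5 boundary points")
    mean = pts.mean(axis=0)
    x, y = (pts - mean).T
    D1 = np.column_stack([x * x, x * y, y * y])
    D2 = np.column_stack([x, y, np.ones_like(x)])
    S1, S2, S3 = D1.T @ D1, D1.T @ D2, D2.T @ D2
    try:
        T = -np.linalg.solve(S3, S2.T)
    except np.linalg.LinAlgError as exc:
        raise PupilNotFoundError("degenerate point configuration") from exc
    M = S1 + S2 @ T
    M = np.array([M[2] / 2.0, -M[1], M[0] / 2.0])
    eigval, eigvec = np.linalg.eig(M)
    # ellipse-specific constraint 4ac - b^2 > 0 selects the solution
    v = np.real(eigvec)
    cond = 4 * v[0] * v[2] - v[1] ** 2
    ok = np.isreal(eigval) & (cond > 0)
    if not np.any(ok):
        raise PupilNotFoundError("no ellipse solution")
    a1 = v[:, np.argmax(ok)]
    A, B, C = a1
    D, E, F = T @ a1
    # undo the centroid shift
    D, E, F = (D - 2 * A * mean[0] - B * mean[1],
               E - 2 * C * mean[1] - B * mean[0],
               F + A * mean[0] ** 2 + B * mean[0] * mean[1]
               + C * mean[1] ** 2 - D * mean[0] - E * mean[1])
    xc, yc, a, b, theta = _conic_to_params(A, B, C, D, E, F)
    if not (np.isfinite([xc, yc, a, b, theta]).all() and a > 0 and b > 0):
        raise PupilNotFoundError("degenerate ellipse fit")
    params = _normalize_ellipse(xc, yc, a, b, theta)
    rms = float(np.sqrt(np.mean(ellipse_residuals(params, pts) ** 2)))
    return params, rms


def ellipse_residuals(params: tuple, pts: np.ndarray) -> np.ndarray:
    """Sampson distance of points to an ellipse (first-order geometric)."""
    xc, yc, a, b, theta = params
    ct, st = np.cos(theta), np.sin(theta)
    dx, dy = pts[:, 0] - xc, pts[:, 1] - yc
    xe = (dx * ct + dy * st) / a
    ye = (-dx * st + dy * ct) / b
    f = xe * xe + ye * ye - 1.0
    grad = 2.0 * np.sqrt((xe / a) ** 2 + (ye / b) ** 2)
    return np.abs(f) / np.maximum(grad, 1e-12)


def _ellipse_bbox(ellipse, image_shape=None):
    xc, yc, a, b, theta = ellipse
    # axis-aligned half-extents of a rotated ellipse
    hw = np.hypot(a * np.cos(theta), b * np.sin(theta))
    hh = np.hypot(a * np.sin(theta), b * np.cos(theta))
    u0, v0, u1, v1 = xc - hw, yc - hh, xc + hw, yc + hh
    if image_shape is not None:
        H, W = image_shape[:2]
        u0, v0 = max(u0, 0.0), max(v0, 0.0)
        u1, v1 = min(u1, W - 1.0), min(v1, H - 1.0)
    return (u0, v0, u1 - u0, v1 - v0)


def detection_from_boundary(points_uv: np.ndarray,
                            center_uv: np.ndarray | None = None,
                            image_shape=None) -> PupilDetection:
    """Build a :class:`PupilDetection` from boundary samples alone.

    Used by the synthetic observation path, where boundary points (with
    injected noise) play the role of the segmented pupil contour.
    """
    ellipse, rms = fit_ellipse(points_uv)
    if center_uv is None:
        center_uv = ellipse[:2]
    bbox = _ellipse_bbox(ellipse, image_shape)
    u = float(np.clip(center_uv[0], bbox[0], bbox[0] + bbox[2]))
    v = float(np.clip(center_uv[1], bbox[1], bbox[1] + bbox[3]))
    return PupilDetection(center=(u, v), bbox=bbox, ellipse=ellipse,
                          score=1.0 / (1.0 + rms))


def detect_pupil_ir(image: np.ndarray,
                    params: DetectionConfig = DetectionConfig()) -> PupilDetection:
    """Detect the pupil in a single-channel IR eye image.

    The pupil is the darkest compact blob: Otsu's threshold restricted to the
    darkest ``dark_quantile`` of the histogram separates it from iris/shadow
    tones, the largest connected component with a plausible area fraction is
    kept, and an ellipse is fitted to its sub-pixel contour.
    """
    img = np.asarray(image)
    if img.ndim != 2:
        raise ValueError("expected a single-channel image")
    if img.shape[0] < 64 or img.shape[1] < 64:
        raise ValueError("image must be at least 64x64")
    img = img.astype(float)
    qcut = np.quantile(img, params.dark_quantile)
    dark = img[img <= qcut]
    if dark.size == 0 or np.ptp(dark) < 1e-9:
        raise PupilNotFoundError("no dark structure in the image")
    try:
        thr = threshold_otsu(dark)
    except ValueError as exc:
        raise PupilNotFoundError("thresholding failed") from exc
    mask = img <= thr
    lab = label(mask)
    area = img.shape[0] * img.shape[1]
    lo, hi = params.min_area_frac * area, params.max_area_frac * area
    candidates = [r for r in regionprops(lab) if lo <= r.area <= hi]
    if not candidates:
        raise PupilNotFoundError("no component with plausible pupil area")
    region = max(candidates, key=lambda r: r.area)
    comp = binary_fill_holes(lab == region.label)
    contours = find_contours(comp.astype(float), 0.5)
    if not contours:
        raise PupilNotFoundError("component has no contour")
    contour = max(contours, key=len)             # (row, col) sub-pixel
    pts_uv = contour[:, ::-1]
    ellipse, rms = fit_ellipse(pts_uv)
    bbox = _ellipse_bbox(ellipse, img.shape)
    u = float(np.clip(ellipse[0], bbox[0], bbox[0] + bbox[2]))
    v = float(np.clip(ellipse[1], bbox[1], bbox[1] + bbox[3]))
    return PupilDetection(center=(u, v), bbox=bbox, ellipse=ellipse,
                          score=_detection_score(img, comp, bbox, rms))


def _detection_score(img: np.ndarray, comp: np.ndarray, bbox, rms: float) -> float:
    """Confidence in [0, 1]: pupil/surround contrast separation (a d'-like
    statistic that degrades with pixel noise) times boundary-fit quality."""
    u0, v0, w, h = bbox
    r0 = int(max(v0 - h, 0)); r1 = int(min(v0 + 2 * h, img.shape[0]))
    c0 = int(max(u0 - w, 0)); c1 = int(min(u0 + 2 * w, img.shape[1]))
    win = img[r0:r1, c0:c1]
    inwin = comp[r0:r1, c0:c1]
    vals_in, vals_out = win[inwin], win[~inwin]
    if vals_in.size == 0 or vals_out.size == 0:
        return 0.0
    sep = (vals_out.mean() - vals_in.mean()) / (
        1.0 + vals_in.std() + vals_out.std())
    sep = max(sep, 0.0)
    return float((sep / (1.0 + sep)) / (1.0 + rms))


def sample_boundary_points(det: PupilDetection, n: int) -> np.ndarray:
    """``n`` points evenly spaced in parameter angle on the fitted ellipse."""
    if n < 4:
        raise ValueError("need n >= 4 boundary points")
    xc, yc, a, b, theta = det.ellipse
    t = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    ct, st = np.cos(theta), np.sin(theta)
    u = xc + a * np.cos(t) * ct - b * np.sin(t) * st
    v = yc + a * np.cos(t) * st + b * np.sin(t) * ct
    return np.stack([u, v], axis=1)
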