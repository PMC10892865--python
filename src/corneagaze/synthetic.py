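"""Synthetic data generation: rigs, eyes, gaze sessions and rendered triads.

Everything the pipeline consumes can be simulated with full ground truth, so
each stage — and the end-to-end system — is testable with no hardware:

* a three-camera rig (IR eye 800x600, RGB eye 1280x960, front scene
  1280x960) with a randomized 5-15 mm eye-camera baseline;
* a sphere-eye of radius 12 mm carrying a circular pupil (default 2 mm
  radius) whose boundary projects to exact ellipses in both eye cameras;
* Gaussian pixel noise on detections, plus feature-match noise and outliers;
* a world modelled as a textured plane, so the corneal-to-scene mapping is
  exactly a homography and scene gaze ground truth is well defined.  The
  mapping is held constant over a session in pupil-centred (crop-local,
  mirrored) coordinates — the regime in which pooling all calibration pairs
  into a single homography is geometrically exact;
* optionally, rendered image triads in which the corneal patch is a
  projectively warped, mirrored, blurred, downsampled copy of the scene.

Streams are timestamped at 20 fps with jitter and paired at 1 fps by nearest
timestamp, mirroring the capture protocol the pipeline expects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from skimage.draw import disk as draw_disk
from skimage.filters import gaussian
from skimage.transform import ProjectiveTransform, resize, warp

from .camera_geometry import CameraIntrinsics, CameraIntrinsics as _K  # noqa: F401
from .camera_geometry import RigidTransform, Rig, project
from .corneal_imaging import corneal_gaze_point, transform_bbox
from .eye_model import EYEBALL_RADIUS_MM, CorrespondenceSet, EyeballModel
from .pupil_detection import PupilDetection, detection_from_boundary
from .scene_mapping import FeatureMatchSet, apply_homography

__all__ = [
    "SyntheticScenario",
    "EventObservation",
    "EventTruth",
    "SessionObservations",
    "GroundTruthBundle",
    "make_rig",
    "make_scenario",
    "simulate_session",
    "correspondence_set",
    "match_sets",
    "make_texture",
    "render_triad",
    "integer_crop_and_homography",
    "pair_nearest_timestamps",
]

logger = logging.getLogger(__name__)

CORNEAL_MIRROR_FOCAL_MM = 3.9   # half the ~7.8 mm corneal curvature radius


def make_rig(seed: int | np.random.Generator = 0) -> Rig:
    """Random plausible headset: eye cameras a few mm apart, both aimed at
    the nominal eye position, plus a front-scene camera."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    K_ir = CameraIntrinsics(
        fx=(f := rng.uniform(650, 750)), fy=f * rng.uniform(0.99, 1.01),
        cx=400 + rng.uniform(-10, 10), cy=300 + rng.uniform(-10, 10),
        width=800, height=600)
    # eye-camera focal lengths frame the whole eye region (~25 mm) at the
    # pupil's working depth, so the pupil stays in view across natural gaze
    K_rgb = CameraIntrinsics(
        fx=(f := rng.uniform(1000, 1200)), fy=f * rng.uniform(0.99, 1.01),
        cx=640 + rng.uniform(-15, 15), cy=480 + rng.uniform(-15, 15),
        width=1280, height=960)
    K_front = CameraIntrinsics(
        fx=(f := rng.uniform(1000, 1200)), fy=f * rng.uniform(0.99, 1.01),
        cx=640 + rng.uniform(-10, 10), cy=480 + rng.uniform(-10, 10),
        width=1280, height=960)

    eye_nominal = np.array([0.0, 0.0, 35.0])
    baseline = rng.uniform(5.0, 15.0)
    phi = rng.uniform(-0.3, 0.3)
    C = np.array([baseline * np.cos(phi), baseline * np.sin(phi),
                  rng.uniform(-2.0, 2.0)])
    z = eye_nominal - C
    z = z / np.linalg.norm(z)
    x = np.cross([0.0, 1.0, 0.0], z)
    x = x / np.linalg.norm(x)
    y = np.cross(z, x)
    R = np.stack([x, y, z])            # rows: RGB-camera axes in IR frame
    rgb_from_ir = RigidTransform(R, -R @ C)
    return Rig(ir=K_ir, rgb=K_rgb, front=K_front, rgb_from_ir=rgb_from_ir)


@dataclass(frozen=True)
class SyntheticScenario:
    """One simulated auto-calibration + evaluation session.

    Defaults reproduce the study conditions the pipeline targets: 100
    eye-model frames, 220 pooled corneal/scene calibration pairs, 500
    evaluation gaze events, 1 px detection and feature noise, 20% match
    outliers.
    """

    seed: int
    rig: Rig
    eye_center: np.ndarray
    gaze_directions: np.ndarray
    pupil_radius: float = 2.0
    pixel_noise: float = 1.0
    feature_noise: float = 1.0
    outlier_frac: float = 0.2
    corneal_blur_sigma: float = 1.0
    corneal_downsample: int = 2
    n_boundary_points: int = 32
    n_model_frames: int = 100
    n_match_pairs: int = 220
    n_eval_events: int = 500
    n_matches_per_pair: int = 30
    gaze_cone_deg: float = 18.0
    margin_frac: float = 0.1
    fps: float = 20.0
    period: float = 1.0

    def __post_init__(self) -> None:
        c = np.asarray(self.eye_center, dtype=float).reshape(3)
        object.__setattr__(self, "eye_center", c)
        g = np.asarray(self.gaze_directions, dtype=float).reshape(-1, 3)
        object.__setattr__(self, "gaze_directions", g)
        if not (25.0 <= c[2] <= 60.0):
            raise ValueError("eyeball centre depth must be within [25, 60] mm")
        for name in ("pixel_noise", "feature_noise", "outlier_frac",
                     "corneal_blur_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not np.allclose(np.linalg.norm(g, axis=1), 1.0, atol=1e-9):
            raise ValueError("gaze directions must be unit vectors")
        if self.n_match_pairs < self.n_model_frames:
            raise ValueError("n_match_pairs must include the model frames")

    @property
    def n_total(self) -> int:
        return (self.n_model_frames
                + (self.n_match_pairs - self.n_model_frames)
                + self.n_eval_events)


def _sample_cone(rng: np.random.Generator, axis: np.ndarray,
                 half_angle_deg: float, n: int) -> np.ndarray:
    """Uniform directions within a cone around ``axis``."""
    axis = axis / np.linalg.norm(axis)
    a = np.cross(axis, [0.0, 1.0, 0.0])
    if np.linalg.norm(a) < 1e-6:
        a = np.cross(axis, [1.0, 0.0, 0.0])
    a = a / np.linalg.norm(a)
    b = np.cross(axis, a)
    cos_max = np.cos(np.radians(half_angle_deg))
    cosT = rng.uniform(cos_max, 1.0, n)
    sinT = np.sqrt(1 - cosT ** 2)
    phi = rng.uniform(0, 2 * np.pi, n)
    return (cosT[:, None] * axis
            + sinT[:, None] * (np.cos(phi)[:, None] * a
                               + np.sin(phi)[:, None] * b))


def make_scenario(seed: int, **overrides) -> SyntheticScenario:
    """Deterministically build a scenario (rig, eye, gaze list) from a seed.

    ``overrides`` replace any :class:`SyntheticScenario` field except the
    sampled rig / eye / gaze list (pass those explicitly to pin them).
    """
    rng = np.random.default_rng([int(seed), 0])
    rig = overrides.pop("rig", None) or make_rig(rng)
    eye_center = overrides.pop("eye_center", None)
    if eye_center is None:
        eye_center = np.array([rng.uniform(-3, 3), rng.uniform(-3, 3),
                               rng.uniform(30, 45)])
    probe = SyntheticScenario(seed=int(seed), rig=rig, eye_center=eye_center,
                              gaze_directions=np.array([[0.0, 0.0, -1.0]]),
                              **{k: v for k, v in overrides.items()
                                 if k != "gaze_directions"})
    gaze = overrides.pop("gaze_directions", None)
    if gaze is None:
        axis = -probe.eye_center / np.linalg.norm(probe.eye_center)
        gaze = _sample_cone(rng, axis, probe.gaze_cone_deg, probe.n_total)
    return replace(probe, gaze_directions=gaze)


@dataclass(frozen=True)
class EventObservation:
    """What the pipeline is allowed to see for one triad."""

    event_id: int
    kind: str                       # 'model' | 'match' | 'eval'
    t_ir: float
    t_rgb: float
    detection: PupilDetection
    boundary_ir: np.ndarray
    boundary_rgb: np.ndarray | None
    matches: FeatureMatchSet | None


@dataclass(frozen=True)
class EventTruth:
    """Noiseless ground truth for one triad."""

    event_id: int
    kind: str
    gaze_dir: np.ndarray
    pupil_center_3d: np.ndarray
    center_ir: np.ndarray
    center_rgb: np.ndarray
    boundary_ir: np.ndarray
    boundary_rgb: np.ndarray
    ellipse_ir: tuple
    ellipse_rgb: tuple
    bbox_ir: tuple
    bbox_rgb: tuple
    gaze_point_crop: tuple
    scene_gaze: np.ndarray


@dataclass(frozen=True)
class SessionObservations:
    rig: Rig
    scenario: SyntheticScenario
    events: list[EventObservation]


@dataclass(frozen=True)
class GroundTruthBundle:
    eye_center: np.ndarray
    radius: float
    H_session: np.ndarray          # crop-local (mirrored) -> scene pixels
    events: list[EventTruth]
    skipped: list[tuple[int, str]]


def pair_nearest_timestamps(times_ir: np.ndarray, times_rgb: np.ndarray,
                            period: float = 1.0) -> list[tuple[int, int]]:
    """Select, per ``period`` window, the IR/RGB frame pair with the nearest
    timestamps; at most one pair per window, none for empty windows."""
    times_ir = np.asarray(times_ir, dtype=float)
    times_rgb = np.asarray(times_rgb, dtype=float)
    if len(times_ir) == 0 or len(times_rgb) == 0:
        return []
    win_ir = np.floor(times_ir / period).astype(int)
    win_rgb = np.floor(times_rgb / period).astype(int)
    pairs = []
    for w in sorted(set(win_ir.tolist()) & set(win_rgb.tolist())):
        ii = np.nonzero(win_ir == w)[0]
        jj = np.nonzero(win_rgb == w)[0]
        dt = np.abs(times_ir[ii][:, None] - times_rgb[jj][None, :])
        k = np.unravel_index(np.argmin(dt), dt.shape)
        pairs.append((int(ii[k[0]]), int(jj[k[1]])))
    return pairs


def _pupil_ring(center: np.ndarray, gaze: np.ndarray, pupil_radius: float,
                n: int) -> tuple[np.ndarray, np.ndarray]:
    """3D pupil boundary circle on the sphere, plus the pupil-centre pole."""
    g = gaze / np.linalg.norm(gaze)
    a = np.cross(g, [0.0, 1.0, 0.0])
    if np.linalg.norm(a) < 1e-6:
        a = np.cross(g, [1.0, 0.0, 0.0])
    a = a / np.linalg.norm(a)
    b = np.cross(g, a)
    alpha = np.arcsin(pupil_radius / EYEBALL_RADIUS_MM)
    phi = np.linspace(0, 2 * np.pi, n, endpoint=False)
    ring = center + EYEBALL_RADIUS_MM * (
        np.cos(alpha) * g[None, :]
        + np.sin(alpha) * (np.cos(phi)[:, None] * a[None, :]
                           + np.sin(phi)[:, None] * b[None, :]))
    pole = center + EYEBALL_RADIUS_MM * g
    return ring, pole


def _session_homography(rng: np.random.Generator, rig: Rig,
                        crop_size: tuple[float, float],
                        pupil_depth: float) -> np.ndarray:
    """Corneal-crop -> scene homography for a session.

    The magnification follows the convex-mirror model: a corneal pixel spans
    ``z_p / f_rgb`` mm on the cornea, i.e. an angular field of that length
    divided by the mirror focal length (half the corneal curvature radius),
    which the front camera renders at ``f_front`` px/rad.  A small rotation
    and mild projective terms stand in for mount misalignment and the
    oblique reflection geometry.
    """
    w0, h0 = crop_size
    mag = (rig.front.fx * pupil_depth) / (rig.rgb.fx * CORNEAL_MIRROR_FOCAL_MM)
    theta = rng.uniform(-np.radians(10), np.radians(10))
    p1, p2 = rng.uniform(-5e-5, 5e-5, 2)
    anchor = np.array([rig.front.cx, rig.front.cy]) + rng.uniform(
        -0.15, 0.15, 2) * [rig.front.width, rig.front.height]
    T_back = np.array([[1, 0, -w0 / 2], [0, 1, -h0 / 2], [0, 0, 1.0]])
    P = np.array([[1, 0, 0], [0, 1, 0], [p1, p2, 1.0]])
    S = np.diag([mag, mag, 1.0])
    Rm = np.array([[np.cos(theta), -np.sin(theta), 0],
                   [np.sin(theta), np.cos(theta), 0], [0, 0, 1.0]])
    T_fwd = np.array([[1, 0, anchor[0]], [0, 1, anchor[1]], [0, 0, 1.0]])
    H = T_fwd @ Rm @ S @ P @ T_back
    return H / H[2, 2]


def _gen_matches(rng: np.random.Generator, H: np.ndarray,
                 crop_size: tuple[float, float], scene: CameraIntrinsics,
                 n: int, noise: float, outlier_frac: float,
                 pair_id: int) -> FeatureMatchSet:
    """Noisy inlier matches from H plus uniform outliers, in crop coords."""
    w, h = crop_size
    src = np.empty((0, 2))
    # rejection-sample source points whose true image lies inside the scene
    for _ in range(50):
        cand = rng.uniform([0, 0], [w, h], size=(4 * n, 2))
        dst = apply_homography(H, cand)
        ok = ((dst[:, 0] >= 0) & (dst[:, 0] <= scene.width - 1)
              & (dst[:, 1] >= 0) & (dst[:, 1] <= scene.height - 1))
        src = np.vstack([src, cand[ok]])
        if len(src) >= n:
            break
    src = src[:n]
    dst = apply_homography(H, src) + rng.normal(0, noise, (len(src), 2))
    n_out = int(round(outlier_frac * len(src)))
    if n_out:
        out_idx = rng.choice(len(src), n_out, replace=False)
        dst[out_idx] = rng.uniform([0, 0],
                                   [scene.width - 1, scene.height - 1],
                                   size=(n_out, 2))
    dist = rng.uniform(0.10, 0.35, len(src))
    if n_out:
        dist[out_idx] = rng.uniform(0.30, 0.80, n_out)
    return FeatureMatchSet(src=src, dst=dst, distance=dist,
                           pair_id=np.full(len(src), pair_id, dtype=int))


def _in_frame(uv: np.ndarray, K: CameraIntrinsics, pad: float = 5.0) -> bool:
    uv = np.atleast_2d(uv)
    return bool(np.all((uv[:, 0] >= pad) & (uv[:, 0] <= K.width - 1 - pad)
                       & (uv[:, 1] >= pad) & (uv[:, 1] <= K.height - 1 - pad)))


def simulate_session(scenario: SyntheticScenario
                     ) -> tuple[SessionObservations, GroundTruthBundle]:
    """Generate one full session: observations the pipeline may consume and
    the ground truth it is judged against.

    Deterministic given the scenario seed.  Gaze events whose pupil faces
    away from the eye cameras, or whose projections leave an eye-camera
    frame, are skipped with a logged reason.
    """
    sc = scenario
    rng = np.random.default_rng([sc.seed, 1])
    rig = sc.rig
    c = sc.eye_center
    true_model = EyeballModel(center=c, n_support_points=4, rms_residual=0.0)
    to_cam = -c / np.linalg.norm(c)

    # nominal crop geometry anchors the session homography
    ring0, pole0 = _pupil_ring(c, to_cam, sc.pupil_radius, 64)
    det0 = detection_from_boundary(project(ring0, rig.ir))
    bbox0 = transform_bbox(det0, true_model, rig.ir, rig.rgb, rig.rgb_from_ir,
                           sc.margin_frac)
    H_sess = _session_homography(rng, rig, (bbox0[2], bbox0[3]), pole0[2])

    n_stream = int(np.ceil(sc.n_total * sc.period * sc.fps)) + int(sc.fps)
    jitter = 0.4 / sc.fps
    t_ir = np.arange(n_stream) / sc.fps + rng.uniform(0, jitter, n_stream)
    t_rgb = np.arange(n_stream) / sc.fps + rng.uniform(0, jitter, n_stream)
    pairs = pair_nearest_timestamps(t_ir, t_rgb, sc.period)

    kinds = (["model"] * sc.n_model_frames
             + ["match"] * (sc.n_match_pairs - sc.n_model_frames)
             + ["eval"] * sc.n_eval_events)

    events: list[EventObservation] = []
    truths: list[EventTruth] = []
    skipped: list[tuple[int, str]] = []
    for k, (kind, g) in enumerate(zip(kinds, sc.gaze_directions)):
        if np.dot(g, to_cam) < np.cos(np.radians(60)):
            logger.info("event %d skipped: pupil_not_visible", k)
            skipped.append((k, "pupil_not_visible"))
            continue
        ring, pole = _pupil_ring(c, g, sc.pupil_radius, sc.n_boundary_points)
        b_ir = project(ring, rig.ir)
        b_rgb = project(rig.rgb_from_ir.apply(ring), rig.rgb)
        c_ir = project(pole, rig.ir)
        c_rgb = project(rig.rgb_from_ir.apply(pole), rig.rgb)
        if not (_in_frame(b_ir, rig.ir) and _in_frame(b_rgb, rig.rgb)):
            logger.info("event %d skipped: projection_out_of_frame", k)
            skipped.append((k, "projection_out_of_frame"))
            continue

        det_true = detection_from_boundary(b_ir, c_ir,
                                           (rig.ir.height, rig.ir.width))
        det_rgb_true = detection_from_boundary(b_rgb, c_rgb,
                                               (rig.rgb.height, rig.rgb.width))
        bbox_rgb_t = transform_bbox(det_true, true_model, rig.ir, rig.rgb,
                                    rig.rgb_from_ir, sc.margin_frac)
        gaze_crop_t = corneal_gaze_point(bbox_rgb_t, c_rgb)
        scene_t = apply_homography(H_sess, np.asarray(gaze_crop_t))

        b_ir_n = b_ir + rng.normal(0, sc.pixel_noise, b_ir.shape)
        b_rgb_n = b_rgb + rng.normal(0, sc.pixel_noise, b_rgb.shape)
        c_ir_n = c_ir + rng.normal(0, sc.pixel_noise, 2)
        try:
            det = detection_from_boundary(b_ir_n, c_ir_n,
                                          (rig.ir.height, rig.ir.width))
        except ValueError:
            logger.info("event %d skipped: detection_failed", k)
            skipped.append((k, "detection_failed"))
            continue

        matches = _gen_matches(rng, H_sess, (bbox_rgb_t[2], bbox_rgb_t[3]),
                               rig.front, sc.n_matches_per_pair,
                               sc.feature_noise, sc.outlier_frac, k)
        i_ir, i_rgb = pairs[k]
        events.append(EventObservation(
            event_id=k, kind=kind, t_ir=float(t_ir[i_ir]),
            t_rgb=float(t_rgb[i_rgb]), detection=det, boundary_ir=b_ir_n,
            boundary_rgb=b_rgb_n if kind == "model" else None,
            matches=matches))
        truths.append(EventTruth(
            event_id=k, kind=kind, gaze_dir=g, pupil_center_3d=pole,
            center_ir=c_ir, center_rgb=c_rgb, boundary_ir=b_ir,
            boundary_rgb=b_rgb, ellipse_ir=det_true.ellipse,
            ellipse_rgb=det_rgb_true.ellipse, bbox_ir=det_true.bbox,
            bbox_rgb=bbox_rgb_t, gaze_point_crop=gaze_crop_t,
            scene_gaze=scene_t))

    obs = SessionObservations(rig=rig, scenario=sc, events=events)
    truth = GroundTruthBundle(eye_center=c, radius=EYEBALL_RADIUS_MM,
                              H_session=H_sess, events=truths,
                              skipped=skipped)
    return obs, truth


def correspondence_set(obs: SessionObservations,
                       max_pairs: int | None = None) -> CorrespondenceSet:
    """Pool IR/RGB boundary correspondences from the model frames."""
    ir, rgb = [], []
    for e in obs.events:
        if e.kind == "model" and e.boundary_rgb is not None:
            ir.append(e.boundary_ir)
            rgb.append(e.boundary_rgb)
    if not ir:
        raise ValueError("session has no model frames")
    ir_all = np.concatenate(ir)
    rgb_all = np.concatenate(rgb)
    if max_pairs is not None:
        ir_all, rgb_all = ir_all[:max_pairs], rgb_all[:max_pairs]
    return CorrespondenceSet(ir=ir_all, rgb=rgb_all)


def match_sets(obs: SessionObservations,
               kinds: tuple[str, ...] = ("model", "match")
               ) -> list[FeatureMatchSet]:
    """Per-pair corneal/scene match sets for homography calibration."""
    return [e.matches for e in obs.events
            if e.kind in kinds and e.matches is not None]


def make_texture(seed: int, shape: tuple[int, int] = (960, 1280),
                 n_blobs: int = 400) -> np.ndarray:
    """Procedural high-contrast planar scene (uint8 RGB): smoothed noise with
    scattered rectangles and disks, feature-rich enough for SIFT."""
    rng = np.random.default_rng([int(seed), 7])
    H, W = shape
    img = gaussian(rng.uniform(0, 1, (H, W, 3)), sigma=3, channel_axis=-1)
    img = 0.4 + 0.4 * (img - img.min()) / max(np.ptp(img), 1e-9)
    for _ in range(n_blobs):
        color = rng.uniform(0, 1, 3)
        if rng.random() < 0.5:
            r = int(rng.integers(3, 18))
            rr, cc = draw_disk((rng.integers(r, H - r), rng.integers(r, W - r)),
                               r, shape=(H, W))
        else:
            h, w = rng.integers(4, 30, 2)
            r0, c0 = rng.integers(0, H - h), rng.integers(0, W - w)
            rr, cc = np.meshgrid(np.arange(r0, r0 + h), np.arange(c0, c0 + w),
                                 indexing="ij")
            rr, cc = rr.ravel(), cc.ravel()
        img[rr, cc] = color
    return (np.clip(img, 0, 1) * 255).astype(np.uint8)


def integer_crop_and_homography(bbox_rgb: tuple, H_session: np.ndarray
                                ) -> tuple[tuple[int, int, int, int], np.ndarray]:
    """Integer pixel crop for a float bbox, and the per-frame true
    crop-to-scene homography for that integer crop.

    The session homography lives in float-crop mirrored coordinates; the
    integer crop differs from it by a pure translation.
    """
    u0f, v0f, wf, hf = bbox_rgb
    u0, v0 = int(np.floor(u0f)), int(np.floor(v0f))
    u1, v1 = int(np.ceil(u0f + wf)) + 1, int(np.ceil(v0f + hf)) + 1
    wi, hi = u1 - u0, v1 - v0
    # mirrored-u offset between the integer and float crop frames
    du = (u0f + wf) - (u0 + wi)
    dv = v0f - v0
    T = np.array([[1, 0, du], [0, 1, dv], [0, 0, 1.0]])
    Hf = H_session @ T
    return (u0, v0, wi, hi), Hf / Hf[2, 2]


def render_triad(truth: EventTruth, rig: Rig, scene_image: np.ndarray,
                 H_session: np.ndarray, blur_sigma: float = 1.0,
                 downsample: int = 2,
                 noise_rng: np.random.Generator | None = None
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Render one (IR eye, RGB eye, front scene) image triad.

    IR: bright background, darker iris disk, dark pupil ellipse at the true
    projection.  RGB: skin/iris background with the corneal patch — the
    scene warped through the true per-frame homography, mirrored, blurred
    and optionally downsampled — composited at the true pupil region.
    """
    if scene_image.shape[0] < 256 or scene_image.shape[1] < 256:
        raise ValueError("scene texture must be at least 256x256")
    scene = scene_image
    if scene.shape[:2] != (rig.front.height, rig.front.width):
        scene = (resize(scene, (rig.front.height, rig.front.width),
                        preserve_range=True, anti_aliasing=True)
                 .astype(scene_image.dtype))

    # --- IR eye image ---
    ir = np.full((rig.ir.height, rig.ir.width), 205.0)
    a_ir = truth.ellipse_ir[2]
    rr, cc = draw_disk((truth.center_ir[1], truth.center_ir[0]),
                       2.6 * a_ir, shape=ir.shape)
    ir[rr, cc] = 120.0
    # anti-aliased pupil ellipse: per-pixel coverage from the approximate
    # signed distance to the true projected conic, so the rasterised
    # boundary carries no half-pixel bias
    xc, yc, a, b, th = truth.ellipse_ir
    pad = int(np.ceil(max(a, b))) + 3
    r0 = max(int(yc) - pad, 0); r1 = min(int(yc) + pad + 1, ir.shape[0])
    c0 = max(int(xc) - pad, 0); c1 = min(int(xc) + pad + 1, ir.shape[1])
    vv, uu = np.mgrid[r0:r1, c0:c1]
    ct, st = np.cos(th), np.sin(th)
    dx, dy = uu - xc, vv - yc
    xe = (dx * ct + dy * st) / a
    ye = (-dx * st + dy * ct) / b
    sd = (np.sqrt(xe * xe + ye * ye) - 1.0) * b   # approx distance in px
    coverage = np.clip(0.5 - sd, 0.0, 1.0)
    ir[r0:r1, c0:c1] = ir[r0:r1, c0:c1] * (1 - coverage) + 30.0 * coverage
    if noise_rng is not None:
        ir = ir + noise_rng.normal(0, 2.0, ir.shape)
    ir_img = np.clip(ir, 0, 255).astype(np.uint8)

    # --- RGB eye image ---
    rgb = np.empty((rig.rgb.height, rig.rgb.width, 3))
    rgb[..., :] = (185.0, 160.0, 140.0)
    a_rgb = truth.ellipse_rgb[2]
    rr, cc = draw_disk((truth.center_rgb[1], truth.center_rgb[0]),
                       2.8 * a_rgb, shape=rgb.shape[:2])
    rgb[rr, cc] = (60.0, 45.0, 35.0)

    (u0, v0, wi, hi), Hf = integer_crop_and_homography(truth.bbox_rgb,
                                                       H_session)
    patch = warp(scene.astype(float), ProjectiveTransform(matrix=Hf),
                 output_shape=(hi, wi), order=1, mode="constant", cval=0.0)
    if blur_sigma > 0:
        patch = gaussian(patch, sigma=blur_sigma, channel_axis=-1)
    if downsample > 1:
        small = resize(patch, (max(hi // downsample, 1),
                               max(wi // downsample, 1)),
                       anti_aliasing=True)
        patch = resize(small, (hi, wi), anti_aliasing=False)
    rgb[v0:v0 + hi, u0:u0 + wi] = patch[:, ::-1]   # un-mirror for compositing
    rgb_img = np.clip(rgb, 0, 255).astype(np.uint8)

    return ir_img, rgb_img, scene
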