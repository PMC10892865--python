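"""Corneal-to-scene gaze transfer.

At every instant the system holds two pictures of the same (locally planar)
world: the front-scene image and the mirrored corneal crop.  Scale-invariant
features matched between the two give point correspondences; a homography H
estimated from them (robustly, since corneal matches are noisy and sparse)
transfers the pupil centre — the gaze point in crop coordinates — into the
scene image:

    S * [u', v', 1]^T = H * [u, v, 1]^T,   (u', v') = (H q~ / S)_{1,2}

The default mode pools matches from every calibration pair of a session into
one homography, which is exact when the crop-local reflection geometry is
stable over the session; a per-frame mode is available for scenes where that
assumption fails.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage.color import rgb2gray
from skimage.feature import SIFT, match_descriptors

from .corneal_imaging import CornealImage

__all__ = [
    "FeatureMatchSet",
    "HomographyModel",
    "SceneMappingError",
    "InsufficientMatchesError",
    "PointAtInfinityError",
    "detect_and_match",
    "accumulate_matches",
    "estimate_homography",
    "apply_homography",
    "gaze_to_scene",
]

logger = logging.getLogger(__name__)

MIN_MATCHES = 4
LOW_CONFIDENCE_INLIERS = 10


class SceneMappingError(ValueError):
    pass


class InsufficientMatchesError(SceneMappingError):
    pass


class PointAtInfinityError(SceneMappingError):
    pass


@dataclass(frozen=True)
class FeatureMatchSet:
    """Matched points: ``src`` in corneal-crop coordinates, ``dst`` in the
    scene image, with descriptor distances and a per-match source pair id."""

    src: np.ndarray
    dst: np.ndarray
    distance: np.ndarray
    pair_id: np.ndarray

    def __post_init__(self) -> None:
        src = np.asarray(self.src, dtype=float).reshape(-1, 2)
        dst = np.asarray(self.dst, dtype=float).reshape(-1, 2)
        distance = np.asarray(self.distance, dtype=float).reshape(-1)
        pair_id = np.asarray(self.pair_id, dtype=int).reshape(-1)
        n = src.shape[0]
        if not (dst.shape[0] == distance.shape[0] == pair_id.shape[0] == n):
            raise ValueError("match arrays must have equal length")
        if np.any(distance < 0):
            raise ValueError("descriptor distances must be non-negative")
        for name, arr in (("src", src), ("dst", dst),
                          ("distance", distance), ("pair_id", pair_id)):
            object.__setattr__(self, name, arr)

    def __len__(self) -> int:
        return self.src.shape[0]

    @classmethod
    def empty(cls) -> "FeatureMatchSet":
        return cls(np.empty((0, 2)), np.empty((0, 2)),
                   np.empty(0), np.empty(0, dtype=int))


@dataclass(frozen=True)
class HomographyModel:
    """3x3 corneal-to-scene homography with RANSAC diagnostics."""

    H: np.ndarray
    n_inliers: int
    n_total: int
    inlier_threshold: float
    per_pair_inlier_counts: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        H = np.asarray(self.H, dtype=float).reshape(3, 3)
        if abs(np.linalg.det(H)) < 1e-12:
            raise SceneMappingError("homography is singular")
        object.__setattr__(self, "H", H / H[2, 2])
        if self.n_inliers > self.n_total:
            raise ValueError("n_inliers cannot exceed n_total")

    @property
    def low_confidence(self) -> bool:
        return self.n_inliers < LOW_CONFIDENCE_INLIERS

    def to_json(self, path: str | Path | None = None) -> dict:
        d = {
            "H": self.H.ravel().tolist(),
            "n_inliers": int(self.n_inliers),
            "n_total": int(self.n_total),
            "inlier_threshold": float(self.inlier_threshold),
            "per_pair_inlier_counts": {str(k): int(v) for k, v in
                                       self.per_pair_inlier_counts.items()},
        }
        if path is not None:
            Path(path).write_text(json.dumps(d, indent=2))
        return d

    @classmethod
    def from_json(cls, src: str | Path | dict) -> "HomographyModel":
        if not isinstance(src, dict):
            src = json.loads(Path(src).read_text())
        return cls(H=np.asarray(src["H"], dtype=float).reshape(3, 3),
                   n_inliers=int(src["n_inliers"]),
                   n_total=int(src["n_total"]),
                   inlier_threshold=float(src["inlier_threshold"]),
                   per_pair_inlier_counts={int(k): int(v) for k, v in
                                           src["per_pair_inlier_counts"].items()})


def _to_gray_float(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image)
    if img.ndim == 3:
        img = rgb2gray(img[..., :3])
    img = img.astype(float)
    if img.max() > 1.5:
        img = img / 255.0
    return img


def detect_and_match(corneal: CornealImage, scene: np.ndarray,
                     ratio: float = 0.75, pair_id: int = 0) -> FeatureMatchSet:
    """SIFT features on the mirrored corneal crop and the scene image,
    matched with Lowe's nearest-neighbour ratio test.

    Corneal features outside the inscribed corneal (pupil-region) ellipse are
    discarded before matching.  Returns an empty set (with a warning log) if
    fewer than 4 matches survive — that pair simply contributes nothing.
    """
    crop = _to_gray_float(corneal.pixels)
    if crop.shape[0] < 32 or crop.shape[1] < 32:
        raise SceneMappingError("corneal crop must be at least 32x32")
    scene_g = _to_gray_float(scene)

    sift_a, sift_b = SIFT(), SIFT()
    try:
        sift_a.detect_and_extract(crop)
        sift_b.detect_and_extract(scene_g)
    except RuntimeError:
        logger.warning("pair %d: SIFT found no features", pair_id)
        return FeatureMatchSet.empty()

    kp_a = sift_a.keypoints[:, ::-1].astype(float)   # (row,col) -> (u,v)
    kp_b = sift_b.keypoints[:, ::-1].astype(float)

    # inscribed-ellipse mask: keep only features in the corneal region
    h, w = crop.shape
    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
    inside = (((kp_a[:, 0] - cx) / max(cx, 1e-9)) ** 2 +
              ((kp_a[:, 1] - cy) / max(cy, 1e-9)) ** 2) <= 1.0
    if inside.sum() < MIN_MATCHES:
        logger.warning("pair %d: too few corneal-region features", pair_id)
        return FeatureMatchSet.empty()
    desc_a = sift_a.descriptors[inside]
    kp_a = kp_a[inside]

    matches = match_descriptors(desc_a, sift_b.descriptors,
                                cross_check=True, max_ratio=ratio)
    if matches.shape[0] < MIN_MATCHES:
        logger.warning("pair %d: only %d matches", pair_id, matches.shape[0])
        return FeatureMatchSet.empty()
    d = np.linalg.norm(desc_a[matches[:, 0]].astype(float) -
                       sift_b.descriptors[matches[:, 1]].astype(float), axis=1)
    return FeatureMatchSet(src=kp_a[matches[:, 0]], dst=kp_b[matches[:, 1]],
                           distance=d,
                           pair_id=np.full(matches.shape[0], pair_id, dtype=int))


def accumulate_matches(pairs: list[FeatureMatchSet]) -> FeatureMatchSet:
    """Pool matches across calibration pairs, keeping per-match provenance."""
    nonempty = [p for p in pairs if len(p) > 0]
    if not nonempty:
        raise InsufficientMatchesError("all match sets are empty")
    return FeatureMatchSet(
        src=np.concatenate([p.src for p in nonempty]),
        dst=np.concatenate([p.dst for p in nonempty]),
        distance=np.concatenate([p.distance for p in nonempty]),
        pair_id=np.concatenate([p.pair_id for p in nonempty]),
    )


def _normalization(pts: np.ndarray) -> np.ndarray:
    """Hartley similarity: centroid at origin, mean distance sqrt(2)."""
    centroid = pts.mean(axis=0)
    mean_dist = np.mean(np.linalg.norm(pts - centroid, axis=1))
    s = np.sqrt(2.0) / max(mean_dist, 1e-12)
    return np.array([[s, 0, -s * centroid[0]],
                     [0, s, -s * centroid[1]],
                     [0, 0, 1.0]])


def _dlt(src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    """Direct linear transform with Hartley normalization; >= 4 points."""
    Ts, Td = _normalization(src), _normalization(dst)
    sh = np.column_stack([src, np.ones(len(src))]) @ Ts.T
    dh = np.column_stack([dst, np.ones(len(dst))]) @ Td.T
    n = len(src)
    A = np.zeros((2 * n, 9))
    A[0::2, 0:3] = sh
    A[0::2, 6:9] = -dh[:, 0:1] * sh
    A[1::2, 3:6] = sh
    A[1::2, 6:9] = -dh[:, 1:2] * sh
    _, _, Vt = np.linalg.svd(A)
    Hn = Vt[-1].reshape(3, 3)
    H = np.linalg.inv(Td) @ Hn @ Ts
    if abs(H[2, 2]) < 1e-12:
        raise SceneMappingError("degenerate homography")
    return H / H[2, 2]


def _transfer_errors(H: np.ndarray, src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    sh = np.column_stack([src, np.ones(len(src))])
    proj = sh @ H.T
    with np.errstate(divide="ignore", invalid="ignore"):
        uv = proj[:, :2] / proj[:, 2:3]
    err = np.linalg.norm(uv - dst, axis=1)
    err[~np.isfinite(err)] = np.inf
    return err


def estimate_homography(matches: FeatureMatchSet,
                        inlier_threshold: float = 3.0,
                        max_iters: int = 2000,
                        confidence: float = 0.99,
                        seed: int | np.random.Generator | None = 0,
                        ) -> HomographyModel:
    """RANSAC homography: 4-point DLT hypotheses, reprojection-error
    consensus, then a least-squares DLT refit on all inliers.

    The iteration count adapts downward as the best inlier ratio grows
    (standard 99%-confidence early exit).
    """
    n = len(matches)
    if n < MIN_MATCHES:
        raise InsufficientMatchesError(f"need >= 4 matches, got {n}")
    rng = np.random.default_rng(seed)
    src, dst = matches.src, matches.dst

    best_inliers = np.zeros(n, dtype=bool)
    best_count = 0
    trials_needed = max_iters
    i = 0
    while i < min(max_iters, trials_needed):
        i += 1
        idx = rng.choice(n, 4, replace=False)
        try:
            H = _dlt(src[idx], dst[idx])
        except (SceneMappingError, np.linalg.LinAlgError):
            continue
        inl = _transfer_errors(H, src, dst) < inlier_threshold
        cnt = int(inl.sum())
        if cnt > best_count:
            best_count, best_inliers = cnt, inl
            w = cnt / n
            if w > 0:
                denom = np.log1p(-min(w ** 4, 1 - 1e-12))
                trials_needed = int(np.ceil(np.log(1 - confidence) / denom))
    if best_count < MIN_MATCHES:
        raise InsufficientMatchesError("RANSAC found no 4-point consensus")

    H = _dlt(src[best_inliers], dst[best_inliers])
    # one re-classification after refit tightens the consensus set
    inl = _transfer_errors(H, src, dst) < inlier_threshold
    if inl.sum() >= MIN_MATCHES:
        H = _dlt(src[inl], dst[inl])
        best_inliers = inl

    ids, counts = np.unique(matches.pair_id[best_inliers], return_counts=True)
    model = HomographyModel(H=H, n_inliers=int(best_inliers.sum()), n_total=n,
                            inlier_threshold=inlier_threshold,
                            per_pair_inlier_counts=dict(zip(ids.tolist(),
                                                            counts.tolist())))
    if model.low_confidence:
        logger.warning("homography supported by only %d inliers",
                       model.n_inliers)
    return model


def apply_homography(model: HomographyModel | np.ndarray,
                     q: np.ndarray) -> np.ndarray:
    """Transfer pixel(s) through H, including the division by the projective
    scale S; raises :class:`PointAtInfinityError` when |S| vanishes."""
    H = model.H if isinstance(model, HomographyModel) else np.asarray(model, float)
    q = np.asarray(q, dtype=float)
    single = q.ndim == 1
    pts = np.atleast_2d(q)
    ph = np.column_stack([pts, np.ones(len(pts))]) @ H.T
    S = ph[:, 2]
    if np.any(np.abs(S) < 1e-12):
        raise PointAtInfinityError("point maps to the line at infinity")
    uv = ph[:, :2] / S[:, None]
    return uv[0] if single else uv


def gaze_to_scene(corneal: CornealImage, model: HomographyModel,
                  scene_size: tuple[int, int] | None = None,
                  ) -> tuple[np.ndarray, bool]:
    """Transfer the crop-local gaze point into the scene image.

    Returns ``(point, clipped)``; ``clipped`` is True when the point lands
    outside the scene frame (a flag, not an error).
    """
    p = apply_homography(model, np.asarray(corneal.gaze_point, dtype=float))
    clipped = False
    if scene_size is not None:
        W, H = scene_size
        clipped = not (0 <= p[0] <= W - 1 and 0 <= p[1] <= H - 1)
    return p, clipped
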