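# Methods

## Geometry and conventions

Pixel coordinates are 0-based, x right, y down, sub-pixel valued; cameras
look down their own +z axis. The IR eye camera frame is the world frame for
all eye-side geometry; the RGB eye camera's pose is the rigid transform
`rgb_from_ir` (p′ = R·p + t, translation in mm). Intrinsics are plain
pinhole; an optional two-coefficient radial distortion model is accepted in
the camera files (and inverted by fixed-point iteration on backprojection)
because real eye cameras are short-focus, but all synthetic work uses zero
distortion. Stereo extrinsics and intrinsics are *inputs* — the offline
chessboard calibration that produces them is out of scope.

## Eyeball model

The eye is modelled as a sphere of fixed radius 12.0 mm, the anatomical
average; it is deliberately not re-estimated per user, which stabilises the
fit from the small spherical cap the pupil actually covers. Corresponding
pupil-boundary pixels from timestamp-paired IR/RGB frames are triangulated
by the midpoint of the common perpendicular; the segment length ("gap") is
a correspondence-quality diagnostic, and pairs with gap ≥ 2 mm are dropped
before fitting (at ≤ 1 px noise, genuine pairs have gaps well under 0.1 mm,
so the cut only removes mismatches). The centre minimises
Σ(‖pᵢ − c‖ − 12)² by Gauss–Newton with the analytic Jacobian
−(pᵢ−c)/‖pᵢ−c‖, initialised at (mean of points) + 12·(unit mean viewing
direction) — the cameras see the near surface, so the centre lies one
radius deeper along the mean line of sight, which also keeps the iteration
off the mirror solution on the camera side. Convergence is a step norm
below 1e-12 within 100 iterations; a Nelder–Mead fallback covers degenerate
caps. The reported `rms_residual` is recomputed from the final centre.

Ray–sphere intersection always takes the root nearer the camera: a visible
pupil lies on the camera-facing hemisphere, so the far root is anatomically
impossible. Only the optical axis (centre → pupil centre) is produced; the
per-person kappa offset to the visual axis is not modelled.

## Pupil detection

A classical detector stands behind the same contract a learned detector
would satisfy (centre, bbox, ellipse, score), so a network can be swapped
in without touching downstream stages. Segmentation is Otsu's threshold
restricted to the darkest 20% of the histogram (separating the pupil from
iris/shadow tones rather than from the bright sclera), followed by
connected components filtered to a plausible area fraction
([0.001, 0.05] of the frame), hole filling, and a sub-pixel contour. The
ellipse fit is the numerically stable direct least-squares conic fit
(Halir–Flusser partitioning of the ellipse-specific scatter problem) —
chosen because frontal pupils are near-circular, which is precisely where
naive conic solvers lose the orientation angle — with Sampson
(gradient-normalised algebraic) distances as residuals. The score in
[0, 1] multiplies a pupil/surround contrast separation term (which decays
with pixel noise) by the boundary-fit quality 1/(1+rms).

One convention worth noting: the detector reports the centre of the
*projected conic*; under perspective this differs by a few pixels from the
projection of the 3D pupil centre. The abstract synthetic observation path
defines its detections around the projected 3D centre so observations and
ground truth share one convention; the rendered-image path tests the
detector against the conic centre. Eyelids, glints and dark irises are not
handled. Detection is never attempted on RGB eye images — reflections make
the boundary unreliable there, which is the reason the 3D mapping exists.

## Corneal imaging and gaze transfer

The IR bbox corners travel through the eyeball mapping; their axis-aligned
hull, enlarged 10% per side (so features just outside the pupil boundary
survive for matching), clipped to the frame, is the corneal crop. The crop
is mirrored horizontally — a convex reflector mirrors a roughly frontal
scene left-right — and the mirror is applied *before* feature extraction,
so matching, the homography and the gaze point all live in one flipped,
crop-local frame. A vertical flip is a one-line change if a mount ever
requires it.

Homography estimation is RANSAC over 4-point DLT hypotheses with Hartley
normalisation, a 3 px reprojection inlier threshold, at most 2000
iterations with the standard 99%-confidence adaptive early exit, a
least-squares DLT refit on the consensus set, and one re-classification
after the refit. Fewer than 10 inliers flags the model low-confidence.
SIFT matching uses Lowe's 0.75 ratio test with cross-checking, and corneal
features outside the ellipse inscribed in the crop are discarded. The
default is one homography per session pooled over all calibration pairs;
this is exact only when the crop-local reflection geometry is stable over
the session (fixed scene plane, stable headset), so a per-frame mode
(`homography_mode: per_frame`) is available for scenes where that fails.

## Evaluation

Angular error backprojects both scene pixels with the front camera's
intrinsics and takes the arccos of the clamped dot product, in degrees.
Records group by participant and session; per participant the mean, sample
(n−1) standard deviation (counts per participant are small) and median are
reported — the median deliberately suppresses outlier triads. Two overall
summaries are computed, the unweighted mean of per-participant means and of
per-participant medians, because both aggregations are in common use and
they answer slightly different questions; both are also given rounded to
2 decimals. A bundled reference table of per-participant statistics from a
published 12-participant indoor/outdoor evaluation regression-tests this
arithmetic.

## Synthetic data: what it emulates and what it does not

The generator reproduces the study conditions end to end with full ground
truth. Defaults: image sizes 800×600 / 1280×960 / 1280×960; eye-camera
baseline 5–15 mm with both cameras aimed at the eye; eyeball centre 30–45 mm
deep (validity range 25–60 mm); pupil radius 2 mm (anatomically typical);
gaze directions in an 18° cone about the line to the cameras; 32 boundary
points per frame; 100 eye-model frames; 220 pooled corneal/scene
calibration pairs of 30 matches each; 500 evaluation events; 1 px Gaussian
pixel noise on detections, 1 px feature-match noise, 20% match outliers.
Eye-camera focal lengths (IR 650–750 px, RGB 1000–1200 px) frame the whole
~25 mm eye region at the pupil's working depth, so the pupil stays in view
across the gaze cone. Streams are timestamped at 20 fps with jitter and
paired at 1 fps by nearest timestamp within each one-second window.

The world is a textured plane, so the corneal-to-scene mapping is exactly a
homography and scene-gaze ground truth is well defined. That session
homography is held constant in pupil-centred (crop-local, mirrored)
coordinates — the regime in which pooling all calibration pairs into one
homography is geometrically exact; its magnification follows the
convex-mirror model (focal length = half the 7.8 mm corneal curvature
radius), giving roughly 4–6 scene px per crop px. Per-frame true
homographies for rendered triads differ from the session one only by the
integer-crop translation. A consequence of holding the mapping fixed is
that true scene gaze points cluster tightly across events; per-event
angular error remains fully informative about pipeline noise, but the
synthetic sessions do not probe gaze-dependent drift of the reflection
geometry, scene depth variation, or headset slippage. Rendered triads are
schematic (uniform background, flat iris disk, no glints or eyelids):
sufficient to exercise the detector and the matching path, not a
photometric eye model.

Zero-noise sessions run through the entire pipeline with error below
numerical tolerance (< 0.05°; in practice ~1e-12 px), so all error in noisy
runs is attributable to the injected noise. Passing synthetic tests
therefore demonstrates the correctness of the geometry and estimators under
the stated noise model — not performance on real eyes, where detector bias,
unmodelled reflection curvature and slippage dominate.

## Problem sizes and numerical choices

The acceptance script runs five study-scale sessions (100 + 220 + 500
events each) and averages the mean angular error over seeds; this is the
scale the pooled-homography design targets and completes in about a minute.
The test suite uses reduced sessions (tens of frames) for pipeline-level
checks and dedicated small fixtures for unit oracles. Determinism: every
random draw flows from explicit seeds (scenario seeds, RANSAC seed);
repeated runs are byte-identical. Degenerate inputs fail loudly with typed
errors (parallel rays, rays missing the sphere, points behind the camera,
matches at the line at infinity, empty crops), and the batch driver converts
per-frame failures into `valid=false` gaze records with machine-parsable
log reasons rather than aborting a session.
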