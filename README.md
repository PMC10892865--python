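# corneagaze

Calibration-free mobile eye tracking via **corneal imaging**, for researchers
who need a head-mounted gaze estimate without asking the wearer to fixate
calibration targets. The wearer simply puts the headset on; the system
calibrates itself from natural viewing.

The headset carries three cameras: an IR eye camera (800×600) that sees the
pupil crisply under any lighting, an RGB eye camera (1280×960) in which the
tear film mirrors a small copy of the world around the pupil (the *corneal
image*), and a front-scene RGB camera (1280×960) that photographs the world
at high resolution. `corneagaze` implements the full pipeline connecting
them, plus a synthetic-data generator with complete ground truth, so every
stage runs and is tested without hardware.

## Method

1. **Per-user eyeball model.** The eyeball is a sphere of fixed anatomical
   radius r = 12 mm. Pupil-boundary points detected simultaneously in the
   two eye cameras are triangulated (midpoint of the common perpendicular of
   the two viewing rays) into 3D surface points pᵢ, and the centre c solves

   &nbsp;&nbsp;&nbsp;&nbsp;min_c Σᵢ (‖pᵢ − c‖ − r)²

   by Gauss–Newton with an analytic Jacobian.

2. **IR→RGB point mapping.** An IR pixel backprojects to a ray, the ray
   meets the sphere at the camera-facing root of ‖o + t·d − c‖² = r², and
   that 3D point reprojects into the RGB eye camera — a true point-to-point
   mapping between the two eye cameras. The optical axis (gaze ray) runs
   from c through the pupil-centre surface point.

3. **Corneal image.** The detected pupil bounding box is mapped into the RGB
   image, enlarged by a 10% margin, cropped, and mirrored horizontally
   (the cornea is a convex mirror), carrying the mapped pupil centre along
   as the crop-local gaze point.

4. **Gaze transfer.** SIFT features matched between corneal crops and scene
   images, pooled over a session's calibration pairs, feed a RANSAC-estimated
   homography H (4-point DLT hypotheses, least-squares refit on inliers).
   The gaze point transfers by S·[u′, v′, 1]ᵀ = H·[u, v, 1]ᵀ followed by
   division by the projective scale S.

5. **Evaluation.** The error between estimated and reference gaze points is
   the angle between their backprojected rays in the front camera, in
   degrees; per participant the mean, sample SD and median are reported, and
   overall summaries are unweighted means across participants.

## Worked example

Simulate a session (80 stereo eye frames for the eyeball model, 120
corneal/scene calibration pairs, 60 evaluation gaze events, 1 px pixel
noise, 20% match outliers), auto-calibrate, track, and evaluate:

```
$ printf 'n_model_frames: 80\nn_match_pairs: 120\nn_eval_events: 60\n' > scenario.yaml
$ corneagaze simulate --seed 42 --out session --config scenario.yaml
wrote session with 180 events to session
$ corneagaze autocalibrate --session session --out models
eye centre (mm): [-1.638, 0.32, 30.96], rms residual 0.0597 mm, 2560 support points
homography: 2837/3600 inliers
$ corneagaze track --session session --models models --out gaze.csv
wrote 60 gaze records (60 valid) to gaze.csv
$ corneagaze evaluate --gaze gaze.csv --rig session/rig.json
session participant  n     mean      std  median
indoors   synthetic 60 0.473557 0.221487 0.45071
```

Reading the numbers: the sphere fit used 2560 boundary correspondences
(80 frames × 32 points) and sits 0.06 mm rms off the triangulated surface
points; the pooled homography kept 2837 of 3600 matches as inliers (the
simulated outlier rate is 20%); and the 60 gaze events land a mean of 0.47°
(median 0.45°) from ground truth — of the order of the accuracy a physical
corneal-imaging tracker reaches, with the remaining error traceable to the
injected pixel noise, since the same pipeline at zero noise is exact to
numerical precision (< 0.05°, see the test suite).

`corneagaze simulate --render` additionally writes PNG triads in which the
corneal patch is a projectively warped, mirrored, blurred copy of the scene
image, usable with the image-based entry points (`detect_pupil_ir`,
`extract_corneal_image`, `detect_and_match`).

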