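import numpy as np
import pytest

from corneagaze.camera_geometry import CameraIntrinsics, Ray, RigidTransform
from corneagaze.eye_model import (EYEBALL_RADIUS_MM, ConvergenceError,
                                  CorrespondenceSet, EyeballModel,
                                  EyeModelError, InsufficientDataError,
                                  NoIntersectionError, build_eye_model,
                                  gaze_ray, map_ir_to_rgb, ray_sphere_intersect)
from corneagaze import synthetic


def fit_from_scenario(seed, pixel_noise, n_pairs, eye_center=None):
    sc = synthetic.make_scenario(
        seed, pixel_noise=pixel_noise, n_model_frames=10, n_match_pairs=10,
        n_eval_events=0, n_matches_per_pair=4,
        **({"eye_center": eye_center} if eye_center is not None else {}))
    obs, truth = synthetic.simulate_session(sc)
    corr = synthetic.correspondence_set(obs, max_pairs=n_pairs)
    model = build_eye_model(corr, sc.rig.ir, sc.rig.rgb, sc.rig.rgb_from_ir)
    return model, truth


class TestSphereFit:
    def test_noiseless_recovery(self):
        model, truth = fit_from_scenario(
            2, 0.0, 50, eye_center=np.array([2.0, -1.0, 35.0]))
        assert np.linalg.norm(model.center - truth.eye_center) < 1e-3
        assert model.rms_residual < 1e-6
        assert model.n_support_points == 50

    def test_noisy_recovery_half_pixel(self):
        errs = []
        for seed in range(5):
            model, truth = fit_from_scenario(100 + seed, 0.5, 200)
            errs.append(np.linalg.norm(model.center - truth.eye_center))
        assert np.median(errs) < 0.5

    def test_recovery_improves_with_less_noise(self):
        """Median centre error decreases through noise levels 2, 1, 0.5, 0 px."""
        medians = []
        for sigma in (2.0, 1.0, 0.5, 0.0):
            errs = []
            for s in range(7):
                model, truth = fit_from_scenario(200 + s, sigma, 200)
                errs.append(np.linalg.norm(model.center - truth.eye_center))
            medians.append(np.median(errs))
        assert medians[0] > medians[1] > medians[2] > medians[3]

    def test_too_few_pairs_rejected(self):
        corr = CorrespondenceSet(ir=np.zeros((3, 2)) + [400, 300],
                                 rgb=np.zeros((3, 2)) + [640, 480])
        K = CameraIntrinsics(fx=700, fy=700, cx=400, cy=300, width=800, height=600)
        with pytest.raises(InsufficientDataError):
            build_eye_model(corr, K, K, RigidTransform.identity())

    def test_reported_residual_is_consistent(self):
        model, truth = fit_from_scenario(3, 1.0, 300)
        # rms recomputed from the fitted sphere must match the report
        sc = synthetic.make_scenario(3, pixel_noise=1.0, n_model_frames=10,
                                     n_match_pairs=10, n_eval_events=0,
                                     n_matches_per_pair=4)
        obs, _ = synthetic.simulate_session(sc)
        corr = synthetic.correspondence_set(obs, max_pairs=300)
        from corneagaze.camera_geometry import triangulate_pixel_pairs
        pts, gaps = triangulate_pixel_pairs(corr.ir, corr.rgb, sc.rig.ir,
                                            sc.rig.rgb, sc.rig.rgb_from_ir)
        pts = pts[gaps < 2.0]
        rms = np.sqrt(np.mean(
            (np.linalg.norm(pts - model.center, axis=1) - 12.0) ** 2))
        assert np.isclose(rms, model.rms_residual, atol=1e-9)

    def test_model_json_roundtrip(self, tmp_path):
        model, _ = fit_from_scenario(4, 0.5, 100)
        path = tmp_path / "eye.json"
        model.to_json(path)
        back = EyeballModel.from_json(path)
        assert np.allclose(back.center, model.center)
        assert back.n_support_points == model.n_support_points

    def test_radius_is_fixed(self):
        with pytest.raises(ValueError):
            EyeballModel(center=np.zeros(3), n_support_points=10,
                         rms_residual=0.0, radius=11.0)


SPHERE = EyeballModel(center=np.array([0.0, 0.0, 35.0]),
                      n_support_points=4, rms_residual=0.0)


class TestRaySphere:
    def test_on_axis_near_root(self):
        p = ray_sphere_intersect(Ray(np.zeros(3), np.array([0, 0, 1.0])), SPHERE)
        assert np.allclose(p, [0, 0, 23.0])

    def test_tangent_ray_single_root(self):
        p = ray_sphere_intersect(
            Ray(np.array([12.0, 0, 0]), np.array([0, 0, 1.0])), SPHERE)
        assert np.allclose(p, [12.0, 0, 35.0], atol=1e-6)

    def test_miss_raises(self):
        with pytest.raises(NoIntersectionError):
            ray_sphere_intersect(
                Ray(np.array([30.0, 0, 0]), np.array([0, 0, 1.0])), SPHERE)

    def test_origin_inside_rejected(self):
        with pytest.raises(EyeModelError):
            ray_sphere_intersect(
                Ray(np.array([0.0, 0, 30.0]), np.array([0, 0, 1.0])), SPHERE)

    def test_matches_bisection_oracle(self):
        """Quadratic root agrees with bisection on ||o+td-c||-r to 1e-9."""
        rng = np.random.default_rng(8)
        for _ in range(25):
            d = rng.normal(size=3)
            d[2] = abs(d[2]) + 1.0
            ray = Ray(np.zeros(3), d)
            # only rays that actually hit
            try:
                p = ray_sphere_intersect(ray, SPHERE)
            except NoIntersectionError:
                continue
            assert abs(np.linalg.norm(p - SPHERE.center) - 12.0) < 1e-9

            def f(t):
                return np.linalg.norm(ray.point_at(t) - SPHERE.center) - 12.0

            lo, hi = 0.0, 35.0
            assert f(lo) > 0 > f(hi)
            for _ in range(80):
                mid = 0.5 * (lo + hi)
                if f(mid) > 0:
                    lo = mid
                else:
                    hi = mid
            t_ref = 0.5 * (lo + hi)
            assert np.linalg.norm(p - ray.point_at(t_ref)) < 1e-9


class TestMappingAndGaze:
    def test_identity_rig_maps_to_itself(self):
        K = CameraIntrinsics(fx=700, fy=700, cx=400, cy=300, width=800, height=600)
        q = np.array([380.0, 310.0])
        out = map_ir_to_rgb(q, SPHERE, K, K, RigidTransform.identity())
        assert np.allclose(out, q, atol=1e-9)

    def test_maps_true_center_across_cameras(self, noiseless_session):
        obs, truth = noiseless_session
        model = EyeballModel(center=truth.eye_center, n_support_points=4,
                             rms_residual=0.0)
        for t in truth.events[:10]:
            out = map_ir_to_rgb(t.center_ir, model, obs.rig.ir, obs.rig.rgb,
                                obs.rig.rgb_from_ir)
            assert np.linalg.norm(out - t.center_rgb) < 0.1

    def test_ray_missing_sphere_raises(self, rig):
        model = EyeballModel(center=np.array([0.0, 0, 35.0]),
                             n_support_points=4, rms_residual=0.0)
        with pytest.raises(NoIntersectionError):
            map_ir_to_rgb(np.array([0.0, 0.0]), model, rig.ir, rig.rgb,
                          rig.rgb_from_ir)

    def test_gaze_at_camera_facing_pole(self):
        K = CameraIntrinsics(fx=700, fy=700, cx=400, cy=300, width=800, height=600)
        ray = gaze_ray(SPHERE, np.array([400.0, 300.0]), K)
        assert np.allclose(ray.origin, SPHERE.center)
        assert np.allclose(ray.direction, [0, 0, -1.0])

    def test_recovers_known_gaze_direction(self, noiseless_session):
        obs, truth = noiseless_session
        model = EyeballModel(center=truth.eye_center, n_support_points=4,
                             rms_residual=0.0)
        for t in truth.events[:10]:
            ray = gaze_ray(model, t.center_ir, obs.rig.ir)
            cosang = np.clip(np.dot(ray.direction, t.gaze_dir), -1, 1)
            assert np.degrees(np.arccos(cosang)) < 0.2
            # the ray passes through the surface point at one radius
            surf = ray.origin + EYEBALL_RADIUS_MM * ray.direction
            assert np.linalg.norm(surf - t.pupil_center_3d) < 1e-6
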