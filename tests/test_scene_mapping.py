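import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from skimage.measure import ransac as sk_ransac
from skimage.transform import ProjectiveTransform

from corneagaze import synthetic
from corneagaze.corneal_imaging import CornealImage, extract_corneal_image
from corneagaze.scene_mapping import (FeatureMatchSet, HomographyModel,
                                      InsufficientMatchesError,
                                      PointAtInfinityError,
                                      accumulate_matches, apply_homography,
                                      detect_and_match, estimate_homography,
                                      gaze_to_scene)


def random_homography(rng, scale=4.0):
    theta = rng.uniform(-0.3, 0.3)
    H = np.array([[scale * np.cos(theta), -scale * np.sin(theta), rng.uniform(100, 500)],
                  [scale * np.sin(theta), scale * np.cos(theta), rng.uniform(100, 500)],
                  [rng.uniform(-1e-4, 1e-4), rng.uniform(-1e-4, 1e-4), 1.0]])
    return H


def matches_from_h(rng, H, n=200, noise=0.0, outlier_frac=0.0, extent=300.0):
    src = rng.uniform(0, extent, (n, 2))
    dst = apply_homography(H, src) + rng.normal(0, noise, (n, 2))
    n_out = int(round(outlier_frac * n))
    idx = rng.choice(n, n_out, replace=False) if n_out else np.array([], int)
    if n_out:
        dst[idx] = rng.uniform(0, 1000, (n_out, 2))
    inlier_mask = np.ones(n, bool)
    inlier_mask[idx] = False
    ms = FeatureMatchSet(src=src, dst=dst, distance=np.zeros(n),
                         pair_id=np.zeros(n, int))
    return ms, inlier_mask


class TestApplyHomography:
    def test_identity(self):
        assert np.allclose(apply_homography(np.eye(3), np.array([3.0, 4.0])),
                           (3, 4))

    def test_pure_scaling(self):
        H = np.diag([2.0, 2.0, 1.0])
        assert np.allclose(apply_homography(H, np.array([3.0, 4.0])), (6, 8))

    def test_projective_scale_division(self):
        H = np.diag([1.0, 1.0, 2.0])
        assert np.allclose(apply_homography(H, np.array([10.0, 20.0])), (5, 10))

    def test_point_at_infinity_raises(self):
        H = np.array([[1, 0, 0], [0, 1, 0], [0, -1, 1.0]])
        with pytest.raises(PointAtInfinityError):
            apply_homography(H, np.array([5.0, 1.0]))

    @given(u=st.floats(0, 300), v=st.floats(0, 300))
    def test_inverse_composition_is_identity(self, u, v):
        H = random_homography(np.random.default_rng(0))
        q = np.array([u, v])
        back = apply_homography(np.linalg.inv(H), apply_homography(H, q))
        assert np.allclose(back, q, atol=1e-9)


class TestEstimateHomography:
    def test_exact_recovery_zero_noise(self):
        rng = np.random.default_rng(1)
        H = random_homography(rng)
        ms, _ = matches_from_h(rng, H, n=60)
        model = estimate_homography(ms, seed=0)
        test = rng.uniform(0, 300, (100, 2))
        err = np.linalg.norm(apply_homography(model, test)
                             - apply_homography(H, test), axis=1)
        assert err.max() < 1e-6

    def test_too_few_matches(self):
        ms, _ = matches_from_h(np.random.default_rng(0), np.eye(3), n=3)
        with pytest.raises(InsufficientMatchesError):
            estimate_homography(ms)

    def test_robust_to_outliers(self):
        rng = np.random.default_rng(2)
        H = random_homography(rng)
        ms, inl = matches_from_h(rng, H, n=200, noise=1.0, outlier_frac=0.3)
        model = estimate_homography(ms, seed=0)
        test = rng.uniform(0, 300, (100, 2))
        err = np.linalg.norm(apply_homography(model, test)
                             - apply_homography(H, test), axis=1)
        assert err.max() < 2.0
        assert model.n_inliers >= 0.8 * inl.sum()

    def test_inliers_nonincreasing_with_tighter_threshold(self):
        rng = np.random.default_rng(3)
        H = random_homography(rng)
        ms, _ = matches_from_h(rng, H, n=150, noise=1.5, outlier_frac=0.2)
        counts = [estimate_homography(ms, inlier_threshold=thr, seed=0).n_inliers
                  for thr in (5.0, 3.0, 1.5, 0.8)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_invariant_to_similarity_renormalization(self):
        """Estimating in rescaled/retranslated coordinate frames and mapping
        the result back gives the same transfer (internal normalisation)."""
        rng = np.random.default_rng(4)
        H = random_homography(rng)
        ms, _ = matches_from_h(rng, H, n=80)
        S1 = np.array([[0.01, 0, -3], [0, 0.01, 2], [0, 0, 1.0]])
        S2 = np.array([[50.0, 0, 1000], [0, 50.0, -500], [0, 0, 1.0]])
        ms2 = FeatureMatchSet(src=apply_homography(S1, ms.src),
                              dst=apply_homography(S2, ms.dst),
                              distance=ms.distance, pair_id=ms.pair_id)
        m1 = estimate_homography(ms, seed=0)
        m2 = estimate_homography(ms2, seed=0)
        H2_back = np.linalg.inv(S2) @ m2.H @ S1
        test = rng.uniform(0, 300, (50, 2))
        err = np.linalg.norm(apply_homography(m1, test)
                             - apply_homography(H2_back / H2_back[2, 2], test),
                             axis=1)
        assert err.max() < 1e-6

    def test_agrees_with_skimage_ransac(self):
        """Dual-route check: same data through skimage's independent RANSAC
        + projective estimator gives the same mapping."""
        rng = np.random.default_rng(5)
        H = random_homography(rng)
        ms, _ = matches_from_h(rng, H, n=200, noise=0.5, outlier_frac=0.2)
        model = estimate_homography(ms, seed=0)
        sk_model, _ = sk_ransac((ms.src, ms.dst), ProjectiveTransform,
                                min_samples=4, residual_threshold=3.0,
                                max_trials=2000, rng=0)
        test = rng.uniform(50, 250, (50, 2))
        err = np.linalg.norm(apply_homography(model, test) - sk_model(test),
                             axis=1)
        assert np.median(err) < 1.0

    def test_json_roundtrip(self, tmp_path):
        rng = np.random.default_rng(6)
        ms, _ = matches_from_h(rng, random_homography(rng), n=50)
        model = estimate_homography(ms, seed=0)
        model.to_json(tmp_path / "h.json")
        back = HomographyModel.from_json(tmp_path / "h.json")
        assert np.allclose(back.H, model.H)
        assert back.n_inliers == model.n_inliers
        assert back.per_pair_inlier_counts == model.per_pair_inlier_counts


class TestAccumulate:
    def two_sets(self):
        rng = np.random.default_rng(7)
        a, _ = matches_from_h(rng, np.eye(3), n=10)
        b = FeatureMatchSet(src=rng.uniform(0, 10, (5, 2)),
                            dst=rng.uniform(0, 10, (5, 2)),
                            distance=np.ones(5), pair_id=np.full(5, 3))
        return a, b

    def test_size_is_sum(self):
        a, b = self.two_sets()
        assert len(accumulate_matches([a, b])) == len(a) + len(b)

    def test_pair_ids_preserved(self):
        a, b = self.two_sets()
        pooled = accumulate_matches([a, b])
        assert set(pooled.pair_id) == {0, 3}
        assert (pooled.pair_id == 3).sum() == 5

    def test_all_empty_raises(self):
        with pytest.raises(InsufficientMatchesError):
            accumulate_matches([FeatureMatchSet.empty()])

    def test_pooled_inlier_rate_vs_per_pair(self, small_session):
        """Pooling all calibration pairs yields an inlier rate at least the
        per-pair median rate."""
        obs, _ = small_session
        sets = synthetic.match_sets(obs)
        pooled_model = estimate_homography(accumulate_matches(sets), seed=0)
        pooled_rate = pooled_model.n_inliers / pooled_model.n_total
        rates = []
        for ms in sets[:40]:
            m = estimate_homography(ms, seed=0)
            rates.append(m.n_inliers / m.n_total)
        assert pooled_rate >= np.median(rates) - 0.05


class TestFeatureMatching:
    def test_self_match_is_translation_consistent(self):
        scene = synthetic.make_texture(21, shape=(480, 640))
        off_u, off_v = 200, 140
        crop = scene[off_v:off_v + 160, off_u:off_u + 160]
        corneal = CornealImage(pixels=crop, bbox_rgb=(0, 0, 160, 160),
                               gaze_point=(80.0, 80.0))
        ms = detect_and_match(corneal, scene)
        assert len(ms) >= 10
        d = ms.dst - ms.src
        good = (np.abs(d[:, 0] - off_u) < 2.0) & (np.abs(d[:, 1] - off_v) < 2.0)
        assert good.mean() >= 0.9

    def test_featureless_crop_gives_empty_set(self):
        corneal = CornealImage(pixels=np.full((64, 64), 128, np.uint8),
                               bbox_rgb=(0, 0, 64, 64), gaze_point=(32.0, 32.0))
        scene = synthetic.make_texture(22, shape=(480, 640))
        assert len(detect_and_match(corneal, scene)) == 0

    def test_rendered_corneal_patch_matches_scene(self, noiseless_session):
        """SIFT matches between a rendered corneal patch and the scene:
        ratio-test survivors localise the true correspondence to sub-pixel
        accuracy on the corneal crop (the measurement domain; the scene-space
        error is that times the crop-to-scene magnification, about 6x here)."""
        obs, truth = noiseless_session
        scene = synthetic.make_texture(11)
        errors, mags = [], []
        for t in truth.events[:3]:
            _, rgb, scene_img = synthetic.render_triad(
                t, obs.rig, scene, truth.H_session, blur_sigma=0.8,
                downsample=1)
            ci = extract_corneal_image(rgb, t.bbox_rgb, t.center_rgb)
            (_, _, _, _), Hf = synthetic.integer_crop_and_homography(
                t.bbox_rgb, truth.H_session)
            ms = detect_and_match(ci, scene_img)
            assert len(ms) >= 8
            errors.append(np.linalg.norm(
                apply_homography(Hf, ms.src) - ms.dst, axis=1))
            mags.append(np.sqrt(abs(np.linalg.det(Hf[:2, :2]))))
        err = np.concatenate(errors)
        mag = np.mean(mags)
        # a survivor is a true correspondence unless it is a gross mismatch
        true_corr = err[err < 20.0]
        assert len(true_corr) > 0.8 * len(err)
        assert np.median(true_corr) / mag < 0.75


class TestGazeToScene:
    def make_model(self, H):
        return HomographyModel(H=H, n_inliers=20, n_total=20,
                               inlier_threshold=3.0)

    def corneal(self, gaze=(50.0, 60.0)):
        return CornealImage(pixels=np.zeros((100, 100), np.uint8),
                            bbox_rgb=(0, 0, 100, 100), gaze_point=gaze)

    def test_identity_homography(self):
        p, clipped = gaze_to_scene(self.corneal(), self.make_model(np.eye(3)),
                                   scene_size=(1280, 960))
        assert np.allclose(p, (50, 60)) and not clipped

    def test_out_of_frame_sets_clipped_flag(self):
        H = np.array([[1, 0, 5000.0], [0, 1, 0], [0, 0, 1]])
        p, clipped = gaze_to_scene(self.corneal(), self.make_model(H),
                                   scene_size=(1280, 960))
        assert clipped and p[0] > 1280

    def test_synthetic_session_transfer(self, noiseless_session):
        """With noiseless features the transferred gaze point lands within
        5 px of the true scene gaze for every event."""
        obs, truth = noiseless_session
        sets = synthetic.match_sets(obs)
        model = estimate_homography(accumulate_matches(sets), seed=0)
        for t in truth.events:
            p = apply_homography(model, np.asarray(t.gaze_point_crop))
            assert np.linalg.norm(p - t.scene_gaze) < 5.0
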