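"""Feature detection, KLT stepping, robust ROI propagation and full tracking runs."""

from dataclasses import replace

import numpy as np
import pytest
from skimage.feature import corner_shi_tomasi

from fluortrack.errors import TrackingLostError, ValidationError
from fluortrack.io import ROIAnnotation
from fluortrack.synth import (
    GROUP_PRESETS,
    SceneConfig,
    simulate_video,
    smooth_camera_path,
)
from fluortrack.tracking import (
    FeaturePoint,
    TrackerConfig,
    TrackingConfig,
    detect_features,
    polygon_iou,
    propagate_roi,
    run_tracking,
    track_step,
)

SQUARE = np.array([[50, 50], [250, 50], [250, 150], [50, 150]], dtype=float)


class TestDetectFeatures:
    def test_constant_frame_no_corners_warns(self):
        frame = np.full((100, 100, 3), 80, dtype=np.uint8)
        with pytest.warns(UserWarning, match="no detectable corners"):
            pts = detect_features(frame, np.array([[10, 10], [90, 10], [50, 90]]))
        assert pts == []

    def test_checkerboard_corners_within_one_pixel(self, checkerboard_rgb):
        polygon = np.array([[30, 30], [90, 30], [90, 90], [30, 90]], float)
        pts = detect_features(checkerboard_rgb, polygon, max_points=20)
        true = [(x, y) for x in (40, 60, 80) for y in (40, 60, 80)]
        assert len(pts) == 9
        for p in pts:
            dist = min(np.hypot(p.position[0] - tx, p.position[1] - ty) for tx, ty in true)
            assert dist <= 1.0

    def test_max_points_keeps_strongest_responses(self, checkerboard_rgb):
        polygon = np.array([[30, 30], [90, 30], [90, 90], [30, 90]], float)
        all_pts = detect_features(checkerboard_rgb, polygon, max_points=20)
        top4 = detect_features(checkerboard_rgb, polygon, max_points=4)
        gray = checkerboard_rgb[..., :3].astype(float) @ [0.299, 0.587, 0.114]
        resp = corner_shi_tomasi(gray, sigma=1.5)
        score = lambda p: resp[int(p.position[1]), int(p.position[0])]
        best4 = sorted((score(p) for p in all_pts), reverse=True)[:4]
        assert sorted((score(p) for p in top4), reverse=True) == pytest.approx(best4)

    def test_points_lie_inside_polygon(self, textured_rgb):
        from matplotlib.path import Path

        pts = detect_features(textured_rgb, SQUARE, max_points=50)
        path = Path(SQUARE)
        assert all(path.contains_point(p.position, radius=1e-9) for p in pts)

    def test_min_distance_respected(self, textured_rgb):
        pts = detect_features(textured_rgb, SQUARE, max_points=50, min_distance=15)
        pos = np.array([p.position for p in pts])
        d = np.hypot(*(pos[:, None, :] - pos[None, :, :]).T)
        np.fill_diagonal(d, np.inf)
        assert d.min() >= 15.0


class TestTrackStep:
    def test_identical_frames_zero_displacement(self, textured_rgb):
        pts = detect_features(textured_rgb, SQUARE, max_points=30)
        moved = track_step(textured_rgb, textured_rgb, pts)
        for p, m in zip(pts, moved):
            assert m.valid
            assert np.hypot(m.position[0] - p.position[0], m.position[1] - p.position[1]) == 0.0

    def test_pure_translation_recovered(self, textured_rgb):
        nxt = np.roll(textured_rgb, 3, axis=1)  # +3 px in x
        pts = detect_features(textured_rgb, SQUARE, max_points=40)
        moved = track_step(textured_rgb, nxt, pts)
        disp = np.array([m.position for m in moved]) - np.array([p.position for p in pts])
        med = np.median(disp, axis=0)
        assert np.hypot(med[0] - 3.0, med[1]) < 0.5

    def test_uncorrelated_noise_invalidates_points(self, textured_rgb):
        rng = np.random.default_rng(1)
        noise = rng.uniform(0, 255, textured_rgb.shape).astype(np.uint8)
        pts = detect_features(textured_rgb, SQUARE, max_points=40)
        moved = track_step(textured_rgb, noise, pts)
        assert sum(not m.valid for m in moved) >= 0.9 * len(moved)

    def test_frame_size_mismatch_raises(self, textured_rgb):
        with pytest.raises(ValidationError):
            track_step(textured_rgb, textured_rgb[:100], [FeaturePoint(0, (60.0, 60.0))])


class TestPropagateRoi:
    def test_pure_translation(self):
        rng = np.random.default_rng(0)
        src = rng.uniform(60, 140, (15, 2))
        new_poly, _ = propagate_roi(SQUARE, (src, src + [5.0, -2.0]))
        assert np.allclose(new_poly, SQUARE + [5.0, -2.0], atol=1e-9)

    def test_known_rotation_closed_form(self):
        rng = np.random.default_rng(2)
        c = SQUARE.mean(axis=0)
        th = np.deg2rad(10.0)
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        src = rng.uniform(60, 140, (20, 2))
        new_poly, _ = propagate_roi(SQUARE, (src, (src - c) @ R.T + c))
        assert np.abs(new_poly - ((SQUARE - c) @ R.T + c)).max() < 0.5

    def test_gross_outliers_ignored(self):
        rng = np.random.default_rng(3)
        src = rng.uniform(60, 140, (20, 2))
        clean, _ = propagate_roi(SQUARE, (src, src + [5.0, -2.0]))
        src2 = np.vstack([src, [[70, 70], [100, 100]]])
        dst2 = np.vstack([src + [5.0, -2.0], [[200, 10], [10, 190]]])
        robust, info = propagate_roi(SQUARE, (src2, dst2))
        assert np.abs(robust - clean).max() < 0.5
        assert info["inlier_ratio"] >= 20 / 22 - 1e-9

    def test_area_scales_with_square_of_scale(self):
        from shapely.geometry import Polygon

        rng = np.random.default_rng(4)
        src = rng.uniform(60, 140, (15, 2))
        s = 1.07
        c = SQUARE.mean(axis=0)
        dst = (src - c) * s + c
        new_poly, info = propagate_roi(SQUARE, (src, dst))
        ratio = Polygon(new_poly).area / Polygon(SQUARE).area
        assert ratio == pytest.approx(info["scale"] ** 2, rel=0.01)

    def test_too_few_points_raises_tracking_lost(self):
        with pytest.raises(TrackingLostError):
            propagate_roi(SQUARE, (np.zeros((2, 2)), np.zeros((2, 2))))


def _scene(duration_s=12.0, fps=15.0, moving=True, occlusions=(), noise=1.0):
    scene = SceneConfig(
        frame_shape=(120, 160),
        fps=fps,
        duration_s=duration_s,
        lesion_polygon=np.array([[30, 30], [65, 28], [70, 60], [35, 65]], float),
        control_polygon=np.array([[100, 35], [132, 38], [130, 70], [98, 66]], float),
        lesion_params=GROUP_PRESETS["control"],
        control_params=GROUP_PRESETS["benign"],
        occlusions=list(occlusions),
        nir_noise_sd_gu=noise,
    )
    if moving:
        scene.camera_path = smooth_camera_path(
            scene.n_frames, scene.fps, translation_px=6, rotation_deg=2,
            scale_amplitude=0.02, period_s=8.0,
        )
    return scene


def _annotations(scene):
    return [
        ROIAnnotation("lesion", "tumour", 0, scene.lesion_polygon),
        ROIAnnotation("control", "control", 0, scene.control_polygon),
    ]


class TestRunTracking:
    def test_static_video_constant_polygons_no_gaps(self):
        scene = _scene(duration_s=4.0, moving=False)
        video = simulate_video(scene)
        results = run_tracking(video, _annotations(scene))
        for res in results:
            polys = np.stack(list(res.per_frame_polygons.values()))
            assert np.allclose(polys, polys[0], atol=1e-6)
            assert res.gaps == []
            assert res.censored_seconds == 0.0

    def test_moving_camera_high_iou_no_censoring(self):
        scene = _scene(duration_s=12.0)
        video = simulate_video(scene)
        results = run_tracking(video, _annotations(scene))
        for res in results:
            assert res.gaps == []
            ious = [
                polygon_iou(res.per_frame_polygons[k], video.truth_polygons[res.roi_label][k])
                for k in res.per_frame_polygons
            ]
            assert np.mean(ious) >= 0.90

    def test_occlusion_opens_single_exact_gap(self):
        scene = _scene(duration_s=10.0, moving=False, occlusions=[(60, 89)])
        video = simulate_video(scene)
        results = run_tracking(video, _annotations(scene), TrackingConfig(auto_reinit=True))
        for res in results:
            assert len(res.gaps) == 1
            start, end, _ = res.gaps[0]
            assert (start, end) == (60, 89)
            assert res.censored_seconds == pytest.approx(30 / scene.fps)
            assert res.reinit_frames == [90]

    def test_manual_reannotation_closes_gap(self):
        scene = _scene(duration_s=10.0, moving=False, occlusions=[(60, 89)])
        video = simulate_video(scene)
        anns = _annotations(scene) + [
            ROIAnnotation("lesion", "tumour", 95, scene.lesion_polygon)
        ]
        results = run_tracking(video, anns, TrackingConfig(auto_reinit=False))
        lesion = next(r for r in results if r.roi_label == "lesion")
        assert lesion.gaps == [(60, 94, lesion.gaps[0][2])]
        assert lesion.reinit_frames == [95]
        assert 96 in lesion.per_frame_polygons

    def test_deterministic_given_identical_inputs(self):
        scene = _scene(duration_s=4.0)
        video = simulate_video(scene)
        r1 = run_tracking(video, _annotations(scene))
        r2 = run_tracking(video, _annotations(scene))
        for a, b in zip(r1, r2):
            for k in a.per_frame_polygons:
                assert np.array_equal(a.per_frame_polygons[k], b.per_frame_polygons[k])

    def test_anchor_beyond_stream_raises(self):
        scene = _scene(duration_s=2.0, moving=False)
        video = simulate_video(scene)
        anns = [ROIAnnotation("late", "tumour", 10_000, scene.lesion_polygon)]
        with pytest.raises(ValidationError, match="beyond the stream end"):
            run_tracking(video, anns)
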