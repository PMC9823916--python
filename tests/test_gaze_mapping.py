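import numpy as np
import pytest

from gaze3d.camera_geometry import BehindCameraError, Ray, project
from gaze3d.eyeball_fit import EyeballModel
from gaze3d.gaze_mapping import (
    GazeMapper,
    export_self_labels,
    intersect_ray_sphere,
    map_point_ir_to_rgb,
    map_rect_ir_to_rgb,
    validate_model,
)
from gaze3d.synthetic_rig import SimulationConfig, simulate_session

def axial_ray(v=(0.0, 0.0, 1.0)):
    return Ray(origin=np.zeros(3), direction=np.asarray(v, float))


class TestIntersectRaySphere:
    def test_axial_two_roots_takes_near_surface(self):
        model = EyeballModel(C=[0, 0, 30.0], r=12.0)
        P, kind = intersect_ray_sphere(axial_ray(), model)
        np.testing.assert_allclose(P, [0, 0, 18.0], atol=1e-12)
        assert kind == "two_roots"

    def test_missing_ray_uses_real_part_of_roots(self):
        # sphere offset sideways beyond the radius: discriminant < 0,
        # real part of the conjugate roots is v.C = 30
        model = EyeballModel(C=[13.0, 0, 30.0], r=12.0)
        P, kind = intersect_ray_sphere(axial_ray(), model)
        np.testing.assert_allclose(P, [0, 0, 30.0], atol=1e-12)
        assert kind == "approximated_complex"

    def test_sphere_behind_camera_raises(self):
        model = EyeballModel(C=[0, 0, -30.0], r=12.0)
        with pytest.raises(BehindCameraError):
            intersect_ray_sphere(axial_ray(), model)

    def test_camera_inside_sphere_rejected(self):
        model = EyeballModel(C=[0, 0, 5.0], r=12.0)
        with pytest.raises(BehindCameraError):
            intersect_ray_sphere(axial_ray(), model)

    def test_matches_dense_sampling_oracle(self, rng):
        """First surface crossing found by 1e-3 mm stepping, 1000 cases."""
        worst = 0.0
        n_real = 0
        for _ in range(1000):
            C = np.array(
                [rng.uniform(-8, 8), rng.uniform(-8, 8), rng.uniform(25, 45)]
            )
            model = EyeballModel(C=C, r=12.0)
            v = np.array([rng.uniform(-0.3, 0.3), rng.uniform(-0.3, 0.3), 1.0])
            v /= np.linalg.norm(v)
            ray = axial_ray(v)
            P, kind = intersect_ray_sphere(ray, model)
            if kind != "two_roots":
                continue
            n_real += 1
            alphas = np.arange(0.0, 60.0, 1e-3)
            dist = np.linalg.norm(alphas[:, None] * v[None, :] - C, axis=1) - 12.0
            crossing = np.nonzero(np.diff(np.sign(dist)))[0]
            assert crossing.size > 0
            alpha_oracle = alphas[crossing[0]]
            worst = max(worst, abs(np.linalg.norm(P) - alpha_oracle))
        assert n_real > 500  # the sampling hits the sphere most of the time
        assert worst < 2e-3

    def test_deeper_center_keeps_axial_intersection_real(self):
        """Pushing the model straight away from the camera never turns a
        real axial intersection complex."""
        for z in np.linspace(15.0, 200.0, 50):
            _, kind = intersect_ray_sphere(axial_ray(), EyeballModel(C=[0, 0, z], r=12.0))
            assert kind == "two_roots"


class TestMapPoint:
    def test_axial_model_principal_point(self, rig):
        model = EyeballModel(C=[0, 0, 30.0], r=12.0)
        res = map_point_ir_to_rgb(rig, model, (400.0, 300.0))
        np.testing.assert_allclose(res.P_w, [0, 0, 18.0], atol=1e-9)
        np.testing.assert_allclose(res.gaze.direction, [0, 0, -1.0], atol=1e-9)

    def test_simulator_roundtrip_within_half_pixel(self):
        session = simulate_session(SimulationConfig(n_frames=60, seed=3))
        model = session.ground_truth
        for frame in session.frames:
            res = map_point_ir_to_rgb(session.rig, model, frame.ir_detection.center)
            gt = project(session.rig, frame.true_pupil_3d, "rgb")
            assert np.linalg.norm(res.p_rgb - gt) < 0.5

    def test_deterministic(self, rig):
        model = EyeballModel(C=[1.0, -0.5, 32.0], r=12.0)
        a = map_point_ir_to_rgb(rig, model, (410.5, 295.25))
        b = map_point_ir_to_rgb(rig, model, (410.5, 295.25))
        assert np.array_equal(a.p_rgb, b.p_rgb)
        assert np.array_equal(a.P_w, b.P_w)

    def test_gaze_pixel_point_mutually_consistent(self, rig, rng):
        """Re-deriving p_rgb from the gaze ray's sphere crossing reproduces it."""
        model = EyeballModel(C=[0.5, 0.5, 31.0], r=12.0)
        for _ in range(100):
            p_ir = rng.uniform([300, 200], [500, 400])
            res = map_point_ir_to_rgb(rig, model, p_ir)
            if res.intersection_kind != "two_roots":
                continue
            assert abs(np.linalg.norm(res.P_w - model.C) - model.r) < 1e-6
            P_again = model.C + model.r * res.gaze.direction
            p_again = project(rig, P_again, "rgb")
            np.testing.assert_array_equal(res.p_rgb, project(rig, res.P_w, "rgb"))
            np.testing.assert_allclose(p_again, res.p_rgb, atol=1e-6)


class TestMapRect:
    def test_degenerate_rect_consistent_with_point_mapping(self, rig):
        model = EyeballModel(C=[0, 0, 30.0], r=12.0)
        rect = ((400.0, 300.0), (401.0, 301.0))
        out = map_rect_ir_to_rgb(rig, model, rect)
        q1 = map_point_ir_to_rgb(rig, model, rect[0]).p_rgb
        q2 = map_point_ir_to_rgb(rig, model, rect[1]).p_rgb
        lo = np.minimum(q1, q2)
        hi = np.maximum(q1, q2)
        np.testing.assert_allclose(out[0], lo)
        np.testing.assert_allclose(out[1], hi)

    def test_noiseless_session_rect_iou_above_0p8(self):
        from gaze3d.evaluation import iou

        session = simulate_session(SimulationConfig(n_frames=60, seed=5))
        model = session.ground_truth
        scores = [
            iou(
                map_rect_ir_to_rgb(session.rig, model, f.ir_detection.rect),
                f.true_rgb_rect,
            )
            for f in session.frames
        ]
        assert np.median(scores) > 0.8

    def test_corner_order_preserved_for_random_rects(self, rig, rng):
        model = EyeballModel(C=[0, 0, 30.0], r=12.0)
        for _ in range(500):
            x1, y1 = rng.uniform([300, 220], [480, 360])
            w, h = rng.uniform(2, 40, 2)
            out = map_rect_ir_to_rgb(rig, model, ((x1, y1), (x1 + w, y1 + h)))
            (ox1, oy1), (ox2, oy2) = out
            assert ox1 <= ox2 and oy1 <= oy2


def rect_at(x, y, w=10.0, h=10.0):
    return ((x, y), (x + w, y + h))


class TestValidateModel:
    def test_agreeing_frames_stay_valid(self):
        frames = [(rect_at(0, 0), rect_at(1, 0)) for _ in range(50)]
        assert validate_model(frames, n_consecutive=5) == "valid"

    def test_consecutive_disagreement_invalidates(self):
        good = [(rect_at(0, 0), rect_at(1, 0))] * 10
        bad = [(rect_at(0, 0), rect_at(100, 100))] * 5
        assert validate_model(good + bad, n_consecutive=5) == "invalid"
        assert validate_model(good + bad[:4], n_consecutive=5) == "valid"

    def test_missing_detections_do_not_break_or_extend_runs(self):
        bad = (rect_at(0, 0), rect_at(100, 100))
        gap = (rect_at(0, 0), None)
        frames = [bad, bad, gap, bad, bad, bad]
        # the gap neither resets nor extends: 5 disagreeing frames total
        assert validate_model(frames, n_consecutive=5) == "invalid"
        assert validate_model(frames[:-1], n_consecutive=5) == "valid"

    def test_matches_scan_for_run_oracle(self, rng):
        for _ in range(200):
            frames = []
            status = []
            for _ in range(int(rng.integers(1, 40))):
                u = rng.uniform()
                if u < 0.2:
                    frames.append((rect_at(0, 0), None))
                    status.append(None)
                elif u < 0.6:
                    frames.append((rect_at(0, 0), rect_at(1, 0)))  # agree
                    status.append(True)
                else:
                    frames.append((rect_at(0, 0), rect_at(50, 50)))  # disagree
                    status.append(False)
            n = int(rng.integers(1, 6))
            run = 0
            invalid = False
            for s in status:
                if s is None:
                    continue
                run = run + 1 if not s else 0
                invalid = invalid or run >= n
            assert validate_model(frames, n_consecutive=n) == (
                "invalid" if invalid else "valid"
            )


class TestSelfLabels:
    def test_perfect_agreement_accepted(self):
        labels = export_self_labels([(rect_at(0, 0), rect_at(0, 0))])
        assert labels[0].accepted and labels[0].iou == 1.0

    def test_disjoint_rejected(self):
        labels = export_self_labels([(rect_at(0, 0), rect_at(100, 100))])
        assert not labels[0].accepted and labels[0].iou == 0.0

    def test_frames_without_detector_dropped(self):
        labels = export_self_labels([(rect_at(0, 0), None), (rect_at(0, 0), rect_at(0, 0))])
        assert [l.frame_id for l in labels] == [1]

    def test_acceptance_fraction_matches_ground_truth_exactly(self, rng):
        """Accepted fraction equals the fraction of frames with IoU >= 0.5."""
        from gaze3d.evaluation import iou

        frames = []
        for _ in range(300):
            shift = rng.uniform(0, 15)
            frames.append((rect_at(0, 0), rect_at(shift, 0) if rng.uniform() > 0.1 else None))
        labels = export_self_labels(frames)
        expected = [
            iou(m, d) >= 0.5 for m, d in frames if d is not None
        ]
        assert [l.accepted for l in labels] == expected
        assert sum(l.accepted for l in labels) / len(labels) == np.mean(expected)


class TestGazeMapperEstimator:
    def test_fit_transform_maps_centers(self):
        from gaze3d.triangulation import (
            filter_points,
            pair_detections,
            triangulate_detections,
        )

        session = simulate_session(SimulationConfig(n_frames=60, seed=11))
        pairs = pair_detections(session.ir_stream, session.rgb_stream)
        pts = filter_points(triangulate_detections(session.rig, pairs))
        mapper = GazeMapper(rig=session.rig).fit(np.array([p.S for p in pts]))
        np.testing.assert_allclose(mapper.model_.C, session.ground_truth.C, atol=1e-3)
        X = np.array([f.ir_detection.center for f in session.frames[:10]])
        Y = mapper.transform(X)
        gt = np.array(
            [project(session.rig, f.true_pupil_3d, "rgb") for f in session.frames[:10]]
        )
        assert np.abs(Y - gt).max() < 0.5
        dirs = mapper.gaze_directions(X)
        np.testing.assert_allclose(np.linalg.norm(dirs, axis=1), 1.0, atol=1e-9)
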