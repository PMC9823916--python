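"""Synthetic stereo eye-tracking sessions with exact ground truth.

Emulates the head-mounted capture geometry: two close-range eye cameras
(IR at the world origin, RGB ~20 mm to the side, yawed toward the eye), a
12 mm eyeball ~35 mm away, and a pupil wandering over a gaze cone while
frames are captured at ~1 Hz.  Each frame carries noisy pupil detections
for both cameras plus the exact 3D ground truth, so every stage of the
pipeline (pairing, triangulation, filtering, sphere fit, mapping) can be
scored against truth.

The bounding-rectangle corners are projections of true 3D points offset
from the pupil center in the camera-facing tangent plane, so corner
triangulation is exact when the pixel noise is zero; rectangle-size jitter
perturbs that 3D half-extent and therefore stays geometrically consistent
between the two cameras.  Failure modes are injected per frame: *outlier*
frames replace one camera's detection with a uniform random in-image
rectangle (a wrong detector lock), *desynced* frames compute one camera's
detection from a different gaze sample (capture during a saccade).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .camera_geometry import CameraIntrinsics, StereoRig, project
from .eyeball_fit import DEFAULT_EYEBALL_RADIUS_MM, EyeballModel
from .gaze_mapping import GazeRay
from .triangulation import DetectionRecord

__all__ = [
    "SimulationConfig",
    "SyntheticFrame",
    "SyntheticSession",
    "SimulationSetupError",
    "make_rig",
    "simulate_session",
    "render_eye_images",
]

FrameFlag = Literal["clean", "outlier", "desynced"]


class SimulationSetupError(ValueError):
    """Raised when the configured geometry cannot produce visible detections."""


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition knobs for one synthetic capture session.

    Defaults mimic the target device scale: 1280x960 sensors, ~20 mm
    stereo baseline, eyeball ~35 mm from the IR camera, one frame pair per
    second, and a 25 degree free-viewing gaze cone.
    """

    focal_px: float = 200.0
    image_size: tuple[int, int] = (1280, 960)  # (width, height)
    baseline_mm: float = 20.0
    rotation_deg: float = 30.0  # RGB yaw (about +y) toward the eye
    eye_center: tuple[float, float, float] = (0.0, 0.0, 35.0)
    r: float = DEFAULT_EYEBALL_RADIUS_MM
    n_frames: int = 150
    frame_interval_s: float = 1.0
    timestamp_jitter_s: float = 0.03
    gaze_cone_half_angle_deg: float = 25.0
    pupil_half_extent_mm: float = 1.5
    rect_size_jitter: float = 0.1
    pixel_noise_sigma: float = 0.0
    outlier_rate: float = 0.0
    desync_rate: float = 0.0
    shift_at_frame: int | None = None  # headset-slip injection
    shift_mm: tuple[float, float, float] = (0.0, 0.0, 3.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames <= 0:
            raise ValueError("n_frames must be positive")
        for name in ("outlier_rate", "desync_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass(frozen=True)
class SyntheticFrame:
    timestamp: float
    true_gaze: GazeRay
    true_pupil_3d: np.ndarray
    ir_detection: DetectionRecord
    rgb_detection: DetectionRecord
    flag: FrameFlag
    true_ir_rect: tuple[tuple[float, float], tuple[float, float]] | None = None
    true_rgb_rect: tuple[tuple[float, float], tuple[float, float]] | None = None


@dataclass(frozen=True)
class SyntheticSession:
    frames: list[SyntheticFrame]
    ground_truth: EyeballModel
    rig: StereoRig
    config: SimulationConfig

    @property
    def ir_stream(self) -> list[DetectionRecord]:
        return [f.ir_detection for f in self.frames]

    @property
    def rgb_stream(self) -> list[DetectionRecord]:
        return [f.rgb_detection for f in self.frames]


def make_rig(config: SimulationConfig) -> StereoRig:
    """Build the stereo rig the simulator (and its consumers) agree on."""
    w, h = config.image_size
    K = np.array(
        [[config.focal_px, 0.0, w / 2.0], [0.0, config.focal_px, h / 2.0], [0.0, 0.0, 1.0]]
    )
    intr = CameraIntrinsics(K=K, image_width=w, image_height=h)
    th = math.radians(config.rotation_deg)
    c, s = math.cos(th), math.sin(th)
    R = np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])
    C_rgb = np.array([config.baseline_mm, 0.0, 0.0])
    T = -R @ C_rgb
    return StereoRig(ir=intr, rgb=intr, R=R, T=T)


def _sample_cone(rng: np.random.Generator, axis: np.ndarray, half_angle_rad: float) -> np.ndarray:
    """Uniform unit vector within the cone of given half-angle about axis."""
    cos_min = math.cos(half_angle_rad)
    z = rng.uniform(cos_min, 1.0)
    phi = rng.uniform(0.0, 2.0 * math.pi)
    rho = math.sqrt(max(0.0, 1.0 - z * z))
    v = np.array([rho * math.cos(phi), rho * math.sin(phi), z])
    # rotate +z onto axis
    axis = axis / np.linalg.norm(axis)
    if axis[2] > 1 - 1e-12:
        return v
    if axis[2] < -1 + 1e-12:
        return np.array([v[0], -v[1], -v[2]])
    k = np.cross(np.array([0.0, 0.0, 1.0]), axis)
    k /= np.linalg.norm(k)
    cos_t = axis[2]
    sin_t = math.sqrt(max(0.0, 1.0 - cos_t * cos_t))
    return v * cos_t + np.cross(k, v) * sin_t + k * (k @ v) * (1 - cos_t)


def _detection_for(
    rig: StereoRig,
    camera: str,
    P: np.ndarray,
    eye_center: np.ndarray,
    r: float,
    half_extent: float,
    timestamp: float,
    sigma: float,
    noise_rng: np.random.Generator,
    score: float,
) -> DetectionRecord:
    """Project the pupil point and its rect-corner 3D offsets; add pixel noise.

    The corner points are offset in the image-axis-aligned tangent
    directions and re-projected onto the eyeball sphere, where the pupil
    boundary physically lies.
    """

    def on_sphere(Q: np.ndarray) -> np.ndarray:
        v = Q - eye_center
        return eye_center + r * v / np.linalg.norm(v)

    tl3 = on_sphere(P + np.array([-half_extent, -half_extent, 0.0]))
    br3 = on_sphere(P + np.array([half_extent, half_extent, 0.0]))
    c2 = project(rig, P, camera)
    p1 = project(rig, tl3, camera)
    p2 = project(rig, br3, camera)
    if sigma > 0:
        c2 = c2 + noise_rng.normal(0.0, sigma, 2)
        p1 = p1 + noise_rng.normal(0.0, sigma, 2)
        p2 = p2 + noise_rng.normal(0.0, sigma, 2)
    lo = np.minimum(p1, p2)
    hi = np.maximum(p1, p2)
    # keep the (noisy) center inside the rect
    lo = np.minimum(lo, c2 - 1e-6)
    hi = np.maximum(hi, c2 + 1e-6)
    return DetectionRecord(
        timestamp=timestamp,
        camera=camera,
        rect_top_left=(float(lo[0]), float(lo[1])),
        rect_bottom_right=(float(hi[0]), float(hi[1])),
        center=(float(c2[0]), float(c2[1])),
        score=score,
    )


def _random_rect_detection(
    rig: StereoRig, camera: str, timestamp: float, rng: np.random.Generator, score: float
) -> DetectionRecord:
    intr = rig.intrinsics(camera)
    size = rng.uniform(8.0, 30.0)
    cx = rng.uniform(size, intr.image_width - size)
    cy = rng.uniform(size, intr.image_height - size)
    return DetectionRecord(
        timestamp=timestamp,
        camera=camera,
        rect_top_left=(cx - size / 2, cy - size / 2),
        rect_bottom_right=(cx + size / 2, cy + size / 2),
        center=(cx, cy),
        score=score,
    )


def _pupil_point(C: np.ndarray, r: float, g: np.ndarray) -> np.ndarray:
    return C + r * g


def simulate_session(config: SimulationConfig) -> SyntheticSession:
    """Generate a full synthetic session; deterministic under ``config.seed``.

    Pupil 3D points are sampled on the eyeball sphere within the gaze cone
    about the camera-facing direction, projected into both cameras, and
    perturbed with isotropic Gaussian pixel noise.  Outlier / desync frames
    are drawn independently per frame at the configured rates.
    """
    rig = make_rig(config)
    C = np.asarray(config.eye_center, dtype=float)
    ss = np.random.SeedSequence(config.seed)
    rng_gaze, rng_noise, rng_fail, rng_time = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )
    axis = -C / np.linalg.norm(C)  # camera-facing direction from the eye center
    half = math.radians(config.gaze_cone_half_angle_deg)

    # setup visibility check on the cone extremes
    for probe in np.linspace(0.0, 2 * math.pi, 8, endpoint=False):
        g = np.array(
            [math.sin(half) * math.cos(probe), math.sin(half) * math.sin(probe), 0.0]
        )
        g = g - (g @ axis) * axis + math.cos(half) * axis
        g /= np.linalg.norm(g)
        P = _pupil_point(C, config.r, g)
        for cam in ("ir", "rgb"):
            p = project(rig, P, cam)
            intr = rig.intrinsics(cam)
            if not (0 <= p[0] < intr.image_width and 0 <= p[1] < intr.image_height):
                raise SimulationSetupError(
                    f"eye not visible in the {cam} camera at the gaze-cone edge "
                    f"(pixel {p}); adjust the rig or eye position"
                )

    frames: list[SyntheticFrame] = []
    for i in range(config.n_frames):
        center = C.copy()
        if config.shift_at_frame is not None and i >= config.shift_at_frame:
            center = center + np.asarray(config.shift_mm, dtype=float)
        g = _sample_cone(rng_gaze, axis, half)
        P = _pupil_point(center, config.r, g)
        t0 = i * config.frame_interval_s
        t_ir = t0 + rng_time.uniform(0.0, config.timestamp_jitter_s)
        t_rgb = t0 + rng_time.uniform(0.0, config.timestamp_jitter_s)
        s_frame = config.pupil_half_extent_mm * (
            1.0 + config.rect_size_jitter * rng_noise.uniform(-1.0, 1.0)
        )
        score_ir = 0.9 + 0.1 * rng_noise.uniform()
        score_rgb = 0.9 + 0.1 * rng_noise.uniform()

        u = rng_fail.uniform()
        flag: FrameFlag = "clean"
        if u < config.outlier_rate:
            flag = "outlier"
        elif u < config.outlier_rate + config.desync_rate:
            flag = "desynced"

        det_ir = _detection_for(
            rig, "ir", P, center, config.r, s_frame, t_ir,
            config.pixel_noise_sigma, rng_noise, score_ir
        )
        det_rgb = _detection_for(
            rig, "rgb", P, center, config.r, s_frame, t_rgb,
            config.pixel_noise_sigma, rng_noise, score_rgb
        )
        true_ir_rect = det_ir.rect if config.pixel_noise_sigma == 0 else None
        true_rgb_rect = det_rgb.rect if config.pixel_noise_sigma == 0 else None

        if flag == "outlier":
            if rng_fail.uniform() < 0.5:
                det_ir = _random_rect_detection(rig, "ir", t_ir, rng_fail, score_ir)
            else:
                det_rgb = _random_rect_detection(rig, "rgb", t_rgb, rng_fail, score_rgb)
        elif flag == "desynced":
            # one camera captured a different fixation (mid-saccade pair)
            g2 = _sample_cone(rng_fail, axis, half)
            P2 = _pupil_point(center, config.r, g2)
            if rng_fail.uniform() < 0.5:
                det_ir = _detection_for(
                    rig, "ir", P2, center, config.r, s_frame, t_ir,
                    config.pixel_noise_sigma, rng_noise, score_ir
                )
            else:
                det_rgb = _detection_for(
                    rig, "rgb", P2, center, config.r, s_frame, t_rgb,
                    config.pixel_noise_sigma, rng_noise, score_rgb
                )

        gaze = GazeRay(origin=center, direction=g, pupil_point=P)
        frames.append(
            SyntheticFrame(
                timestamp=t0,
                true_gaze=gaze,
                true_pupil_3d=P,
                ir_detection=det_ir,
                rgb_detection=det_rgb,
                flag=flag,
                true_ir_rect=true_ir_rect,
                true_rgb_rect=true_rgb_rect,
            )
        )
    model = EyeballModel(C=C, r=config.r)
    return SyntheticSession(frames=frames, ground_truth=model, rig=rig, config=config)


def render_eye_images(
    session: SyntheticSession,
    out_dir,
    camera: str = "ir",
    scale: float = 0.25,
    specular_blobs: int = 0,
) -> list[dict]:
    """Render simple synthetic eye images plus exact label sidecars.

    Dark elliptical pupil on an iris disc on a lighter sclera background,
    optionally with bright specular blobs emulating corneal reflections.
    Images are written as PNG named by timestamp with a JSON sidecar per
    frame carrying the detection rect and center (labels are unaffected by
    styling).  Returns the label dictionaries.
    """
    import json
    from pathlib import Path

    from PIL import Image

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    intr = session.rig.intrinsics(camera)
    W = max(8, int(round(intr.image_width * scale)))
    H = max(8, int(round(intr.image_height * scale)))
    yy, xx = np.mgrid[0:H, 0:W].astype(float)
    rng = np.random.default_rng(session.config.seed + 104729)
    labels = []
    for i, frame in enumerate(session.frames):
        det = frame.ir_detection if camera == "ir" else frame.rgb_detection
        cx, cy = det.center[0] * scale, det.center[1] * scale
        (x1, y1), (x2, y2) = det.rect
        ax = max(1.0, (x2 - x1) * scale / 2.0)
        ay = max(1.0, (y2 - y1) * scale / 2.0)
        img = np.full((H, W), 200.0)  # sclera
        iris = ((xx - cx) / (3.0 * ax)) ** 2 + ((yy - cy) / (3.0 * ay)) ** 2 <= 1.0
        img[iris] = 110.0
        pupil = ((xx - cx) / ax) ** 2 + ((yy - cy) / ay) ** 2 <= 1.0
        img[pupil] = 20.0
        for _ in range(specular_blobs):
            bx = cx + rng.uniform(-2 * ax, 2 * ax)
            by = cy + rng.uniform(-2 * ay, 2 * ay)
            blob = (xx - bx) ** 2 + (yy - by) ** 2 <= (0.3 * ax) ** 2
            img[blob] = 250.0
        name = f"{camera}_{frame.timestamp:010.3f}"
        Image.fromarray(img.astype(np.uint8), mode="L").save(out_dir / f"{name}.png")
        label = {
            "frame": i,
            "camera": camera,
            "timestamp": frame.timestamp,
            "image": f"{name}.png",
            "scale": scale,
            "center": [det.center[0], det.center[1]],
            "rect": [[x1, y1], [x2, y2]],
            "score": det.score,
        }
        (out_dir / f"{name}.json").write_text(json.dumps(label))
        labels.append(label)
    return labels
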