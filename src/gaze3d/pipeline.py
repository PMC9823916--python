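"""High-level session pipeline: detections → eyeball model → mappings → metrics.

Glue shared by the CLI, the tests and the reproduction script.  Each stage
delegates to the corresponding module and records counts so a run can be
audited (how many pairs formed, how many 3D points survived each filter).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .camera_geometry import StereoRig
from .evaluation import FramePairEvaluation, angular_error, iou, pixel_error
from .eyeball_fit import EyeballModel, RobustFitConfig, fit_eyeball
from .gaze_mapping import MappingResult, map_point_ir_to_rgb, map_rect_ir_to_rgb
from .triangulation import (
    DetectionRecord,
    filter_points,
    pair_detections,
    triangulate_detections,
)

__all__ = ["PipelineConfig", "FitReport", "build_eyeball_model", "map_session",
           "evaluate_synthetic_session"]


@dataclass(frozen=True)
class PipelineConfig:
    """All pipeline tunables with their standard defaults.

    gap_max / norm_window: stereo-consistency filters (mm); deltas: the
    M-estimator truncation schedule (mm); iou_min / n_consecutive /
    validation_period: online model validation; r: eyeball radius (mm).
    """

    one_per_interval: float = 1.0
    triangulate_points: str = "corners+center"
    gap_max: float = 2.0
    norm_window: float = 2.0
    r: float = 12.0
    fit: RobustFitConfig = field(default_factory=RobustFitConfig)
    iou_min: float = 0.5
    n_consecutive: int = 10
    validation_period: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("one_per_interval", "gap_max", "norm_window", "r"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class FitReport:
    n_ir: int
    n_rgb: int
    n_pairs: int
    n_points: int
    n_kept: int
    model: EyeballModel


def build_eyeball_model(
    rig: StereoRig,
    ir_stream: Sequence[DetectionRecord],
    rgb_stream: Sequence[DetectionRecord],
    config: PipelineConfig | None = None,
) -> FitReport:
    """Pair → triangulate → filter → robust sphere fit, with stage counts."""
    config = config or PipelineConfig()
    pairs = pair_detections(ir_stream, rgb_stream, config.one_per_interval)
    points = triangulate_detections(rig, pairs, points=config.triangulate_points)
    kept = filter_points(points, gap_max=config.gap_max, norm_window=config.norm_window)
    model = fit_eyeball(
        np.array([p.S for p in kept]), r=config.r, config=config.fit
    )
    return FitReport(
        n_ir=len(ir_stream),
        n_rgb=len(rgb_stream),
        n_pairs=len(pairs),
        n_points=len(points),
        n_kept=len(kept),
        model=model,
    )


def map_session(
    rig: StereoRig,
    model: EyeballModel,
    ir_stream: Sequence[DetectionRecord],
) -> list[tuple[DetectionRecord, MappingResult, tuple]]:
    """Map every IR detection (center + rect) through the fitted model."""
    out = []
    for det in ir_stream:
        res = map_point_ir_to_rgb(rig, model, det.center)
        rect = map_rect_ir_to_rgb(rig, model, det.rect)
        out.append((det, res, rect))
    return out


def evaluate_synthetic_session(session, model: EyeballModel) -> list[FramePairEvaluation]:
    """Score every synthetic frame against its exact ground truth.

    For each frame the IR detection center is mapped through the fitted
    model; the angular error compares the estimated and true gaze
    directions, the pixel error compares the mapped RGB center with the
    noiseless projection of the true pupil point, and the IoUs compare the
    mapped rectangle with the true RGB rectangle (ground truth) and the RGB
    detection (detector consensus).
    """
    from .camera_geometry import project

    evals = []
    for frame in session.frames:
        res = map_point_ir_to_rgb(session.rig, model, frame.ir_detection.center)
        rect = map_rect_ir_to_rgb(session.rig, model, frame.ir_detection.rect)
        gt_rgb_center = project(session.rig, frame.true_pupil_3d, "rgb")
        gt_rect = frame.true_rgb_rect or frame.rgb_detection.rect
        det_rect = frame.rgb_detection.rect
        iou_auto_dl = iou(rect, det_rect)
        evals.append(
            FramePairEvaluation(
                valid=True,
                ir_detected=True,
                gaze_error_deg=angular_error(res.gaze.direction, frame.true_gaze.direction),
                gaze_error_px=pixel_error(res.p_rgb, gt_rgb_center),
                iou_auto_gt=iou(rect, gt_rect),
                iou_dl_gt=iou(det_rect, gt_rect),
                consensus=iou_auto_dl > 0.5,
            )
        )
    return evals
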