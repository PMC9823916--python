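"""Point-to-point IR→RGB mapping through the eyeball sphere, gaze rays,
online model validation and self-supervised label export.

Once the per-user eyeball model exists, only the IR camera is needed: an IR
pupil pixel back-projects to a ray from the origin, the ray's first
intersection with the sphere is the 3D pupil point ``P_w``, the gaze ray
runs from the eyeball center through ``P_w`` out to the world, and ``P_w``
projects into the RGB image with the perspective matrix ``M_rgb``.

The quadratic ``alpha^2 - 2 (v.C) alpha + (||C||^2 - r^2) = 0`` gives the
ray depth; with two real roots the smaller positive one (the near, camera
facing surface) is taken.  When noise makes the discriminant negative the
real part of the conjugate roots, ``alpha = v.C``, is used and the result is
flagged ``approximated_complex`` so consumers can weight such frames.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
from sklearn.base import BaseEstimator

from .camera_geometry import BehindCameraError, Ray, StereoRig, backproject, project
from .evaluation import iou as rect_iou
from .eyeball_fit import EyeballModel

__all__ = [
    "GazeRay",
    "MappingResult",
    "SelfLabel",
    "GazeMapper",
    "intersect_ray_sphere",
    "map_point_ir_to_rgb",
    "map_rect_ir_to_rgb",
    "validate_model",
    "export_self_labels",
]

IntersectionKind = Literal["two_roots", "approximated_complex"]

Rect = tuple[tuple[float, float], tuple[float, float]]


@dataclass(frozen=True)
class GazeRay:
    """Optical-axis gaze: from the eyeball center through the pupil center."""

    origin: np.ndarray  # eyeball center, mm
    direction: np.ndarray  # unit, toward the world
    pupil_point: np.ndarray  # ray-sphere intersection P_w, mm


@dataclass(frozen=True)
class MappingResult:
    p_rgb: np.ndarray
    P_w: np.ndarray
    intersection_kind: IntersectionKind
    gaze: GazeRay


@dataclass(frozen=True)
class SelfLabel:
    """Automatically generated RGB pupil label candidate for one frame."""

    frame_id: int
    rgb_rect: Rect
    detector_rect: Rect
    iou: float
    accepted: bool


def intersect_ray_sphere(
    ray: Ray, model: EyeballModel
) -> tuple[np.ndarray, IntersectionKind]:
    """First intersection of a camera ray with the eyeball sphere.

    The ray must start at the world origin (the IR camera center).  Returns
    the 3D point and whether it came from a real root or from the
    complex-root approximation ``alpha = v.C``.
    """
    if np.linalg.norm(ray.origin) > 1e-9:
        raise ValueError("ray must originate at the IR camera center (origin)")
    v = ray.direction
    C = model.C
    b = float(v @ C)  # half the linear coefficient, sign flipped
    c = float(C @ C - model.r**2)
    disc = b * b - c
    if disc < 0:
        return b * v, "approximated_complex"
    sq = float(np.sqrt(disc))
    roots = (b - sq, b + sq)
    if roots[1] <= 0:
        raise BehindCameraError(
            "sphere lies behind the camera; the eyeball model is broken"
        )
    alpha = roots[0] if roots[0] > 0 else roots[1]
    if roots[0] <= 0 < roots[1]:
        # camera inside the sphere: geometrically impossible for a valid model
        raise BehindCameraError(
            "camera center lies inside the fitted sphere; model invalid"
        )
    return alpha * v, "two_roots"


def map_point_ir_to_rgb(rig: StereoRig, model: EyeballModel, p_ir) -> MappingResult:
    """Full IR-pixel → sphere → RGB-pixel chain, plus the gaze ray."""
    ray = backproject(rig, p_ir, "ir")
    P_w, kind = intersect_ray_sphere(ray, model)
    p_rgb = project(rig, P_w, "rgb")
    g = P_w - model.C
    n = np.linalg.norm(g)
    if n < 1e-12:
        raise ValueError("pupil point coincides with the eyeball center")
    gaze = GazeRay(origin=model.C.copy(), direction=g / n, pupil_point=P_w)
    return MappingResult(p_rgb=p_rgb, P_w=P_w, intersection_kind=kind, gaze=gaze)


def _normalize_rect(p1, p2) -> Rect:
    (x1, y1), (x2, y2) = p1, p2
    return (
        (float(min(x1, x2)), float(min(y1, y2))),
        (float(max(x1, x2)), float(max(y1, y2))),
    )


def map_rect_ir_to_rgb(rig: StereoRig, model: EyeballModel, rect: Rect) -> Rect:
    """Map an IR bounding rectangle corner-by-corner into the RGB plane.

    The two corners are mapped independently and re-ordered so the result
    stays a top-left / bottom-right rectangle; this region is the corneal
    image crop.
    """
    tl, br = rect
    q1 = map_point_ir_to_rgb(rig, model, tl).p_rgb
    q2 = map_point_ir_to_rgb(rig, model, br).p_rgb
    return _normalize_rect(q1, q2)


def validate_model(
    frames: Sequence[tuple[Rect, Rect | None]],
    iou_min: float = 0.5,
    n_consecutive: int = 10,
) -> str:
    """Online model check against occasional independent RGB detections.

    ``frames`` is a time-ordered sequence of ``(mapped_rect,
    detector_rect_or_None)``.  The model is declared ``"invalid"`` iff some
    run of ``n_consecutive`` successive frames *with* detector output all
    disagree (IoU below ``iou_min``); frames without a detection neither
    break nor extend a run.
    """
    run = 0
    for mapped, detected in frames:
        if detected is None:
            continue
        if rect_iou(mapped, detected) < iou_min:
            run += 1
            if run >= n_consecutive:
                return "invalid"
        else:
            run = 0
    return "valid"


def export_self_labels(
    frames: Iterable[tuple[Rect, Rect | None]],
    iou_min: float = 0.5,
) -> list[SelfLabel]:
    """Turn mapped/detected rectangle agreements into training labels.

    One label per frame with a detector rectangle; it is accepted iff the
    IoU with the mapped rectangle reaches ``iou_min``.  Frames without a
    detection are dropped (there is nothing to corroborate).
    """
    labels = []
    for i, (mapped, detected) in enumerate(frames):
        if detected is None:
            continue
        score = rect_iou(mapped, detected)
        labels.append(
            SelfLabel(
                frame_id=i,
                rgb_rect=mapped,
                detector_rect=detected,
                iou=score,
                accepted=score >= iou_min,
            )
        )
    return labels


class GazeMapper(BaseEstimator):
    """Sklearn-style transformer from IR pupil pixels to RGB pixels.

    ``fit`` ingests triangulated-and-filtered 3D pupil points (n, 3) and
    fits the eyeball sphere; ``transform`` maps an (n, 2) array of IR pixels
    to RGB pixels through the fitted model.  Thin composition of
    :class:`~gaze3d.eyeball_fit.EyeballEstimator` and
    :func:`map_point_ir_to_rgb` for pipeline use.
    """

    def __init__(self, rig: StereoRig | None = None, r: float = 12.0,
                 deltas: tuple[float, ...] = (1.0, 0.5)):
        self.rig = rig
        self.r = r
        self.deltas = deltas

    def fit(self, X, y=None) -> "GazeMapper":
        from .eyeball_fit import EyeballEstimator

        if self.rig is None:
            raise ValueError("GazeMapper requires a StereoRig")
        self.estimator_ = EyeballEstimator(r=self.r, deltas=self.deltas).fit(X)
        self.model_ = self.estimator_.model_
        return self

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return np.array(
            [map_point_ir_to_rgb(self.rig, self.model_, p).p_rgb for p in X]
        )

    def gaze_directions(self, X) -> np.ndarray:
        """Unit gaze directions (n, 3) for an (n, 2) array of IR pixels."""
        X = np.asarray(X, dtype=float)
        return np.array(
            [map_point_ir_to_rgb(self.rig, self.model_, p).gaze.direction for p in X]
        )
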