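"""Pairing, triangulation and outlier filtering of stereo pupil detections.

A pupil detection is a time-stamped bounding rectangle plus center in one
camera's pixel plane.  Synchronized IR/RGB detections are paired by nearest
timestamp (at most one pair per sampling interval), their rays are
back-projected and triangulated by the closest-approach midpoint, and the
resulting 3D points are filtered with two rules: the ray gap must not exceed
2 mm, and each ray depth must lie within 2 mm of its camera's median depth.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .camera_geometry import Ray, StereoRig, backproject

__all__ = [
    "DetectionRecord",
    "TriangulatedPoint",
    "DegenerateGeometryError",
    "pair_detections",
    "triangulate_pair",
    "triangulate_rays",
    "triangulate_detections",
    "filter_points",
    "read_detections",
    "write_detections",
]

DETECTION_COLUMNS = ["timestamp", "camera", "x1", "y1", "x2", "y2", "cx", "cy", "score"]


class DegenerateGeometryError(ValueError):
    """Raised when ray geometry admits no unique triangulation."""


@dataclass(frozen=True)
class DetectionRecord:
    """One pupil detection: bounding rectangle + center in pixel coordinates."""

    timestamp: float
    camera: str  # "ir" | "rgb"
    rect_top_left: tuple[float, float]
    rect_bottom_right: tuple[float, float]
    center: tuple[float, float]
    score: float = 1.0

    def __post_init__(self) -> None:
        (x1, y1), (x2, y2) = self.rect_top_left, self.rect_bottom_right
        if not (x1 < x2 and y1 < y2):
            raise ValueError("rect_top_left must be strictly above-left of rect_bottom_right")
        cx, cy = self.center
        if not (x1 <= cx <= x2 and y1 <= cy <= y2):
            raise ValueError("center must lie inside the bounding rectangle")
        if not 0.0 <= self.score <= 1.0:
            raise ValueError("score must be in [0, 1]")

    @property
    def rect(self) -> tuple[tuple[float, float], tuple[float, float]]:
        return (self.rect_top_left, self.rect_bottom_right)


@dataclass(frozen=True)
class TriangulatedPoint:
    """Closest-approach estimate of a 3D pupil point.

    ``S`` is the midpoint of the two closest ray points, ``d`` the gap
    between them, and ``alpha_ir``/``alpha_rgb`` the signed depths along the
    two rays (mm from each camera center).
    """

    S: np.ndarray
    d: float
    alpha_ir: float
    alpha_rgb: float
    source_pair: tuple[DetectionRecord, DetectionRecord] | None = None


def pair_detections(
    ir_stream: Sequence[DetectionRecord],
    rgb_stream: Sequence[DetectionRecord],
    one_per_interval: float = 1.0,
) -> list[tuple[DetectionRecord, DetectionRecord]]:
    """Pick, per time interval, the IR/RGB couple with the closest timestamps.

    Intervals are ``[k*T, (k+1)*T)`` anchored at t=0.  Within each interval
    every (ir, rgb) combination is considered and the minimum ``|dt|`` pair
    wins; ties go to the earlier RGB frame.  Intervals with detections from
    only one camera yield nothing.
    """
    if one_per_interval <= 0:
        raise ValueError("one_per_interval must be positive")
    by_interval_ir: dict[int, list[DetectionRecord]] = {}
    by_interval_rgb: dict[int, list[DetectionRecord]] = {}
    for rec in ir_stream:
        by_interval_ir.setdefault(int(rec.timestamp // one_per_interval), []).append(rec)
    for rec in rgb_stream:
        by_interval_rgb.setdefault(int(rec.timestamp // one_per_interval), []).append(rec)

    pairs = []
    for k in sorted(set(by_interval_ir) & set(by_interval_rgb)):
        best = min(
            ((ir, rgb) for ir in by_interval_ir[k] for rgb in by_interval_rgb[k]),
            key=lambda pr: (abs(pr[0].timestamp - pr[1].timestamp), pr[1].timestamp),
        )
        pairs.append(best)
    return pairs


def triangulate_rays(ray_a: Ray, ray_b: Ray) -> tuple[np.ndarray, float, float, float]:
    """Closest point between two rays by linear least squares.

    Solves ``min ||(o_a + a*d_a) - (o_b + b*d_b)||`` for the depths
    ``(a, b)`` and returns ``(midpoint, gap, a, b)``.
    """
    A = np.column_stack([ray_a.direction, -ray_b.direction])
    if np.linalg.norm(np.cross(ray_a.direction, ray_b.direction)) < 1e-12:
        raise DegenerateGeometryError("rays are parallel; closest point is not unique")
    rhs = ray_b.origin - ray_a.origin
    (a, b), *_ = np.linalg.lstsq(A, rhs, rcond=None)
    Pa = ray_a.point_at(a)
    Pb = ray_b.point_at(b)
    S = 0.5 * (Pa + Pb)
    d = float(np.linalg.norm(Pa - Pb))
    return S, d, float(a), float(b)


def triangulate_pair(rig: StereoRig, p_ir, p_rgb) -> TriangulatedPoint:
    """Triangulate one IR/RGB pixel correspondence to a 3D pupil point."""
    ray_ir = backproject(rig, p_ir, "ir")
    ray_rgb = backproject(rig, p_rgb, "rgb")
    S, d, a_ir, a_rgb = triangulate_rays(ray_ir, ray_rgb)
    return TriangulatedPoint(S=S, d=d, alpha_ir=a_ir, alpha_rgb=a_rgb)


def triangulate_detections(
    rig: StereoRig,
    pairs: Iterable[tuple[DetectionRecord, DetectionRecord]],
    points: str = "corners+center",
) -> list[TriangulatedPoint]:
    """Triangulate paired detections into 3D samples for the sphere fit.

    By default the top-left, center and bottom-right rectangle points are
    each triangulated as an independent sample; ``points="center"``
    restricts to the centers.
    """
    if points not in ("corners+center", "center"):
        raise ValueError("points must be 'corners+center' or 'center'")
    out = []
    for ir, rgb in pairs:
        if points == "center":
            keys = [(ir.center, rgb.center)]
        else:
            keys = [
                (ir.rect_top_left, rgb.rect_top_left),
                (ir.center, rgb.center),
                (ir.rect_bottom_right, rgb.rect_bottom_right),
            ]
        for p_ir, p_rgb in keys:
            tp = triangulate_pair(rig, p_ir, p_rgb)
            out.append(replace(tp, source_pair=(ir, rgb)))
    return out


def filter_points(
    points: Sequence[TriangulatedPoint],
    gap_max: float = 2.0,
    norm_window: float = 2.0,
) -> list[TriangulatedPoint]:
    """Apply the two stereo-consistency filters, preserving order.

    Keeps points whose ray gap ``d`` is at most ``gap_max`` (mm) and whose
    ray depths lie within ``norm_window`` (mm) of the per-camera median
    depth.  Points with a negative depth (behind a camera) are removed
    before the medians are taken.
    """
    if len(points) == 0:
        raise ValueError("filter_points requires a non-empty input")
    front = [p for p in points if p.alpha_ir > 0 and p.alpha_rgb > 0]
    if not front:
        return []
    med_ir = float(np.median([p.alpha_ir for p in front]))
    med_rgb = float(np.median([p.alpha_rgb for p in front]))
    return [
        p
        for p in front
        if p.d <= gap_max
        and abs(p.alpha_ir - med_ir) <= norm_window
        and abs(p.alpha_rgb - med_rgb) <= norm_window
    ]


def write_detections(records: Iterable[DetectionRecord], path) -> None:
    """Write detection records as CSV (columns: timestamp,camera,x1,y1,x2,y2,cx,cy,score)."""
    rows = [
        {
            "timestamp": r.timestamp,
            "camera": r.camera,
            "x1": r.rect_top_left[0],
            "y1": r.rect_top_left[1],
            "x2": r.rect_bottom_right[0],
            "y2": r.rect_bottom_right[1],
            "cx": r.center[0],
            "cy": r.center[1],
            "score": r.score,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=DETECTION_COLUMNS).to_csv(path, index=False)


def read_detections(path) -> list[DetectionRecord]:
    """Read detection records from the CSV dialect written by :func:`write_detections`."""
    df = pd.read_csv(Path(path))
    missing = set(DETECTION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"detection file missing columns: {sorted(missing)}")
    return [
        DetectionRecord(
            timestamp=float(r.timestamp),
            camera=str(r.camera),
            rect_top_left=(float(r.x1), float(r.y1)),
            rect_bottom_right=(float(r.x2), float(r.y2)),
            center=(float(r.cx), float(r.cy)),
            score=float(r.score),
        )
        for r in df.itertuples()
    ]
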