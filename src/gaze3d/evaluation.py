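"""Comparison metrics and cohort aggregation.

Frame-level metrics: rectangle IoU (Jaccard index), angular gaze error in
degrees, and pixel gaze error in the RGB image plane.  A frame is a *valid
test pair* when the IR pupil was detected and an RGB ground-truth label
exists; metric medians are taken over valid frames only, while detection /
validity / consensus rates are taken over all frames.  Cohort summaries are
medians of per-participant medians.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FramePairEvaluation",
    "SessionSummary",
    "CohortSummary",
    "iou",
    "angular_error",
    "pixel_error",
    "evaluate_session",
    "summarize_cohort",
]

log = logging.getLogger(__name__)

Rect = tuple[tuple[float, float], tuple[float, float]]

METRIC_FIELDS = ("gaze_error_deg", "gaze_error_px", "iou_auto_gt", "iou_dl_gt")


def iou(rect_a: Rect, rect_b: Rect) -> float:
    """Intersection-over-union (Jaccard index) of two axis-aligned rectangles.

    Rectangles are ((x1, y1), (x2, y2)) with the first corner top-left.
    Disjoint rectangles score 0; a zero-area rectangle scores 0 by
    convention (logged).
    """
    (ax1, ay1), (ax2, ay2) = rect_a
    (bx1, by1), (bx2, by2) = rect_b
    area_a = max(0.0, ax2 - ax1) * max(0.0, ay2 - ay1)
    area_b = max(0.0, bx2 - bx1) * max(0.0, by2 - by1)
    if area_a == 0.0 or area_b == 0.0:
        log.debug("zero-area rectangle in IoU; returning 0 by convention")
        return 0.0
    iw = min(ax2, bx2) - max(ax1, bx1)
    ih = min(ay2, by2) - max(ay1, by1)
    if iw <= 0 or ih <= 0:
        return 0.0
    inter = iw * ih
    return inter / (area_a + area_b - inter)


def angular_error(g1, g2) -> float:
    """Angle between two gaze vectors, degrees in [0, 180]; scale invariant."""
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    n1, n2 = np.linalg.norm(g1), np.linalg.norm(g2)
    if n1 == 0 or n2 == 0:
        raise ValueError("gaze vectors must be non-zero")
    cos = np.clip(g1 @ g2 / (n1 * n2), -1.0, 1.0)
    return math.degrees(math.acos(cos))


def pixel_error(p1, p2) -> float:
    """Euclidean distance (px) between two pupil centers in the RGB plane."""
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    return float(np.linalg.norm(p1 - p2))


@dataclass(frozen=True)
class FramePairEvaluation:
    """Per-frame metrics; metric fields are present only when ``valid``."""

    valid: bool
    ir_detected: bool = True
    gaze_error_deg: float | None = None
    gaze_error_px: float | None = None
    iou_auto_gt: float | None = None
    iou_dl_gt: float | None = None
    consensus: bool | None = None  # mapped vs detector rect IoU > 0.5

    def __post_init__(self) -> None:
        if self.valid:
            for name in ("iou_auto_gt", "iou_dl_gt"):
                v = getattr(self, name)
                if v is not None and not 0.0 <= v <= 1.0:
                    raise ValueError(f"{name} must be in [0, 1]")


@dataclass(frozen=True)
class SessionSummary:
    """Medians over valid frames plus whole-session rates (exact fractions)."""

    medians: dict[str, float | None]
    rate_detected_ir: float
    rate_valid_pairs: float
    rate_consensus: float
    n_frames: int
    n_valid: int


@dataclass(frozen=True)
class CohortSummary:
    overall: dict[str, float | None]
    per_session_type: dict[str, dict[str, float | None]]
    rates: dict[str, float]


def _median_or_none(values: Sequence[float]) -> float | None:
    vals = [v for v in values if v is not None]
    return float(np.median(vals)) if vals else None


def evaluate_session(frames: Sequence[FramePairEvaluation]) -> SessionSummary:
    """Median each metric over valid frames; rates over all frames.

    The median (even length: mean of the two central values) filters out
    outlier measurements; with no valid frames all metric medians are None.
    """
    n = len(frames)
    valid = [f for f in frames if f.valid]
    medians = {
        name: _median_or_none([getattr(f, name) for f in valid])
        for name in METRIC_FIELDS
    }
    consensus = [f for f in frames if f.consensus]
    return SessionSummary(
        medians=medians,
        rate_detected_ir=(sum(f.ir_detected for f in frames) / n) if n else 0.0,
        rate_valid_pairs=(len(valid) / n) if n else 0.0,
        rate_consensus=(len(consensus) / n) if n else 0.0,
        n_frames=n,
        n_valid=len(valid),
    )


def summarize_cohort(
    sessions: Mapping[tuple[str, str], SessionSummary]
) -> CohortSummary:
    """Median-of-medians cohort summary.

    ``sessions`` maps ``(participant, session_type)`` to a session summary.
    For each metric, every participant contributes the median of their own
    session medians; the cohort value is the median across participants —
    overall and per session type.
    """
    if not sessions:
        raise ValueError("summarize_cohort needs at least one session")

    def median_of_medians(items: Mapping[tuple[str, str], SessionSummary]) -> dict:
        out = {}
        for name in METRIC_FIELDS:
            per_participant = {}
            for (pid, _stype), summ in items.items():
                v = summ.medians.get(name)
                if v is not None:
                    per_participant.setdefault(pid, []).append(v)
            participant_medians = [float(np.median(v)) for v in per_participant.values()]
            out[name] = _median_or_none(participant_medians)
        return out

    session_types = sorted({stype for (_pid, stype) in sessions})
    per_type = {
        stype: median_of_medians(
            {k: v for k, v in sessions.items() if k[1] == stype}
        )
        for stype in session_types
    }
    total_frames = sum(s.n_frames for s in sessions.values())
    rates = {
        "rate_detected_ir": sum(s.rate_detected_ir * s.n_frames for s in sessions.values())
        / total_frames
        if total_frames
        else 0.0,
        "rate_valid_pairs": sum(s.rate_valid_pairs * s.n_frames for s in sessions.values())
        / total_frames
        if total_frames
        else 0.0,
        "rate_consensus": sum(s.rate_consensus * s.n_frames for s in sessions.values())
        / total_frames
        if total_frames
        else 0.0,
    }
    return CohortSummary(
        overall=median_of_medians(sessions), per_session_type=per_type, rates=rates
    )


def cohort_report(summary: CohortSummary) -> pd.DataFrame:
    """Tabular report: one row overall plus one per session type."""
    rows = [{"session": "all", **{k: summary.overall[k] for k in METRIC_FIELDS}}]
    for stype, med in summary.per_session_type.items():
        rows.append({"session": stype, **{k: med[k] for k in METRIC_FIELDS}})
    return pd.DataFrame(rows)
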