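"""Pluggable pupil-detector contract.

The core pipeline never depends on a trained detector: anything that takes
an eye image (path) plus camera tag and returns at most one
:class:`~gaze3d.triangulation.DetectionRecord` can drive it.  A detection
is emitted only when its confidence clears the acceptance threshold
(default 0.9 for the best-scoring bounding rectangle).

Two implementations are provided:

* :class:`SidecarFixtureDetector` — a noisy oracle for testing: reads the
  exact label sidecar written by the synthetic renderer and perturbs it.
* :class:`ExternalCommandDetector` — subprocess/file contract so trained
  models (heavy CNN stacks) stay out of this package: the command receives
  the image path and must print one JSON detection (or nothing) on stdout.
"""

from __future__ import annotations

import json
import subprocess
from pathlib import Path
from typing import Protocol, runtime_checkable

import numpy as np

from .triangulation import DetectionRecord

__all__ = [
    "SCORE_THRESHOLD",
    "PupilDetector",
    "SidecarFixtureDetector",
    "ExternalCommandDetector",
]

SCORE_THRESHOLD = 0.9


@runtime_checkable
class PupilDetector(Protocol):
    def __call__(self, image_path, camera: str) -> DetectionRecord | None: ...


def _apply_threshold(rec: DetectionRecord | None, threshold: float) -> DetectionRecord | None:
    if rec is None or rec.score < threshold:
        return None
    return rec


class SidecarFixtureDetector:
    """Noisy-oracle detector backed by the renderer's JSON label sidecars.

    Optionally perturbs centers/corners with Gaussian pixel noise and drops
    detections at a configurable miss rate, emulating an imperfect trained
    detector with controlled error statistics.
    """

    def __init__(
        self,
        noise_sigma: float = 0.0,
        miss_rate: float = 0.0,
        score_threshold: float = SCORE_THRESHOLD,
        seed: int = 0,
    ):
        self.noise_sigma = noise_sigma
        self.miss_rate = miss_rate
        self.score_threshold = score_threshold
        self._rng = np.random.default_rng(seed)

    def __call__(self, image_path, camera: str) -> DetectionRecord | None:
        sidecar = Path(image_path).with_suffix(".json")
        if not sidecar.exists():
            return None
        label = json.loads(sidecar.read_text())
        if label.get("camera") != camera:
            return None
        if self._rng.uniform() < self.miss_rate:
            return None
        (x1, y1), (x2, y2) = label["rect"]
        cx, cy = label["center"]
        if self.noise_sigma > 0:
            dx = self._rng.normal(0.0, self.noise_sigma, 6)
            x1, y1, x2, y2, cx, cy = (
                x1 + dx[0], y1 + dx[1], x2 + dx[2], y2 + dx[3], cx + dx[4], cy + dx[5],
            )
            x1, x2 = min(x1, x2), max(x1, x2)
            y1, y2 = min(y1, y2), max(y1, y2)
            cx = min(max(cx, x1), x2)
            cy = min(max(cy, y1), y2)
        rec = DetectionRecord(
            timestamp=float(label["timestamp"]),
            camera=camera,
            rect_top_left=(x1, y1),
            rect_bottom_right=(x2, y2),
            center=(cx, cy),
            score=float(label.get("score", 1.0)),
        )
        return _apply_threshold(rec, self.score_threshold)


class ExternalCommandDetector:
    """Run an external command on each image; parse one JSON detection.

    The command is invoked as ``cmd <image_path> <camera>`` and must print
    either nothing (no detection) or a JSON object with keys
    ``timestamp, x1, y1, x2, y2, cx, cy, score`` on stdout.
    """

    def __init__(self, command: list[str], score_threshold: float = SCORE_THRESHOLD,
                 timeout: float = 30.0):
        self.command = list(command)
        self.score_threshold = score_threshold
        self.timeout = timeout

    def __call__(self, image_path, camera: str) -> DetectionRecord | None:
        proc = subprocess.run(
            [*self.command, str(image_path), camera],
            capture_output=True,
            text=True,
            timeout=self.timeout,
            check=True,
        )
        out = proc.stdout.strip()
        if not out:
            return None
        d = json.loads(out)
        rec = DetectionRecord(
            timestamp=float(d["timestamp"]),
            camera=camera,
            rect_top_left=(float(d["x1"]), float(d["y1"])),
            rect_bottom_right=(float(d["x2"]), float(d["y2"])),
            center=(float(d["cx"]), float(d["cy"])),
            score=float(d.get("score", 1.0)),
        )
        return _apply_threshold(rec, self.score_threshold)
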