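"""Pinhole camera models for the stereo IR+RGB eye-camera rig.

The IR camera frame is the world frame: its center sits at the origin with
identity rotation, and every 3D quantity in the package is expressed in
millimetres in this frame.  The RGB camera is described by its relative pose
``(R, T)`` such that a world point ``X`` projects to ``K_rgb @ (R X + T)``
(homogeneous).  Consequently the RGB camera center is ``-R.T @ T`` and the
world direction of an RGB pixel ``p`` is ``R.T @ K_rgb^-1 @ p``.

Pixel convention: 0-based, origin at the top-left corner, x to the right,
y down.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import yaml

__all__ = [
    "CameraIntrinsics",
    "StereoRig",
    "Ray",
    "CalibrationError",
    "BehindCameraError",
    "load_calibration",
    "save_calibration",
    "backproject",
    "project",
]

Camera = Literal["ir", "rgb"]

_ORTHO_TOL = 1e-6


class CalibrationError(ValueError):
    """Raised for malformed or inconsistent calibration input."""


class BehindCameraError(ValueError):
    """Raised when a 3D point has non-positive depth in the target camera."""


@dataclass(frozen=True)
class CameraIntrinsics:
    """Intrinsic matrix and sensor size of one pinhole camera.

    Parameters
    ----------
    K : (3, 3) array
        Upper-triangular intrinsic matrix in pixels, ``K[2, 2] == 1``.
    image_width, image_height : int
        Sensor size in pixels.
    """

    K: np.ndarray
    image_width: int
    image_height: int

    def __post_init__(self) -> None:
        K = np.asarray(self.K, dtype=float)
        if K.shape != (3, 3):
            raise CalibrationError(f"K must be 3x3, got {K.shape}")
        if not np.isclose(K[2, 2], 1.0):
            raise CalibrationError("K[2,2] must be 1")
        if np.any(np.abs(K[np.tril_indices(3, -1)]) > 1e-9):
            raise CalibrationError("K must be upper-triangular")
        if K[0, 0] <= 0 or K[1, 1] <= 0:
            raise CalibrationError("focal entries must be positive")
        cx, cy = K[0, 2], K[1, 2]
        if not (0 <= cx < self.image_width and 0 <= cy < self.image_height):
            raise CalibrationError("principal point outside image bounds")
        object.__setattr__(self, "K", K)

    @property
    def K_inv(self) -> np.ndarray:
        return np.linalg.inv(self.K)


@dataclass(frozen=True)
class StereoRig:
    """Calibrated IR+RGB stereo pair; the IR frame is the world frame.

    ``R`` and ``T`` map world (IR-frame) coordinates into the RGB camera
    frame: ``X_rgb = R @ X + T``, with ``T`` in millimetres.
    """

    ir: CameraIntrinsics
    rgb: CameraIntrinsics
    R: np.ndarray
    T: np.ndarray
    C_ir: np.ndarray = field(init=False)
    C_rgb: np.ndarray = field(init=False)
    M_rgb: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        R = np.asarray(self.R, dtype=float)
        T = np.asarray(self.T, dtype=float).reshape(3)
        if R.shape != (3, 3):
            raise CalibrationError(f"R must be 3x3, got {R.shape}")
        if np.max(np.abs(R @ R.T - np.eye(3))) > _ORTHO_TOL:
            raise CalibrationError("R is not orthonormal")
        if np.linalg.det(R) < 0:
            raise CalibrationError("R is a reflection (det = -1)")
        object.__setattr__(self, "R", R)
        object.__setattr__(self, "T", T)
        object.__setattr__(self, "C_ir", np.zeros(3))
        object.__setattr__(self, "C_rgb", -R.T @ T)
        object.__setattr__(self, "M_rgb", self.rgb.K @ np.column_stack([R, T]))

    def intrinsics(self, camera: Camera) -> CameraIntrinsics:
        return self.ir if camera == "ir" else self.rgb

    def center(self, camera: Camera) -> np.ndarray:
        return self.C_ir if camera == "ir" else self.C_rgb


@dataclass(frozen=True)
class Ray:
    """Half-line ``origin + alpha * direction`` (mm, world frame)."""

    origin: np.ndarray
    direction: np.ndarray

    def __post_init__(self) -> None:
        o = np.asarray(self.origin, dtype=float).reshape(3)
        d = np.asarray(self.direction, dtype=float).reshape(3)
        n = np.linalg.norm(d)
        if abs(n - 1.0) > 1e-9:
            raise ValueError("ray direction must be unit length")
        object.__setattr__(self, "origin", o)
        object.__setattr__(self, "direction", d)

    def point_at(self, alpha: float) -> np.ndarray:
        return self.origin + alpha * self.direction


def backproject(rig: StereoRig, p, camera: Camera) -> Ray:
    """Back-project pixel ``p = (x, y)`` into a world-frame ray.

    For the IR camera the direction is ``K_ir^-1 @ [x, y, 1]``; for the RGB
    camera it is additionally rotated into the world frame with ``R.T``.
    """
    p = np.asarray(p, dtype=float).reshape(2)
    if not np.all(np.isfinite(p)):
        raise ValueError("pixel coordinates must be finite")
    intr = rig.intrinsics(camera)
    d = intr.K_inv @ np.array([p[0], p[1], 1.0])
    if camera == "rgb":
        d = rig.R.T @ d
    d = d / np.linalg.norm(d)
    return Ray(origin=rig.center(camera), direction=d)


def project(rig: StereoRig, P, camera: Camera) -> np.ndarray:
    """Project a world point ``P`` (mm) to pixel coordinates.

    Uses ``K_ir @ P`` for the IR camera and the full perspective matrix
    ``M_rgb @ [P, 1]`` for the RGB camera, with homogeneous division.
    Raises :class:`BehindCameraError` for non-positive depth.
    """
    P = np.asarray(P, dtype=float).reshape(3)
    if camera == "ir":
        h = rig.ir.K @ P
    else:
        h = rig.M_rgb @ np.append(P, 1.0)
    if h[2] <= 0:
        raise BehindCameraError(
            f"point {P} has non-positive depth {h[2]:.3g} in the {camera} camera"
        )
    return h[:2] / h[2]


def _intr_to_dict(intr: CameraIntrinsics) -> dict:
    return {"K": intr.K.tolist(), "size": [intr.image_width, intr.image_height]}


def _intr_from_dict(d: dict, name: str) -> CameraIntrinsics:
    try:
        K = d["K"]
        w, h = d["size"]
    except (KeyError, TypeError, ValueError) as exc:
        raise CalibrationError(f"calibration section '{name}' malformed: {exc}") from exc
    return CameraIntrinsics(K=np.asarray(K, float), image_width=int(w), image_height=int(h))


def save_calibration(rig: StereoRig, path) -> None:
    """Write a rig to a YAML/JSON calibration file (units: mm)."""
    doc = {
        "units": "mm",
        "ir": _intr_to_dict(rig.ir),
        "rgb": _intr_to_dict(rig.rgb),
        "R": rig.R.tolist(),
        "T": rig.T.tolist(),
    }
    path = Path(path)
    text = (
        json.dumps(doc, indent=2)
        if path.suffix.lower() == ".json"
        else yaml.safe_dump(doc, sort_keys=False)
    )
    path.write_text(text)


def load_calibration(path) -> StereoRig:
    """Load and validate a stereo calibration file (YAML or JSON)."""
    path = Path(path)
    if not path.exists():
        raise CalibrationError(f"calibration file not found: {path}")
    doc = yaml.safe_load(path.read_text())  # YAML is a JSON superset
    if not isinstance(doc, dict):
        raise CalibrationError("calibration file must contain a mapping")
    for key in ("ir", "rgb", "R", "T"):
        if key not in doc:
            raise CalibrationError(f"calibration file missing field '{key}'")
    units = doc.get("units", "mm")
    if units != "mm":
        raise CalibrationError(f"calibration units must be 'mm', got {units!r}")
    return StereoRig(
        ir=_intr_from_dict(doc["ir"], "ir"),
        rgb=_intr_from_dict(doc["rgb"], "rgb"),
        R=np.asarray(doc["R"], float),
        T=np.asarray(doc["T"], float),
    )
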