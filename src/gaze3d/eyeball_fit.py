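"""Robust eyeball-sphere fitting from triangulated pupil points.

The eyeball is modelled as a sphere of fixed radius (12 mm, the adult
population average); only its center is estimated.  Fitting has two phases:

1. *Approximation* — the pupil samples lie on a small cap of the sphere, so
   they are nearly coplanar.  The plane normal is taken from the SVD of the
   centered point cloud and the initial center is the mean point plus the
   radius along the normal (sign chosen away from the cameras, i.e. toward
   larger depth).
2. *Optimization* — a truncated-absolute M-estimator of the center,
   minimizing ``sum_P min(| ||P - C|| - r |, delta)``, run twice with a
   decreasing truncation threshold (default 1 mm then 0.5 mm) so gross
   outliers are first bounded and then effectively ignored.

The estimator is exposed sklearn-style as :class:`EyeballEstimator`.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
import numpy as np
from scipy.optimize import minimize
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .triangulation import DegenerateGeometryError

__all__ = [
    "DEFAULT_EYEBALL_RADIUS_MM",
    "EyeballModel",
    "RobustFitConfig",
    "EyeballEstimator",
    "robust_distance",
    "init_center",
    "refine_center",
    "fit_eyeball",
    "naive_sphere_fit",
    "save_model",
    "load_model",
]

DEFAULT_EYEBALL_RADIUS_MM = 12.0

#: Minimum filtered points accepted for a fit (guards the SVD plane estimate).
MIN_FIT_POINTS = 10


@dataclass(frozen=True)
class EyeballModel:
    """Spherical eyeball: center ``C`` (mm, IR/world frame) and radius ``r``."""

    C: np.ndarray
    r: float = DEFAULT_EYEBALL_RADIUS_MM
    n_points: int | None = None
    fit_residual: float | None = None

    def __post_init__(self) -> None:
        C = np.asarray(self.C, dtype=float).reshape(3)
        if self.r <= 0:
            raise ValueError("eyeball radius must be positive")
        object.__setattr__(self, "C", C)


@dataclass(frozen=True)
class RobustFitConfig:
    """Truncation schedule and stopping rules for the M-estimator passes."""

    deltas: tuple[float, ...] = (1.0, 0.5)
    max_iterations: int = 500
    tolerance: float = 1e-6  # mm

    def __post_init__(self) -> None:
        d = tuple(float(x) for x in self.deltas)
        if not d or any(x <= 0 for x in d) or any(nxt >= prev for prev, nxt in zip(d, d[1:])):
            raise ValueError("deltas must be strictly decreasing and positive")
        object.__setattr__(self, "deltas", d)


def robust_distance(P, C, delta: float, r: float = DEFAULT_EYEBALL_RADIUS_MM) -> float:
    """Truncated absolute distance of ``P`` from the sphere surface.

    ``min(| ||P-C|| - r |, delta)`` — bounded influence for outliers.
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    resid = abs(float(np.linalg.norm(np.asarray(P, float) - np.asarray(C, float))) - r)
    return min(resid, delta)


def _truncated_objective(points: np.ndarray, C: np.ndarray, delta: float, r: float) -> float:
    resid = np.abs(np.linalg.norm(points - C, axis=1) - r)
    return float(np.minimum(resid, delta).sum())


def init_center(points, r: float = DEFAULT_EYEBALL_RADIUS_MM) -> np.ndarray:
    """Plane/SVD initialization of the sphere center.

    The pupil samples approximately span a plane tangent to the sphere;
    the center estimate is ``mean(points) + r * N`` with ``N`` the unit
    normal (smallest right singular vector), signed toward larger depth.
    """
    P = np.asarray(points, dtype=float)
    if P.ndim != 2 or P.shape[1] != 3 or len(P) < 3:
        raise ValueError("init_center needs at least 3 points of dimension 3")
    mean = P.mean(axis=0)
    _, s, Vt = np.linalg.svd(P - mean, full_matrices=False)
    if s[1] < 1e-9:
        raise DegenerateGeometryError("points are collinear; plane normal undefined")
    N = Vt[-1]
    if N[2] < 0:  # cameras look down +z; the center is deeper than the pupils
        N = -N
    return mean + r * N


def refine_center(
    points,
    C0,
    r: float = DEFAULT_EYEBALL_RADIUS_MM,
    delta: float = 1.0,
    config: RobustFitConfig | None = None,
) -> np.ndarray:
    """One M-estimator pass: locally minimize the truncated objective from ``C0``.

    Uses a derivative-free simplex search (the truncation makes the
    objective piecewise smooth).  Returns the best iterate even on
    non-convergence (with a warning).
    """
    config = config or RobustFitConfig()
    P = np.asarray(points, dtype=float)
    if len(P) < 4:
        raise ValueError("refine_center needs at least 4 points")
    C0 = np.asarray(C0, dtype=float).reshape(3)
    res = minimize(
        lambda c: _truncated_objective(P, c, delta, r),
        C0,
        method="Nelder-Mead",
        options={
            "xatol": config.tolerance,
            "fatol": 1e-9,
            "maxiter": config.max_iterations,
            "maxfev": 4 * config.max_iterations,
        },
    )
    if not res.success:
        warnings.warn(
            f"M-estimator pass (delta={delta}) did not converge in "
            f"{config.max_iterations} iterations; returning best iterate",
            RuntimeWarning,
            stacklevel=2,
        )
    # Nelder-Mead never moves uphill from the start simplex's best vertex,
    # but guard the contract explicitly.
    if _truncated_objective(P, res.x, delta, r) <= _truncated_objective(P, C0, delta, r):
        return np.asarray(res.x, dtype=float)
    return C0


class EyeballEstimator(BaseEstimator):
    """Sklearn-style robust sphere-center estimator at fixed radius.

    Parameters
    ----------
    r : float
        Sphere radius in mm (never re-estimated; override only for
        sensitivity analysis).
    deltas : tuple of float
        Decreasing truncation thresholds for the M-estimator passes, mm.
    max_iterations, tolerance :
        Stopping rules per pass (simplex iterations; center motion in mm).

    Attributes
    ----------
    center_ : (3,) ndarray
        Fitted sphere center, mm, world frame.
    init_center_ : (3,) ndarray
        Plane/SVD initialization the refinement started from.
    n_points_ : int
        Number of samples used.
    residual_ : float
        Mean absolute surface residual (untruncated) at the fitted center.
    """

    def __init__(
        self,
        r: float = DEFAULT_EYEBALL_RADIUS_MM,
        deltas: tuple[float, ...] = (1.0, 0.5),
        max_iterations: int = 500,
        tolerance: float = 1e-6,
        min_points: int = MIN_FIT_POINTS,
    ):
        self.r = r
        self.deltas = deltas
        self.max_iterations = max_iterations
        self.tolerance = tolerance
        self.min_points = min_points

    def fit(self, X, y=None) -> "EyeballEstimator":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 3:
            raise ValueError("X must be an (n, 3) array of 3D points in mm")
        if len(X) < self.min_points:
            raise ValueError(
                f"refusing to fit on {len(X)} points (< {self.min_points}); "
                "too few for a stable plane estimate"
            )
        config = RobustFitConfig(
            deltas=self.deltas,
            max_iterations=self.max_iterations,
            tolerance=self.tolerance,
        )
        C = init_center(X, self.r)
        self.init_center_ = C.copy()
        for delta in config.deltas:
            C = refine_center(X, C, self.r, delta, config)
        self.center_ = C
        self.n_points_ = len(X)
        self.residual_ = float(np.mean(np.abs(np.linalg.norm(X - C, axis=1) - self.r)))
        return self

    def score(self, X, y=None) -> float:
        """Negative truncated objective at the smallest delta (higher is better)."""
        check_is_fitted(self, "center_")
        X = np.asarray(X, dtype=float)
        return -_truncated_objective(X, self.center_, min(self.deltas), self.r)

    @property
    def model_(self) -> EyeballModel:
        check_is_fitted(self, "center_")
        return EyeballModel(
            C=self.center_, r=self.r, n_points=self.n_points_, fit_residual=self.residual_
        )


def fit_eyeball(
    points,
    r: float = DEFAULT_EYEBALL_RADIUS_MM,
    config: RobustFitConfig | None = None,
) -> EyeballModel:
    """Fit the eyeball sphere: plane/SVD init, then M-estimator passes."""
    config = config or RobustFitConfig()
    est = EyeballEstimator(
        r=r,
        deltas=config.deltas,
        max_iterations=config.max_iterations,
        tolerance=config.tolerance,
    ).fit(np.asarray(points, dtype=float))
    return est.model_


def naive_sphere_fit(points, r: float = DEFAULT_EYEBALL_RADIUS_MM) -> np.ndarray:
    """Unrobust least-squares sphere center at fixed radius (baseline only).

    Minimizes ``sum (||P - C|| - r)^2`` from the same SVD initialization,
    with no truncation and no outlier handling.
    """
    P = np.asarray(points, dtype=float)
    C0 = init_center(P, r)
    res = minimize(
        lambda c: float(((np.linalg.norm(P - c, axis=1) - r) ** 2).sum()),
        C0,
        method="Nelder-Mead",
        options={"xatol": 1e-8, "fatol": 1e-12, "maxiter": 2000, "maxfev": 8000},
    )
    return np.asarray(res.x, dtype=float)


def save_model(model: EyeballModel, path) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "C": model.C.tolist(),
                "r": model.r,
                "units": "mm",
                "n_points": model.n_points,
                "fit_residual": model.fit_residual,
            },
            indent=2,
        )
    )


def load_model(path) -> EyeballModel:
    doc = json.loads(Path(path).read_text())
    if doc.get("units", "mm") != "mm":
        raise ValueError("model units must be mm")
    return EyeballModel(
        C=np.asarray(doc["C"], float),
        r=float(doc["r"]),
        n_points=doc.get("n_points"),
        fit_residual=doc.get("fit_residual"),
    )
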