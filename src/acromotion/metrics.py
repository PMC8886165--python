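"""Per-phase subacromial metrics: minimal vertical AHD, rotation radius and angle.

During one abduction or adduction phase the greater tuberosity travels an
approximately circular arc about the humeral-head rotation centre.  Fitting
a circle to the relative-trajectory samples of the phase, by minimising the
geometric cost

    F(xc, yc, rc) = sum_i (r_i - rc)^2,     r_i = sqrt((x_i-xc)^2 + (y_i-yc)^2),

yields the rotation radius ``rc``.  The rotation angle ``theta`` is the
angle subtended at the fitted centre by the leftmost and rightmost observed
trajectory points.  The minimal vertical acromiohumeral distance of the
phase is the minimum of the vertical separation y over the phase's frames.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .exceptions import DegenerateGeometryError, ZeroArcError
from .landmarks import RelativeTrajectory
from .phases import PhaseSegment

__all__ = [
    "CircleFitResult",
    "RotationResult",
    "PhaseMetrics",
    "fit_circle",
    "rotation_angle",
    "min_vertical_ahd",
    "compute_phase_metrics",
    "average_by_direction",
]

#: Gauss-Newton stop: relative cost change below this, or iteration cap.
FIT_FTOL = 1e-10
FIT_MAX_ITER = 100


@dataclass(frozen=True)
class CircleFitResult:
    """Least-squares circle: centre (xc, yc), radius rc, residual cost F (cm^2)."""

    xc: float
    yc: float
    rc: float
    cost: float
    n_points: int
    converged: bool


@dataclass(frozen=True)
class RotationResult:
    """Rotation angle of the humeral head over one phase.

    ``theta`` (degrees) is the angle at the fitted circle centre between the
    leftmost and rightmost observed points.  Angles at or above 90 degrees
    violate the model's small-arc assumption and are flagged via
    ``exceeds_90`` but still reported.
    """

    theta: float
    endpoint_left: tuple[float, float]
    endpoint_right: tuple[float, float]
    exceeds_90: bool


@dataclass(frozen=True)
class PhaseMetrics:
    """All metrics for one abduction/adduction phase."""

    direction: str
    cycle: int
    min_vertical_ahd: float
    rotation: RotationResult
    fit: CircleFitResult
    ahd_clipped: bool = False


def _kasa_init(pts: np.ndarray) -> tuple[float, float, float]:
    """Algebraic (Kasa) circle fit: linear least squares on
    x^2 + y^2 + D x + E y + F = 0; used to initialise the geometric fit."""
    x, y = pts[:, 0], pts[:, 1]
    A = np.column_stack([x, y, np.ones_like(x)])
    b = -(x**2 + y**2)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    D, E, F = sol
    xc, yc = -D / 2, -E / 2
    rc2 = xc**2 + yc**2 - F
    rc = float(np.sqrt(max(rc2, 0.0)))
    return float(xc), float(yc), rc


def fit_circle(points: np.ndarray) -> CircleFitResult:
    """Fit a circle to 2-D points by minimising the geometric cost F.

    An algebraic Kasa fit provides the starting point; Gauss-Newton
    refinement (Levenberg-Marquardt) of the radial residuals r_i - rc then
    minimises F itself.  Convergence is declared when the relative cost
    change falls below ``FIT_FTOL`` within ``FIT_MAX_ITER`` iterations;
    otherwise the best iterate is returned with ``converged=False`` and a
    warning.

    Raises
    ------
    DegenerateGeometryError
        For fewer than 3 distinct points or (near-)collinear geometry,
        where no finite circle is identified.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array")
    if not np.all(np.isfinite(pts)):
        raise ValueError("points must be finite")
    distinct = np.unique(pts, axis=0)
    if distinct.shape[0] < 3:
        raise DegenerateGeometryError(
            f"need >= 3 distinct points, got {distinct.shape[0]}"
        )
    centered = pts - pts.mean(axis=0)
    sv = np.linalg.svd(centered, compute_uv=False)
    if sv[1] <= 1e-9 * sv[0]:
        raise DegenerateGeometryError("points are collinear; no unique circle")

    x0 = np.array(_kasa_init(pts))
    if x0[2] <= 0:
        x0[2] = float(np.mean(np.linalg.norm(centered, axis=1)))

    def resid(p):
        return np.hypot(pts[:, 0] - p[0], pts[:, 1] - p[1]) - p[2]

    res = least_squares(
        resid,
        x0,
        method="lm",
        ftol=FIT_FTOL,
        xtol=1e-14,
        gtol=1e-14,
        max_nfev=FIT_MAX_ITER * 4,
    )
    converged = res.status > 0
    if not converged:
        warnings.warn(
            "circle fit did not converge within the iteration cap; "
            "returning best iterate",
            stacklevel=2,
        )
    xc, yc, rc = res.x
    cost = float(np.sum(resid(res.x) ** 2))
    return CircleFitResult(
        xc=float(xc),
        yc=float(yc),
        rc=float(abs(rc)),
        cost=cost,
        n_points=pts.shape[0],
        converged=bool(converged),
    )


def rotation_angle(fit: CircleFitResult, points: np.ndarray) -> RotationResult:
    """Angle subtended at the fitted centre by the extreme trajectory points.

    (x1, y1) is the observed point with the smallest X and (x2, y2) the one
    with the largest X (ties resolved to the earliest frame);

        theta = arccos[ ((x1-xc)(x2-xc) + (y1-yc)(y2-yc))
                        / (|(x1,y1)-(xc,yc)| * |(x2,y2)-(xc,yc)|) ]

    in degrees.  Values >= 90 degrees are flagged, with a warning, but
    reported unchanged.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
        raise ValueError("points must be an (n>=2, 2) array")
    i_left = int(np.argmin(pts[:, 0]))   # argmin/argmax take the earliest tie
    i_right = int(np.argmax(pts[:, 0]))
    p1, p2 = pts[i_left], pts[i_right]
    if np.allclose(p1, p2):
        raise ZeroArcError("leftmost and rightmost points coincide; no arc swept")
    c = np.array([fit.xc, fit.yc])
    v1, v2 = p1 - c, p2 - c
    cos_t = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    theta = float(np.degrees(np.arccos(np.clip(cos_t, -1.0, 1.0))))
    exceeds = theta >= 90.0
    if exceeds:
        warnings.warn(
            f"rotation angle {theta:.2f} deg >= 90 deg exceeds the model's "
            "assumed range; reported unchanged",
            stacklevel=2,
        )
    return RotationResult(
        theta=theta,
        endpoint_left=(float(p1[0]), float(p1[1])),
        endpoint_right=(float(p2[0]), float(p2[1])),
        exceeds_90=bool(exceeds),
    )


def min_vertical_ahd(traj: RelativeTrajectory, seg: PhaseSegment) -> float:
    """Minimal vertical acromiohumeral distance (cm) over the segment.

    Negative vertical separations (greater tuberosity annotated above the
    acromial edge — physically implausible, usually a labelling slip) are
    clipped to zero with a warning before taking the minimum.
    """
    if not (0 <= seg.start_index < seg.end_index < traj.n):
        raise ValueError("segment out of trajectory bounds")
    y = traj.y[seg.start_index : seg.end_index + 1]
    if np.any(y < 0):
        warnings.warn(
            f"{int((y < 0).sum())} negative vertical separation(s) in "
            f"{seg.direction} cycle {seg.cycle}; clipped to 0",
            stacklevel=2,
        )
        y = np.maximum(y, 0.0)
    return float(np.min(y))


def compute_phase_metrics(
    traj: RelativeTrajectory, segments: list[PhaseSegment]
) -> list[PhaseMetrics]:
    """Fit a separate circle per phase and collect all per-phase metrics."""
    out = []
    for seg in segments:
        pts = traj.points(seg.start_index, seg.end_index + 1)
        y_seg = traj.y[seg.start_index : seg.end_index + 1]
        clipped = bool(np.any(y_seg < 0))
        fit = fit_circle(pts)
        rot = rotation_angle(fit, pts)
        ahd = min_vertical_ahd(traj, seg)
        out.append(
            PhaseMetrics(
                direction=seg.direction,
                cycle=seg.cycle,
                min_vertical_ahd=ahd,
                rotation=rot,
                fit=fit,
                ahd_clipped=clipped,
            )
        )
    return out


def average_by_direction(metrics: list[PhaseMetrics]) -> dict[str, dict[str, float]]:
    """Arithmetic mean of per-phase metrics over the retained cycles,
    separately for the abduction and adduction directions.

    A direction with no phases is omitted with a warning.
    """
    out: dict[str, dict[str, float]] = {}
    for direction in ("abduction", "adduction"):
        group = [m for m in metrics if m.direction == direction]
        if not group:
            warnings.warn(f"no {direction} phases present; omitted from averages",
                          stacklevel=2)
            continue
        out[direction] = {
            "min_vertical_ahd": float(np.mean([m.min_vertical_ahd for m in group])),
            "radius": float(np.mean([m.fit.rc for m in group])),
            "theta": float(np.mean([m.rotation.theta for m in group])),
            "n_phases": len(group),
        }
    return out
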