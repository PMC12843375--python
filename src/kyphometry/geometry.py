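"""Circle-fit kyphosis geometry.

The thoracic spine seen on a lateral scan approximates a circular arc.  Given
the centroids of the nine thoracic vertebrae Th4–Th12, the kyphosis angle is
estimated in three steps:

1. fit a least-squares circle through the centroids,
2. take the central angle θ subtended at the circle center by the radii to
   the Th4 and Th12 centroids,
3. convert θ to a Cobb-equivalent angle as the angle between the tangents to
   the circle at the two endpoints (for points exactly on the circle the
   tangent–tangent angle equals θ).

Scans with missing levels, a degenerate (collinear) centroid chain, or a
chain that is not convex toward the fitted arc are flagged as unsuitable for
automated analysis rather than measured — mirroring a referral-to-manual
quality-control workflow.

Coordinates follow the image convention: origin top-left, x to the right,
y increasing caudally.  All angle computations are invariant to translation,
rotation, reflection and uniform scaling of the input.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Literal, NamedTuple, Sequence

import numpy as np
from scipy.optimize import least_squares

from .errors import (
    CollinearPointsError,
    DegenerateAngleError,
    InsufficientPointsError,
)

__all__ = [
    "Point2D",
    "VertebraLevel",
    "CentroidObservation",
    "VertebralCentroidSet",
    "FittedCircle",
    "MeasurementConfig",
    "KyphosisMeasurement",
    "fit_circle",
    "central_angle",
    "cobb_from_tangents",
    "measure_kyphosis",
    "classify_kyphosis",
    "THORACIC_LEVELS",
]

FitMethod = Literal["algebraic", "geometric-refined"]


class Point2D(NamedTuple):
    """A planar point; units (px or mm) are consistent within one scan."""

    x: float
    y: float

    def is_finite(self) -> bool:
        return math.isfinite(self.x) and math.isfinite(self.y)


class VertebraLevel(enum.IntEnum):
    """Thoracic vertebral levels Th4 (cranial) through Th12 (caudal).

    The integer value is the anatomical level number, so the natural integer
    order is the cranial-to-caudal order.
    """

    TH4 = 4
    TH5 = 5
    TH6 = 6
    TH7 = 7
    TH8 = 8
    TH9 = 9
    TH10 = 10
    TH11 = 11
    TH12 = 12

    @property
    def label(self) -> str:
        return f"Th{self.value}"

    @classmethod
    def parse(cls, text: str) -> "VertebraLevel":
        t = str(text).strip().lower()
        if t.startswith("th"):
            t = t[2:]
        try:
            return cls(int(t))
        except ValueError as exc:
            raise ValueError(f"unknown vertebral level: {text!r}") from exc


#: The nine levels used for curvature estimation, cranial to caudal.
THORACIC_LEVELS: tuple[VertebraLevel, ...] = tuple(VertebraLevel)


class CentroidObservation(NamedTuple):
    point: Point2D
    confidence: float


@dataclass
class VertebralCentroidSet:
    """Ordered Th4→Th12 vertebral centroids with per-level confidence.

    At most one entry per level; iteration is always cranial → caudal
    regardless of insertion order.
    """

    scan_id: str = ""
    units: Literal["px", "mm"] = "px"
    entries: dict[VertebraLevel, CentroidObservation] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.entries = {
            lvl: self.entries[lvl] for lvl in sorted(self.entries)
        }

    def add(self, level: VertebraLevel, point: Point2D, confidence: float = 1.0) -> None:
        if level in self.entries:
            raise ValueError(f"duplicate centroid for level {level.label}")
        self.entries[level] = CentroidObservation(Point2D(*point), float(confidence))
        self.entries = {lvl: self.entries[lvl] for lvl in sorted(self.entries)}

    def levels(self) -> list[VertebraLevel]:
        return sorted(self.entries)

    def points(self) -> list[Point2D]:
        return [self.entries[lvl].point for lvl in sorted(self.entries)]

    def missing_levels(self) -> list[VertebraLevel]:
        return [lvl for lvl in THORACIC_LEVELS if lvl not in self.entries]

    def complete(self) -> bool:
        return not self.missing_levels()

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(sorted(self.entries))


@dataclass(frozen=True)
class FittedCircle:
    """Least-squares circle through a point set.

    ``rms_residual`` is the root-mean-square of the radial residuals
    ``|dist(point, center) - radius|``.
    """

    center: Point2D
    radius: float
    rms_residual: float
    n_points: int

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise ValueError("radius must be positive")
        if self.rms_residual < 0:
            raise ValueError("rms_residual must be non-negative")
        if self.n_points < 3:
            raise ValueError("a circle fit needs at least 3 points")


@dataclass(frozen=True)
class MeasurementConfig:
    """Tunables for :func:`measure_kyphosis`.

    collinearity_tol is the relative singular-value ratio below which the
    centroid chain is declared degenerate (scale-free test).
    """

    fit_method: FitMethod = "algebraic"
    collinearity_tol: float = 1e-10
    threshold_deg: float = 40.0


@dataclass(frozen=True)
class KyphosisMeasurement:
    """Result of the automated kyphosis measurement on one scan.

    When ``qc_flag == "unsuitable"`` the angle fields are ``None`` and the
    scan should be referred for manual measurement.
    """

    scan_id: str
    qc_flag: Literal["ok", "unsuitable"]
    qc_reason: str = ""
    central_angle_deg: float | None = None
    cobb_equiv_deg: float | None = None
    levels_used: tuple[VertebraLevel, ...] = ()
    circle: FittedCircle | None = None


def _as_array(points: Sequence[Point2D] | np.ndarray) -> np.ndarray:
    arr = np.asarray(points, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array-like")
    if not np.all(np.isfinite(arr)):
        raise ValueError("points contain non-finite coordinates")
    return arr


def _check_collinear(arr: np.ndarray, tol: float = 1e-10) -> None:
    centered = arr - arr.mean(axis=0)
    sv = np.linalg.svd(centered, compute_uv=False)
    if sv[0] == 0.0 or sv[-1] <= tol * sv[0]:
        raise CollinearPointsError(
            "points are collinear within tolerance; circle fit is degenerate"
        )


def fit_circle(
    points: Sequence[Point2D] | np.ndarray,
    method: FitMethod = "algebraic",
    collinearity_tol: float = 1e-10,
) -> FittedCircle:
    """Least-squares circle through ``points``.

    ``method="algebraic"`` is the Kåsa linearized fit: with coordinates
    centered on the data mean, solve the linear system
    ``2*a*x + 2*b*y + c = x**2 + y**2`` for the center ``(a, b)`` and
    ``r = sqrt(c + a**2 + b**2)``.  It is closed-form, deterministic and
    exact whenever the points lie exactly on one circle.

    ``method="geometric-refined"`` additionally minimizes the sum of squared
    radial residuals ``sum((dist_i - r)**2)`` with Levenberg–Marquardt,
    seeded by the algebraic solution.

    Raises
    ------
    InsufficientPointsError
        for fewer than 3 points.
    CollinearPointsError
        when the points are collinear within ``collinearity_tol`` (relative
        smallest singular value of the centered coordinates).
    """
    arr = _as_array(points)
    if arr.shape[0] < 3:
        raise InsufficientPointsError(
            f"circle fit needs at least 3 points, got {arr.shape[0]}"
        )
    _check_collinear(arr, collinearity_tol)

    mean = arr.mean(axis=0)
    u = arr - mean
    # Kåsa: linear least squares in (a, b, c)
    A = np.column_stack([2.0 * u[:, 0], 2.0 * u[:, 1], np.ones(len(u))])
    rhs = (u ** 2).sum(axis=1)
    (a, b, c), *_ = np.linalg.lstsq(A, rhs, rcond=None)
    r = math.sqrt(max(c + a * a + b * b, 0.0))
    cx, cy = a + mean[0], b + mean[1]

    if method == "geometric-refined":

        def radial_residuals(p: np.ndarray) -> np.ndarray:
            d = np.hypot(arr[:, 0] - p[0], arr[:, 1] - p[1])
            return d - p[2]

        sol = least_squares(
            radial_residuals, x0=np.array([cx, cy, r]), method="lm", xtol=1e-14,
            ftol=1e-14, gtol=1e-14,
        )
        cx, cy, r = sol.x
    elif method != "algebraic":
        raise ValueError(f"unknown fit method: {method!r}")

    dists = np.hypot(arr[:, 0] - cx, arr[:, 1] - cy)
    rms = float(np.sqrt(np.mean((dists - r) ** 2)))
    return FittedCircle(
        center=Point2D(float(cx), float(cy)),
        radius=float(r),
        rms_residual=rms,
        n_points=int(arr.shape[0]),
    )


def _radius_vector(circle: FittedCircle, p: Point2D) -> np.ndarray:
    v = np.array([p[0] - circle.center.x, p[1] - circle.center.y], dtype=float)
    norm = float(np.hypot(*v))
    if norm <= 1e-12 * circle.radius:
        raise DegenerateAngleError("endpoint coincides with the circle center")
    return v


def central_angle(circle: FittedCircle, p_start: Point2D, p_end: Point2D) -> float:
    """Central angle θ (degrees, minor arc, in [0, 180]) subtended at the
    circle center by the radii to ``p_start`` and ``p_end``.

    For points exactly on the circle this equals
    ``2*arcsin(chord / (2*radius))``.
    """
    if tuple(p_start) == tuple(p_end):
        raise DegenerateAngleError("angle endpoints coincide")
    u = _radius_vector(circle, p_start)
    v = _radius_vector(circle, p_end)
    cross = abs(u[0] * v[1] - u[1] * v[0])
    dot = float(u @ v)
    return math.degrees(math.atan2(cross, dot))


def cobb_from_tangents(circle: FittedCircle, p_start: Point2D, p_end: Point2D) -> float:
    """Cobb-equivalent angle (degrees, in [0, 180]) between the tangents to
    the fitted circle at the two endpoints.

    The endpoints are first projected radially onto the circle; the tangent
    at each projection is perpendicular to its radius.  For endpoints on one
    circle the tangent–tangent angle equals the central angle; antipodal
    endpoints (parallel tangents) return 180.
    """
    if tuple(p_start) == tuple(p_end):
        raise DegenerateAngleError("angle endpoints coincide")
    u = _radius_vector(circle, p_start)
    v = _radius_vector(circle, p_end)
    # Tangent direction = radius rotated by +90 degrees (consistent sense so
    # the directed angle between tangents equals the central angle).
    tu = np.array([-u[1], u[0]]) / np.hypot(*u)
    tv = np.array([-v[1], v[0]]) / np.hypot(*v)
    cross = abs(tu[0] * tv[1] - tu[1] * tv[0])
    dot = float(tu @ tv)
    return math.degrees(math.atan2(cross, dot))


def _cross2(a: np.ndarray, b: np.ndarray) -> float:
    return float(a[0] * b[1] - a[1] * b[0])


def _chain_convex_toward_arc(
    circle: FittedCircle, points: Sequence[Point2D]
) -> bool:
    """True when all interior centroids lie on the same side of the
    start–end chord as the minor arc's midpoint."""
    p0 = np.asarray(points[0], dtype=float)
    p1 = np.asarray(points[-1], dtype=float)
    chord = p1 - p0
    c = np.array([circle.center.x, circle.center.y])
    mid = 0.5 * (p0 + p1)
    out = mid - c
    norm = float(np.hypot(*out))
    if norm <= 1e-12 * circle.radius:
        # chord is a diameter: require all interior points on one side
        sides = [
            math.copysign(1.0, _cross2(chord, np.asarray(p, dtype=float) - p0))
            for p in points[1:-1]
        ]
        return abs(sum(sides)) == len(sides)
    arc_mid = c + circle.radius * out / norm
    ref_side = _cross2(chord, arc_mid - p0)
    for p in points[1:-1]:
        s = _cross2(chord, np.asarray(p, dtype=float) - p0)
        if s * ref_side < 0:
            return False
    return True


def measure_kyphosis(
    centroids: VertebralCentroidSet,
    config: MeasurementConfig | None = None,
) -> KyphosisMeasurement:
    """Automated kyphosis measurement with quality control.

    Requires all nine levels Th4–Th12.  Fits the circle through all nine
    centroids, reports the central angle θ between the raw Th4 and Th12
    centroids and the Cobb-equivalent tangent angle.  Incomplete sets,
    collinear chains and chains not convex toward the fitted arc yield
    ``qc_flag="unsuitable"`` with a reason — never an exception — so the scan
    can be referred for manual measurement.
    """
    cfg = config or MeasurementConfig()
    missing = centroids.missing_levels()
    if missing:
        return KyphosisMeasurement(
            scan_id=centroids.scan_id,
            qc_flag="unsuitable",
            qc_reason="missing levels: " + ", ".join(l.label for l in missing),
        )
    points = centroids.points()
    try:
        circle = fit_circle(points, cfg.fit_method, cfg.collinearity_tol)
    except CollinearPointsError:
        return KyphosisMeasurement(
            scan_id=centroids.scan_id,
            qc_flag="unsuitable",
            qc_reason="collinear centroids (degenerate circle fit)",
        )
    except (InsufficientPointsError, ValueError) as exc:
        return KyphosisMeasurement(
            scan_id=centroids.scan_id,
            qc_flag="unsuitable",
            qc_reason=f"invalid centroid geometry: {exc}",
        )
    if not _chain_convex_toward_arc(circle, points):
        return KyphosisMeasurement(
            scan_id=centroids.scan_id,
            qc_flag="unsuitable",
            qc_reason="geometry-inconsistent chain: interior centroids not "
            "convex toward the fitted arc",
            circle=circle,
        )
    try:
        theta = central_angle(circle, points[0], points[-1])
        cobb = cobb_from_tangents(circle, points[0], points[-1])
    except DegenerateAngleError as exc:
        return KyphosisMeasurement(
            scan_id=centroids.scan_id,
            qc_flag="unsuitable",
            qc_reason=f"degenerate endpoint geometry: {exc}",
            circle=circle,
        )
    return KyphosisMeasurement(
        scan_id=centroids.scan_id,
        qc_flag="ok",
        central_angle_deg=theta,
        cobb_equiv_deg=cobb,
        levels_used=tuple(centroids.levels()),
        circle=circle,
    )


def classify_kyphosis(
    angle_deg: float, threshold_deg: float = 40.0
) -> Literal["significant", "not_significant"]:
    """Clinically significant kyphosis is an angle at or above the threshold
    (default 40°); the boundary is inclusive."""
    if not math.isfinite(angle_deg):
        raise ValueError("angle must be finite")
    return "significant" if angle_deg >= threshold_deg else "not_significant"
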