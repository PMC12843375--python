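"""Synthetic spine phantoms with known ground truth.

Clinical lateral DEXA images cannot be redistributed, so every downstream
stage (geometry, detection, agreement statistics) is exercised on synthetic
spines instead.  A phantom is a circular arc of known central angle carrying
nine vertebral centroids at equal angular steps; around it the module can
generate

* noisy "detected" centroids (Gaussian positional noise, per-level dropout),
* a raster rendering — bright rotated vertebral bodies on a dark background,
  Gaussian-blurred with additive noise, values in [0, 1] — plus ground-truth
  bounding boxes,
* two simulated manual observers measuring the Cobb angle with bias and
  noise, resolved by a consensus rule when they disagree by more than 2°,
* whole cohorts of paired (true, automated, manual) angles.

Everything is deterministic given the seed: a single ``SeedSequence`` fans
out into independent streams for centroid noise, rendering noise and the two
observers, so adding one stage never perturbs another.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from shapely.geometry import Polygon
from skimage.draw import polygon as draw_polygon
from skimage.filters import gaussian as gaussian_blur

from .detection import BoundingBox
from .errors import SpecError
from .geometry import (
    THORACIC_LEVELS,
    MeasurementConfig,
    Point2D,
    VertebraLevel,
    VertebralCentroidSet,
    measure_kyphosis,
)

__all__ = [
    "PhantomSpec",
    "ObserverModel",
    "GroundTruth",
    "make_centroids",
    "render_phantom",
    "simulate_manual_cobb",
    "make_cohort",
]

#: Geometric validity bounds (degrees) for sampled true angles.
ANGLE_BOUNDS = (5.0, 120.0)


@dataclass(frozen=True)
class PhantomSpec:
    """Generative parameters for one synthetic spine.

    The nine true centroids span exactly ``true_central_angle_deg`` on a
    circle of ``radius`` pixels, centered in the image with the arc convex
    toward the image left (the anterior side on a standard lateral view).
    ``vertebra_size`` is (extent along the arc tangent, extent along the
    radius) of the rendered vertebral body; the long axis lies tangent to
    the arc.
    """

    true_central_angle_deg: float = 45.3
    radius: float = 300.0
    n_levels: int = 9
    start_level: VertebraLevel = VertebraLevel.TH4
    centroid_noise_sd: float = 1.0
    dropout_prob: float | Mapping[VertebraLevel, float] = 0.0
    image_size: tuple[int, int] = (640, 640)  # (width, height)
    vertebra_size: tuple[float, float] | None = None
    background_noise_sd: float = 0.02
    blur_sigma: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 < self.true_central_angle_deg < 180.0:
            raise SpecError("true central angle must lie in (0, 180) degrees")
        if self.radius <= 0:
            raise SpecError("radius must be positive")
        if not 0 <= self.n_levels <= len(THORACIC_LEVELS):
            raise SpecError("n_levels must be between 0 and 9")
        for name in ("centroid_noise_sd", "background_noise_sd", "blur_sigma"):
            if getattr(self, name) < 0:
                raise SpecError(f"{name} must be non-negative")
        for p in self._dropout_map().values():
            if not 0.0 <= p <= 1.0:
                raise SpecError("dropout probabilities must lie in [0, 1]")
        if self.vertebra_size is not None and min(self.vertebra_size) <= 0:
            raise SpecError("vertebra_size must be positive")

    def effective_vertebra_size(self) -> tuple[float, float]:
        """Rendered body size: the explicit ``vertebra_size`` if given, else
        scaled to the arc spacing so bodies never overlap — the body spans
        70% of the centroid-to-centroid arc step (the vertebra share of the
        vertebra+disc unit), with a 0.6 short/long aspect ratio."""
        if self.vertebra_size is not None:
            return self.vertebra_size
        if self.n_levels > 1:
            step = self.radius * math.radians(self.true_central_angle_deg) / (
                self.n_levels - 1
            )
        else:
            step = 30.0
        long_axis = 0.7 * step
        return (long_axis, 0.6 * long_axis)

    def levels(self) -> tuple[VertebraLevel, ...]:
        start = THORACIC_LEVELS.index(self.start_level)
        return THORACIC_LEVELS[start : start + self.n_levels]

    def _dropout_map(self) -> dict[VertebraLevel, float]:
        if isinstance(self.dropout_prob, Mapping):
            return {lvl: float(self.dropout_prob.get(lvl, 0.0)) for lvl in self.levels()}
        return {lvl: float(self.dropout_prob) for lvl in self.levels()}


@dataclass(frozen=True)
class ObserverModel:
    """A simulated physician reading the Cobb angle: systematic bias plus
    zero-mean Gaussian reading noise."""

    bias_deg: float = 0.0
    noise_sd_deg: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd_deg < 0:
            raise ValueError("noise_sd_deg must be non-negative")


@dataclass
class GroundTruth:
    """Pre-noise truth for one phantom: the true angle, the exact centroid
    chain, the rendered-body polygons and their axis-aligned hull boxes."""

    true_angle_deg: float
    true_centroids: VertebralCentroidSet
    true_boxes: list[BoundingBox]
    body_polygons: list[np.ndarray] = field(default_factory=list, repr=False)


def _arc_geometry(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """True centroid positions, tangent unit vectors and radial unit vectors
    for the spec's arc (arrays of shape (n_levels, 2))."""
    w, h = spec.image_size
    theta = math.radians(spec.true_central_angle_deg)
    r = spec.radius
    # arc bulges toward image left; center the arc's bounding box
    cx = w / 2.0 + r * (1.0 + math.cos(theta / 2.0)) / 2.0
    cy = h / 2.0
    n = spec.n_levels
    if n == 0:
        return np.empty((0, 2)), np.empty((0, 2)), np.empty((0, 2))
    if n == 1:
        phis = np.array([math.pi])
    else:
        # Th4 (cranial, smaller y) at pi + theta/2, Th12 at pi - theta/2
        phis = math.pi + theta / 2.0 - np.arange(n) * theta / (n - 1)
    pts = np.column_stack([cx + r * np.cos(phis), cy + r * np.sin(phis)])
    radial = np.column_stack([np.cos(phis), np.sin(phis)])
    tangent = np.column_stack([np.sin(phis), -np.cos(phis)])
    return pts, tangent, radial


def _body_corners(
    pts: np.ndarray, tangent: np.ndarray, radial: np.ndarray, size: tuple[float, float]
) -> list[np.ndarray]:
    long_half, short_half = size[0] / 2.0, size[1] / 2.0
    corners = []
    for p, t, rdir in zip(pts, tangent, radial):
        c = np.array(
            [
                p + long_half * t + short_half * rdir,
                p + long_half * t - short_half * rdir,
                p - long_half * t - short_half * rdir,
                p - long_half * t + short_half * rdir,
            ]
        )
        corners.append(c)
    return corners


def make_centroids(spec: PhantomSpec) -> tuple[VertebralCentroidSet, GroundTruth]:
    """Generate the observed (noisy, possibly incomplete) centroid set and
    the exact ground truth for one phantom.

    Observed centroids are the true arc positions plus i.i.d. Gaussian noise
    of sd ``centroid_noise_sd``; each level is independently dropped with its
    dropout probability.  Deterministic given ``spec.seed``.
    """
    spec.validate()
    pts, tangent, radial = _arc_geometry(spec)
    levels = spec.levels()
    w, h = spec.image_size

    corners = _body_corners(pts, tangent, radial, spec.effective_vertebra_size())
    for c in corners:
        if (c[:, 0] < 0).any() or (c[:, 0] >= w).any() or (c[:, 1] < 0).any() or (
            c[:, 1] >= h
        ).any():
            raise SpecError(
                "arc does not fit the image bounds at the given radius/size"
            )

    true_set = VertebralCentroidSet(scan_id=f"phantom-{spec.seed}", units="px")
    boxes = []
    for lvl, p, c in zip(levels, pts, corners):
        true_set.add(lvl, Point2D(float(p[0]), float(p[1])), 1.0)
        boxes.append(
            BoundingBox(
                x_min=float(c[:, 0].min()),
                y_min=float(c[:, 1].min()),
                x_max=float(c[:, 0].max()),
                y_max=float(c[:, 1].max()),
                level=lvl,
                confidence=1.0,
            )
        )
    truth = GroundTruth(
        true_angle_deg=spec.true_central_angle_deg,
        true_centroids=true_set,
        true_boxes=boxes,
        body_polygons=corners,
    )

    rng = np.random.default_rng(np.random.SeedSequence(spec.seed).spawn(2)[0])
    n = len(levels)
    noise = rng.normal(0.0, spec.centroid_noise_sd, size=(n, 2)) if n else np.empty((0, 2))
    drop_draws = rng.random(n)
    confidences = rng.uniform(0.85, 0.99, size=n)
    dropout = spec._dropout_map()

    observed = VertebralCentroidSet(scan_id=true_set.scan_id, units="px")
    for i, lvl in enumerate(levels):
        if drop_draws[i] < dropout[lvl]:
            continue
        observed.add(
            lvl,
            Point2D(float(pts[i, 0] + noise[i, 0]), float(pts[i, 1] + noise[i, 1])),
            float(confidences[i]),
        )
    return observed, truth


def render_phantom(
    spec: PhantomSpec, truth: GroundTruth
) -> tuple[np.ndarray, list[BoundingBox]]:
    """Render the phantom as a (height, width) float image in [0, 1].

    Each vertebral body is a bright filled rotated rectangle at its true
    centroid (long axis tangent to the arc), on a dark background; the image
    is then Gaussian-blurred (``blur_sigma``) and corrupted with additive
    Gaussian noise (``background_noise_sd``), clipped to [0, 1].  Returns the
    image and the axis-aligned ground-truth boxes.

    Raises :class:`SpecError` when neighbouring bodies overlap (the arc
    spacing is too tight for ``vertebra_size``).
    """
    spec.validate()
    polys = [Polygon(c) for c in truth.body_polygons]
    for i in range(len(polys)):
        for j in range(i + 1, len(polys)):
            if polys[i].intersection(polys[j]).area > 0:
                raise SpecError(
                    "vertebral bodies overlap: arc spacing too tight for "
                    "vertebra_size"
                )

    w, h = spec.image_size
    img = np.zeros((h, w), dtype=float)
    for c in truth.body_polygons:
        rr, cc = draw_polygon(c[:, 1], c[:, 0], shape=img.shape)
        img[rr, cc] = 1.0
    if spec.blur_sigma > 0:
        img = gaussian_blur(img, sigma=spec.blur_sigma, preserve_range=True)
    if spec.background_noise_sd > 0:
        rng = np.random.default_rng(np.random.SeedSequence(spec.seed).spawn(2)[1])
        img = img + rng.normal(0.0, spec.background_noise_sd, size=img.shape)
    return np.clip(img, 0.0, 1.0), list(truth.true_boxes)


def simulate_manual_cobb(
    true_angle_deg: float,
    obs_a: ObserverModel,
    obs_b: ObserverModel,
    consensus_threshold_deg: float = 2.0,
    rng_a: np.random.Generator | None = None,
    rng_b: np.random.Generator | None = None,
) -> float:
    """Simulate the two-reader manual Cobb measurement with consensus.

    Each observer reads ``true + bias + N(0, sd)``.  If the readings agree
    within the consensus threshold (default 2°) the result is their mean;
    otherwise the discrepancy is resolved by a consensus discussion, modeled
    as both observers re-reading with half their noise sd and averaging —
    consensus reduces, but does not eliminate, reading error.
    """
    if not math.isfinite(true_angle_deg):
        raise ValueError("true angle must be finite")
    rng_a = rng_a if rng_a is not None else np.random.default_rng(obs_a.seed)
    rng_b = rng_b if rng_b is not None else np.random.default_rng(obs_b.seed)
    read_a = true_angle_deg + obs_a.bias_deg + rng_a.normal(0.0, obs_a.noise_sd_deg)
    read_b = true_angle_deg + obs_b.bias_deg + rng_b.normal(0.0, obs_b.noise_sd_deg)
    if abs(read_a - read_b) <= consensus_threshold_deg:
        return (read_a + read_b) / 2.0
    re_a = true_angle_deg + obs_a.bias_deg + rng_a.normal(0.0, obs_a.noise_sd_deg / 2.0)
    re_b = true_angle_deg + obs_b.bias_deg + rng_b.normal(0.0, obs_b.noise_sd_deg / 2.0)
    return (re_a + re_b) / 2.0


def _sample_true_angles(
    n: int, mean: float, sd: float, rng: np.random.Generator
) -> np.ndarray:
    lo, hi = ANGLE_BOUNDS
    if sd == 0:
        if not lo <= mean <= hi:
            raise SpecError("angle mean outside geometric validity bounds")
        return np.full(n, float(mean))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)


def make_cohort(
    n: int,
    angle_mean: float,
    angle_sd: float,
    spec_template: PhantomSpec | None = None,
    obs_a: ObserverModel | None = None,
    obs_b: ObserverModel | None = None,
    seed: int = 0,
    consensus_threshold_deg: float = 2.0,
    config: MeasurementConfig | None = None,
) -> pd.DataFrame:
    """Simulate a cohort of ``n`` scans and return the paired angle table.

    True angles are drawn from a normal(``angle_mean``, ``angle_sd``)
    truncated to [5°, 120°].  For each scan the full pipeline runs: noisy
    centroids → automated circle-fit measurement, and two simulated readers →
    manual consensus angle.  Columns: ``scan_id, true_deg, automated_deg,
    manual_deg, qc_flag``; QC-flagged scans carry NaN in ``automated_deg``.
    """
    if n < 2:
        raise ValueError("a cohort needs at least 2 scans")
    spec_template = spec_template or PhantomSpec()
    obs_a = obs_a or ObserverModel(seed=1)
    obs_b = obs_b or ObserverModel(seed=2)

    ss = np.random.SeedSequence(seed)
    angle_ss, obs_a_ss, obs_b_ss, scan_ss = ss.spawn(4)
    rng_angles = np.random.default_rng(angle_ss)
    rng_a = np.random.default_rng(obs_a_ss)
    rng_b = np.random.default_rng(obs_b_ss)
    scan_seeds = scan_ss.generate_state(n) % np.uint32(2**31)

    true_angles = _sample_true_angles(n, angle_mean, angle_sd, rng_angles)
    rows = []
    for i in range(n):
        spec = replace(
            spec_template,
            true_central_angle_deg=float(true_angles[i]),
            seed=int(scan_seeds[i]),
        )
        observed, _ = make_centroids(spec)
        meas = measure_kyphosis(observed, config)
        manual = simulate_manual_cobb(
            float(true_angles[i]),
            obs_a,
            obs_b,
            consensus_threshold_deg,
            rng_a=rng_a,
            rng_b=rng_b,
        )
        rows.append(
            {
                "scan_id": f"scan-{i:04d}",
                "true_deg": float(true_angles[i]),
                "automated_deg": meas.central_angle_deg
                if meas.qc_flag == "ok"
                else np.nan,
                "manual_deg": manual,
                "qc_flag": meas.qc_flag,
            }
        )
    return pd.DataFrame(rows)
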