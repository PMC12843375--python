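"""Shared fixtures and independent oracles.

The brute-force circle fit here is deliberately independent of the package's
fitting code: a 2-D grid search over the center (the optimal radius for a
fixed center is the mean point-to-center distance, so the radius is profiled
out exactly), refined by shrinking the search window around the running
optimum.
"""

from __future__ import annotations

import numpy as np
import pytest


def arc_points(
    theta_deg: float,
    radius: float = 55.0,
    center: tuple[float, float] = (12.5, -40.0),
    n: int = 9,
    mid_phi_deg: float = 180.0,
) -> np.ndarray:
    """n points at equal angular steps spanning exactly theta_deg."""
    theta = np.radians(theta_deg)
    mid = np.radians(mid_phi_deg)
    phis = mid + theta / 2.0 - np.arange(n) * theta / (n - 1)
    return np.column_stack(
        [center[0] + radius * np.cos(phis), center[1] + radius * np.sin(phis)]
    )


def brute_force_circle_fit(
    points: np.ndarray, n_grid: int = 21, iters: int = 70, polish: bool = False
) -> tuple[float, float, float]:
    """Global minimizer of sum((dist_i - r)^2) by profiled grid refinement.

    Returns (cx, cy, r).  Independent oracle: no shared code with
    kyphometry.geometry.fit_circle.  With ``polish=True`` the grid result is
    refined by Nelder-Mead on the profiled 2-D objective, which tracks the
    banana-shaped valley of shallow arcs better than isotropic shrinking.
    """
    pts = np.asarray(points, dtype=float)
    c0 = pts.mean(axis=0)
    span = float(
        np.max(np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1))
    )
    half = 10.0 * span
    best = (float(c0[0]), float(c0[1]), 0.0)
    for _ in range(iters):
        xs = np.linspace(c0[0] - half, c0[0] + half, n_grid)
        ys = np.linspace(c0[1] - half, c0[1] + half, n_grid)
        gx, gy = np.meshgrid(xs, ys, indexing="ij")
        d = np.sqrt(
            (pts[:, 0] - gx[..., None]) ** 2 + (pts[:, 1] - gy[..., None]) ** 2
        )
        r = d.mean(axis=-1)
        obj = ((d - r[..., None]) ** 2).sum(axis=-1)
        i, j = np.unravel_index(np.argmin(obj), obj.shape)
        c0 = np.array([gx[i, j], gy[i, j]])
        best = (float(c0[0]), float(c0[1]), float(r[i, j]))
        half *= 0.6
    if polish:
        from scipy.optimize import minimize

        def obj(c):
            d = np.hypot(pts[:, 0] - c[0], pts[:, 1] - c[1])
            return float(((d - d.mean()) ** 2).sum())

        res = minimize(
            obj,
            [best[0], best[1]],
            method="Nelder-Mead",
            options=dict(xatol=1e-12, fatol=1e-16, maxiter=20000, maxfev=20000),
        )
        d = np.hypot(pts[:, 0] - res.x[0], pts[:, 1] - res.x[1])
        best = (float(res.x[0]), float(res.x[1]), float(d.mean()))
    return best


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260928)
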