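"""Helix axis fitting, inter-helix orientation angles, and helix bend.

The axis of a helix is estimated from its C-alpha atoms by a geometric
least-squares cylinder fit (the C-alphas of a regular helix all lie at
the cylinder radius from the axis), initialised from 3-point running
means of the C-alpha positions, which suppress the ~100 deg/residue
helical wobble; the axis is oriented N->C.  Helix bend is quantified two
ways, reflecting two common
conventions: the radius of the circle fitted to the smoothed axis points
(a bent helix follows an arc), and the radius of the minimal sphere
enclosing the C-alpha atoms (a bent helix packs into a smaller sphere
than an extended one of the same length).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .selection import Selection
from .trajectory import Ensemble

__all__ = [
    "HelixAxisModel",
    "HelixMetricSeries",
    "fit_helix_axis",
    "interhelix_angle_series",
    "bend_radius_series",
    "minimal_enclosing_sphere",
    "STRAIGHT_RADIUS_CAP",
]

STRAIGHT_RADIUS_CAP = 1e6  # Å reported for an exactly straight axis


@dataclass(frozen=True)
class HelixAxisModel:
    axis: np.ndarray        # unit vector, oriented N->C
    centroid: np.ndarray    # point on the axis, Å
    radius: float           # mean C-alpha distance to the axis (cylinder radius)
    residual_rms: float     # RMS distance of smoothed axis points to the line

    def __post_init__(self):
        if abs(np.linalg.norm(self.axis) - 1.0) > 1e-9:
            raise ValueError("axis must be unit length")


def _smoothed_axis_points(calphas: np.ndarray) -> np.ndarray:
    """3-point running means of consecutive C-alphas: local axis estimates."""
    return (calphas[:-2] + calphas[1:-1] + calphas[2:]) / 3.0


def _line_from_smoothed(ca: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Initial axis guess: principal direction of 3-point-smoothed C-alphas."""
    pts = _smoothed_axis_points(ca)
    centroid = pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts - centroid, full_matrices=False)
    return centroid, vt[0]


def fit_helix_axis(frame: np.ndarray, calpha_selection: Selection) -> HelixAxisModel:
    """Best-fit cylinder axis through a helix's C-alpha atoms on one frame.

    The C-alphas of a regular helix lie on a cylinder, so the axis is
    estimated by a geometric least-squares cylinder fit (minimising the
    spread of point-to-axis distances), initialised from the principal
    direction of the 3-point-smoothed C-alphas.  Exact on ideal helices;
    oriented so that axis . (last CA - first CA) > 0.  Degenerate
    (collinear) input yields the exact line with cylinder radius 0.
    """
    ca = np.asarray(frame, dtype=float)[calpha_selection.indices]
    if len(ca) < 5:
        raise ValueError("helix axis fit needs at least 5 C-alpha atoms")
    centroid0, axis0 = _line_from_smoothed(ca)
    rel0 = ca - centroid0
    rho0 = np.linalg.norm(rel0 - np.outer(rel0 @ axis0, axis0), axis=1)
    axis, centroid, radius = axis0, centroid0, float(rho0.mean())
    if len(ca) >= 7 and radius > 1e-9:       # lm needs >= as many residuals as params

        def resid(params):
            c = params[:3]
            n = params[3:6] / np.linalg.norm(params[3:6])
            rel = ca - c
            rho = np.linalg.norm(rel - np.outer(rel @ n, n), axis=1)
            return rho - params[6]

        fit = least_squares(
            resid, np.concatenate([centroid0, axis0, [radius]]),
            method="lm", max_nfev=1000,
        )
        axis = fit.x[3:6] / np.linalg.norm(fit.x[3:6])
        centroid = fit.x[:3]
        radius = float(abs(fit.x[6]))
    if np.dot(axis, ca[-1] - ca[0]) < 0:
        axis = -axis
    rel = ca - centroid
    h = rel @ axis
    rho = np.linalg.norm(rel - np.outer(h, axis), axis=1)
    residual = float(np.sqrt(np.mean((rho - radius) ** 2)))
    # report the axis point nearest the C-alpha centroid
    centroid = centroid + h.mean() * axis
    return HelixAxisModel(axis, centroid, radius, residual)


@dataclass(frozen=True)
class HelixMetricSeries:
    """Per-frame helix metric: orientation angle or bend/sphere radius."""

    metric: str                      # 'angle' | 'bend_radius' | 'sphere_radius'
    values: np.ndarray               # degrees or Å
    selections: tuple[str, ...]
    straight: np.ndarray | None = None   # flags where the axis was straight


def interhelix_angle_series(
    ensemble: Ensemble, helix_a: Selection, helix_b: Selection
) -> HelixMetricSeries:
    """Angle (degrees, in [0, 180]) between two helix axes, per frame.

    Both axes are N->C oriented, so parallel helices give 0 deg and
    antiparallel ones 180 deg.
    """
    values = np.empty(ensemble.n_frames)
    for f in range(ensemble.n_frames):
        try:
            ax_a = fit_helix_axis(ensemble.coords[f], helix_a).axis
            ax_b = fit_helix_axis(ensemble.coords[f], helix_b).axis
        except ValueError as exc:
            raise ValueError(f"axis fit failed on frame {f}: {exc}") from exc
        values[f] = np.degrees(np.arccos(np.clip(np.dot(ax_a, ax_b), -1.0, 1.0)))
    return HelixMetricSeries(
        "angle", values, (helix_a.expression, helix_b.expression)
    )


# ---------------------------------------------------------------------------
# circle fit


def _initial_circle(pts: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Plane (total least squares) + algebraic Kasa circle fit in-plane.

    Returns (3-D centre, unit normal, radius); radius may be inf for
    straight input.
    """
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    normal = vt[2]
    xy = centered @ vt[:2].T          # in-plane coordinates
    x, y = xy[:, 0], xy[:, 1]
    a_mat = np.column_stack([2 * x, 2 * y, np.ones_like(x)])
    rhs = x**2 + y**2
    sol, *_ = np.linalg.lstsq(a_mat, rhs, rcond=None)
    cx, cy = sol[0], sol[1]
    r0 = float(np.sqrt(max(sol[2] + cx**2 + cy**2, 0.0)))
    centre = centroid + cx * vt[0] + cy * vt[1]
    return centre, normal, r0


def _fit_axis_circle(calphas: np.ndarray, cap: float) -> tuple[float, bool]:
    """Radius of the circular arc the helix axis follows.

    The C-alphas of a circularly bent helix lie at a constant distance
    (the cylinder radius) from the axis arc, so the arc is recovered by a
    geometric least-squares fit of a 3-D circle minimising the spread of
    point-to-circle distances.  This is insensitive to the per-residue
    helical wobble that biases a plain circle fit through smoothed axis
    points when the arc is short.  Initialised from a plane + algebraic
    circle fit of the 3-point-smoothed axis points; (nearly) straight
    axes are reported as the cap radius with a flag.
    """
    smoothed = _smoothed_axis_points(calphas)
    centre0, normal0, r0 = _initial_circle(smoothed)
    if not np.isfinite(r0) or r0 > cap:
        return cap, True
    # straight-axis alternative: distances of C-alphas to the best-fit line
    axis_centroid = smoothed.mean(axis=0)
    _, _, vt_line = np.linalg.svd(smoothed - axis_centroid, full_matrices=False)
    rel = calphas - axis_centroid
    perp = rel - np.outer(rel @ vt_line[0], vt_line[0])
    sd_line = float(np.std(np.linalg.norm(perp, axis=1)))

    def dist_to_circle(params):
        c = params[:3]
        n = params[3:6]
        n = n / np.linalg.norm(n)
        r = params[6]
        rel = calphas - c
        h = rel @ n
        rho = np.linalg.norm(rel - np.outer(h, n), axis=1)
        return np.sqrt((rho - r) ** 2 + h**2)

    def resid(params):
        d = dist_to_circle(params)
        return d - d.mean()

    x0 = np.concatenate([centre0, normal0, [r0]])
    fit = least_squares(resid, x0=x0, method="lm", max_nfev=2000)
    radius = float(abs(fit.x[6]))
    sd_circle = float(np.std(dist_to_circle(fit.x)))
    # a straight helix is fitted at least as well by a line (constant
    # cylinder radius); in that regime the circle radius is meaningless
    if not np.isfinite(radius) or radius > cap or sd_line <= sd_circle * 1.05 + 1e-9:
        return cap, True
    return radius, False


def bend_radius_series(
    ensemble: Ensemble,
    calpha_selection: Selection,
    method: str = "enclosing_sphere",
    straight_cap: float = STRAIGHT_RADIUS_CAP,
) -> HelixMetricSeries:
    """Per-frame helix bend measured as a circle or enclosing-sphere radius.

    ``arc_circle``: geometric least-squares fit of the circular arc the
    helix axis follows (smaller radius = more bent); an exactly straight
    axis is reported as the cap radius with a straightness flag.  ``enclosing_sphere``: radius
    of the minimal sphere containing the selected C-alpha atoms (a bent
    helix needs a smaller sphere than an extended one).
    """
    if len(calpha_selection) < 6:
        raise ValueError("bend radius needs at least 6 C-alpha atoms")
    values = np.empty(ensemble.n_frames)
    straight = np.zeros(ensemble.n_frames, dtype=bool)
    for f in range(ensemble.n_frames):
        ca = ensemble.coords[f, calpha_selection.indices, :]
        if method == "arc_circle":
            values[f], straight[f] = _fit_axis_circle(ca, straight_cap)
        elif method == "enclosing_sphere":
            _, values[f] = minimal_enclosing_sphere(ca)
        else:
            raise ValueError("method must be 'arc_circle' or 'enclosing_sphere'")
    metric = "bend_radius" if method == "arc_circle" else "sphere_radius"
    return HelixMetricSeries(
        metric, values, (calpha_selection.expression,),
        straight if method == "arc_circle" else None,
    )


# ---------------------------------------------------------------------------
# minimal enclosing sphere (Welzl)


def _circumsphere(support: list[np.ndarray]) -> tuple[np.ndarray, float]:
    """Smallest sphere with all support points (1-4) on its boundary."""
    if not support:
        return np.zeros(3), 0.0
    if len(support) == 1:
        return support[0].copy(), 0.0
    p0 = support[0]
    a = np.array([2.0 * (p - p0) for p in support[1:]])
    b = np.array([np.dot(p, p) - np.dot(p0, p0) for p in support[1:]])
    # centre = p0 + x with x in the affine hull of the support points;
    # the minimum-norm lstsq solution lies in the row space of `a`, which
    # is exactly that hull, so equidistance holds for all support points
    sol, *_ = np.linalg.lstsq(a, b - a @ p0, rcond=None)
    centre = p0 + sol
    radius = float(np.linalg.norm(centre - p0))
    return centre, radius


def _welzl(points: list[np.ndarray], support: list[np.ndarray]) -> tuple[np.ndarray, float]:
    if not points or len(support) == 4:
        return _circumsphere(support)
    p = points[-1]
    centre, radius = _welzl(points[:-1], support)
    if np.linalg.norm(p - centre) <= radius * (1 + 1e-12) + 1e-12:
        return centre, radius
    return _welzl(points[:-1], support + [p])


def minimal_enclosing_sphere(points: np.ndarray) -> tuple[np.ndarray, float]:
    """Centre and radius of the minimal sphere enclosing 3-D points (Welzl).

    Exact (up to floating point) for the point counts arising from single
    helices; a fixed internal shuffle keeps the recursion shallow and the
    result deterministic.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) == 0:
        raise ValueError("points must be a non-empty (n, 3) array")
    order = np.random.default_rng(12345).permutation(len(pts))
    shuffled = [pts[i] for i in order]
    import sys

    old = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old, 10 * len(pts) + 1000))
    try:
        centre, radius = _welzl(shuffled, [])
    finally:
        sys.setrecursionlimit(old)
    return centre, float(radius)
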