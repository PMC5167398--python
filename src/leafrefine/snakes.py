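"""Fixed-endpoint open snakes that lock onto leaf edges.

Each recovered feature gets a *pair* of open active contours bounding the
missed leaf region: the evolved particle path translated +-D/2 along its
orthogonal (D = local leaf width from the control-point anchors), with the
heads pinned at the anchors p_L / p_R and the tails pinned according to the
feature type (tip/axil corner, opposing-fragment anchors for a twist, or
points astride the intersection for a leaf edge).

The snake minimizes the discrete energy

    E = sum_i alpha * |v_{i+1} - v_i|^2 + lam * E_ext(v_i),

a first-order (membrane) internal term that shortens the curve plus an
edge-attraction term E_ext = -|grad(G_sigma * I)|^2.  Minimization is by
semi-implicit Euler steps on the interior points (tridiagonal solve with
Dirichlet endpoints) with a backtracking line search on the step size, so
the total energy never increases between iterations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_banded
from scipy.ndimage import gaussian_filter, map_coordinates

from .config import RefinementConfig
from .contours import Contour
from .evolution import EvolutionResult, StopReason

__all__ = [
    "Snake",
    "SnakePair",
    "external_energy",
    "evolve_snake",
    "initialize_snake_pair",
    "resample_polyline",
]


@dataclass
class Snake:
    points: np.ndarray  # (n, 2) open polyline, sub-pixel
    fixed_head: bool = True
    fixed_tail: bool = True

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, float)
        if len(self.points) < 3:
            raise ValueError("snake needs >= 3 points")


@dataclass
class SnakePair:
    left: Snake
    right: Snake
    feature: StopReason
    source: EvolutionResult


def external_energy(image: np.ndarray, sigma: float) -> np.ndarray:
    """Edge-attraction energy E_ext = -|grad(G_sigma * I)|^2 (minima on edges)."""
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    sm = gaussian_filter(np.asarray(image, float), sigma, mode="reflect")
    g_r = np.gradient(sm, axis=0)
    g_c = np.gradient(sm, axis=1)
    return -(g_r**2 + g_c**2)


def resample_polyline(points: np.ndarray, spacing: float = 1.0, min_points: int = 3) -> np.ndarray:
    """Resample an open polyline to uniform spacing ~``spacing``.

    Endpoints are preserved exactly.  Degenerate (near-zero length) inputs
    return ``min_points`` copies interpolated between the endpoints.
    """
    points = np.asarray(points, float)
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    n = max(min_points, int(round(total / spacing)) + 1)
    if total <= 1e-12:
        return np.linspace(points[0], points[-1], n)
    t = np.linspace(0.0, total, n)
    return np.column_stack([np.interp(t, s, points[:, i]) for i in (0, 1)])


def _snake_energy(pts: np.ndarray, energy: np.ndarray, alpha: float, lam: float) -> float:
    seg2 = np.sum(np.diff(pts, axis=0) ** 2, axis=1)
    e_ext = map_coordinates(energy, pts.T, order=1, mode="nearest")
    return float(alpha * seg2.sum() + lam * e_ext.sum())


def evolve_snake(
    snake: Snake,
    energy: np.ndarray,
    alpha: float,
    lam: float,
    max_iter: int = 500,
    tol: float = 0.05,
    energy_history: list | None = None,
) -> Snake:
    """Minimize the snake energy; endpoints flagged fixed never move.

    Semi-implicit Euler on the interior points: the internal (membrane)
    force is treated implicitly via a tridiagonal solve, the external force
    explicitly through bilinear interpolation of the energy gradient.  A
    backtracking line search halves the step whenever a trial step would
    raise the total energy, so the energy is non-increasing; points are
    resampled to roughly unit spacing every 25 iterations (never reducing
    the point count, which keeps the re-measured energy from jumping).
    Iteration stops when the largest point displacement falls below ``tol``.
    """
    pts = snake.points.copy()
    g_r, g_c = np.gradient(energy)
    tau0 = 1.0 / (4.0 * alpha + 1.0)
    tau = tau0
    tau_min = tau0 * 1e-6
    e_old = _snake_energy(pts, energy, alpha, lam)
    if not np.isfinite(e_old):
        raise ValueError("non-finite energy under the initial snake")
    if energy_history is not None:
        energy_history.append(("init", e_old))

    for it in range(max_iter):
        if len(pts) < 3:
            break
        interior = pts[1:-1]
        grad_ext = np.column_stack(
            [
                map_coordinates(g_r, interior.T, order=1, mode="nearest"),
                map_coordinates(g_c, interior.T, order=1, mode="nearest"),
            ]
        )
        moved = None
        while tau > tau_min:
            new_pts = _semi_implicit_step(pts, grad_ext, alpha, lam, tau)
            e_new = _snake_energy(new_pts, energy, alpha, lam)
            if not np.isfinite(e_new):
                raise ValueError("non-finite energy under the snake")
            if e_new <= e_old + 1e-12:
                moved = new_pts
                e_old = e_new
                tau = min(tau * 1.2, 4.0 * tau0)
                break
            tau *= 0.5
        if moved is None:
            break  # no descent step possible: local minimum
        disp = float(np.max(np.linalg.norm(moved - pts, axis=1)))
        pts = moved
        if energy_history is not None:
            energy_history.append(("step", e_old))
        if disp < tol:
            break
        if (it + 1) % 25 == 0:
            n_old = len(pts)
            res = resample_polyline(pts, spacing=1.0, min_points=max(3, n_old))
            pts = res
            e_old = _snake_energy(pts, energy, alpha, lam)
            if energy_history is not None:
                energy_history.append(("resample", e_old))

    out = Snake(points=pts, fixed_head=snake.fixed_head, fixed_tail=snake.fixed_tail)
    # fixed endpoints are bit-identical to the input's
    out.points[0] = snake.points[0]
    out.points[-1] = snake.points[-1]
    return out


def _semi_implicit_step(
    pts: np.ndarray, grad_ext: np.ndarray, alpha: float, lam: float, tau: float
) -> np.ndarray:
    """One semi-implicit update of the interior points (Dirichlet endpoints)."""
    m = len(pts) - 2
    c = 2.0 * tau * alpha
    ab = np.zeros((3, m))
    ab[0, 1:] = -c
    ab[1, :] = 1.0 + 2.0 * c
    ab[2, :-1] = -c
    rhs = pts[1:-1] - tau * lam * grad_ext
    rhs[0] += c * pts[0]
    rhs[-1] += c * pts[-1]
    new = pts.copy()
    new[1:-1] = np.column_stack(
        [solve_banded((1, 1), ab, rhs[:, i]) for i in (0, 1)]
    )
    return new


def _path_orthogonals(path: np.ndarray, fallback: np.ndarray) -> np.ndarray:
    """Unit orthogonals of a polyline (rotated tangents), consistent along it."""
    if len(path) == 1:
        t = fallback / max(np.linalg.norm(fallback), 1e-12)
        return np.array([[-t[1], t[0]]])
    t = np.gradient(path, axis=0)
    norms = np.linalg.norm(t, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    t = t / norms
    return np.column_stack([-t[:, 1], t[:, 0]])


def _assign_by_proximity(
    targets: tuple[np.ndarray, np.ndarray], a: np.ndarray, b: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Pair (a, b) with the two targets so total distance is minimal."""
    t0, t1 = targets
    keep = np.linalg.norm(a - t0) + np.linalg.norm(b - t1)
    swap = np.linalg.norm(a - t1) + np.linalg.norm(b - t0)
    return (t0, t1) if keep <= swap else (t1, t0)


def initialize_snake_pair(
    result: EvolutionResult,
    corner,
    cfg: RefinementConfig,
    contours: list[Contour] | None = None,
) -> SnakePair:
    """Build the initial left/right snakes for one evolved particle.

    Base curves are the particle path translated +-D/2 along the path
    orthogonal; heads are fixed at the control point's anchors p_L / p_R.
    Tails: TIP/AXIL -> both at the detected corner (joined by a straight
    segment); TWIST -> at the matched foreign control point's anchors;
    EDGE -> at the two points offset +-D/2 from the entry point along the
    foreign contour's local tangent.
    """
    if result.stop_reason == StopReason.ABORTED:
        raise ValueError("cannot build snakes for an aborted evolution")
    cp = result.control_point
    d_half = cp.leaf_width / 2.0
    path = result.path
    init_dir = path[1] - path[0] if len(path) > 1 else cp.outward_normal
    orth = _path_orthogonals(path, init_dir)
    base_a = path + d_half * orth
    base_b = path - d_half * orth

    head_a, head_b = _assign_by_proximity(
        (cp.anchor_left, cp.anchor_right), base_a[0], base_b[0]
    )

    if result.stop_reason in (StopReason.TIP, StopReason.AXIL):
        if corner is None:
            raise ValueError("corner estimate required for TIP/AXIL snakes")
        tail = np.asarray(corner.location, float)
        tail_a = tail_b = tail
    elif result.stop_reason == StopReason.TWIST:
        matched = result.matched_control_point
        if matched is None:
            raise ValueError("TWIST result lacks a matched foreign control point")
        tail_a, tail_b = _assign_by_proximity(
            (matched.anchor_left, matched.anchor_right), base_a[-1], base_b[-1]
        )
    elif result.stop_reason == StopReason.EDGE:
        if contours is None:
            raise ValueError("EDGE snakes need the contour list")
        foreign = next(
            c for c in contours if c.component_id == result.entered_contour_id
        )
        fp = foreign.points
        i = int(np.argmin(np.linalg.norm(fp - result.terminal_point, axis=1)))
        t = fp[(i + 1) % len(fp)] - fp[(i - 1) % len(fp)]
        t = t / max(np.linalg.norm(t), 1e-12)
        tail_a, tail_b = _assign_by_proximity(
            (fp[i] + d_half * t, fp[i] - d_half * t), base_a[-1], base_b[-1]
        )
    else:  # pragma: no cover
        raise ValueError(f"unsupported stop reason {result.stop_reason}")

    def build(head: np.ndarray, base: np.ndarray, tail: np.ndarray) -> Snake:
        pts = np.vstack([head[None, :], base, tail[None, :]])
        pts = resample_polyline(pts, spacing=1.0, min_points=3)
        return Snake(points=pts, fixed_head=True, fixed_tail=True)

    return SnakePair(
        left=build(head_a, base_a, tail_a),
        right=build(head_b, base_b, tail_b),
        feature=result.stop_reason,
        source=result,
    )
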