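"""Particle evolution: tracing control points to the plant feature they flag.

A control point marks where the initial segmentation probably clipped a
feature, but the feature itself (the true tip, the axil vertex, the far
side of a twist) may lie far away.  Each control point is therefore evolved
as a particle: starting along the contour normal, it takes unit steps whose
direction is re-derived every iteration from the dominant modes of the
local orientation histogram, so the particle follows the leaf.  Four
stopping criteria, checked in sequence each iteration, classify the feature
reached:

TIP    the travel-aligned histogram mode has (almost) no support left --
       the leaf has ended (outward particles only);
AXIL   the inner-edge lobes of the perpendicular tangent/travel dot-product
       signal vanish -- the axil vertex was passed (inward particles only);
EDGE   the particle entered another object's contour away from its control
       points -- two leaves intersect;
TWIST  the particle entered another contour within w/2 of one of that
       contour's control points -- it crossed a twist where the leaf was
       broken in two.

A particle that leaves the image or exhausts its step budget is ABORTED and
contributes nothing downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from matplotlib.path import Path as MplPath

from .config import RefinementConfig
from .contours import Contour, ControlPoint
from .orientation import (
    OrientationField,
    OrientationHistogram,
    dominant_modes,
    label_modes,
    orientation_histogram,
    step_direction,
    unit_vector,
)

__all__ = [
    "StopReason",
    "EvolutionResult",
    "initial_direction",
    "evolve_particle",
    "check_tip",
    "axil_signal",
    "check_axil",
    "classify_contour_entry",
]


# a leaf edge cannot turn faster than this per unit step; proposed directions
# beyond the cap (noise modes in weak-gradient windows) are clamped toward
# the previous heading
MAX_TURN_RAD = np.pi / 6.0


class StopReason(Enum):
    TIP = "tip"
    AXIL = "axil"
    EDGE = "edge"
    TWIST = "twist"
    ABORTED = "aborted"


@dataclass
class EvolutionResult:
    """Path and outcome of one evolved particle."""

    control_point: ControlPoint
    path: np.ndarray  # (n, 2) sub-pixel positions, path[0] = control point
    stop_reason: StopReason
    inward: bool
    entered_contour_id: int | None = None
    matched_control_point: ControlPoint | None = None

    @property
    def terminal_point(self) -> np.ndarray:
        return self.path[-1]


def _polyline_length(points: list[np.ndarray]) -> float:
    return float(
        sum(np.linalg.norm(b - a) for a, b in zip(points[:-1], points[1:]))
    )


def initial_direction(
    contour: Contour, cp: ControlPoint, delta: float = 3.0
) -> tuple[np.ndarray, bool]:
    """Choose between the outward and inward normal for the first step.

    For both candidates a trial point is placed at cp.location + delta * n
    and the length of the polyline (previous neighbour, trial point, next
    neighbour) is compared: the direction that adds more length to the
    contour is the direction in which the clipped feature extends.  Returns
    (unit direction, inward flag); ties choose outward with a warning.
    """
    if delta <= 0:
        raise ValueError("delta must be > 0")
    n = len(contour)
    prev_pt = contour.points[(cp.index - 1) % n]
    next_pt = contour.points[(cp.index + 1) % n]
    lengths = {}
    for sign in (+1.0, -1.0):
        trial = cp.location + delta * sign * cp.outward_normal
        lengths[sign] = _polyline_length([prev_pt, trial, next_pt])
    if abs(lengths[1.0] - lengths[-1.0]) < 1e-9:
        warnings.warn("initial-direction tie; choosing outward normal", stacklevel=2)
        return cp.outward_normal.copy(), False
    if lengths[1.0] > lengths[-1.0]:
        return cp.outward_normal.copy(), False
    return -cp.outward_normal, True


def check_tip(hist: OrientationHistogram, theta1: float, epsilon: float) -> bool:
    """Leaf-tip criterion: the travel mode has lost its support.

    True iff the smoothed histogram count in theta1's bin is <= epsilon,
    i.e. no dominant orientation remains along the direction of travel.
    """
    return hist.count_at(theta1) <= epsilon


def axil_signal(
    field: OrientationField, p: np.ndarray, v: np.ndarray, w: int
) -> np.ndarray:
    """Tangent/travel alignment along the line perpendicular to the motion.

    Samples the perpendicular line through ``p`` (length w, unit spacing,
    nearest-pixel lookup) and returns the dot product between the tangent
    field's unit vector and the travel direction ``v`` at each sample.
    Inner leaf edges give values near +1, outer edges near -1.
    """
    p = np.asarray(p, float)
    v = np.asarray(v, float)
    perp = np.array([-v[1], v[0]])
    offsets = np.arange(-(w // 2), w // 2 + 1, dtype=float)
    samples = p[None, :] + offsets[:, None] * perp[None, :]
    rows = np.clip(np.round(samples[:, 0]).astype(int), 0, field.shape[0] - 1)
    cols = np.clip(np.round(samples[:, 1]).astype(int), 0, field.shape[1] - 1)
    in_image = (
        (np.round(samples[:, 0]) >= 0)
        & (np.round(samples[:, 0]) < field.shape[0])
        & (np.round(samples[:, 1]) >= 0)
        & (np.round(samples[:, 1]) < field.shape[1])
    )
    if not in_image.any():
        raise ValueError("perpendicular sampling line lies entirely off-image")
    theta = field.theta[rows, cols]
    signal = np.cos(theta) * v[0] + np.sin(theta) * v[1]
    signal[~in_image] = 0.0
    # 3-sample moving average: coherent edge lobes survive, isolated
    # noise-orientation spikes are damped
    kernel = np.ones(3) / 3.0
    return np.convolve(signal, kernel, mode="same")


def _first_extremum(signal: np.ndarray, start: int, step: int, floor: float = 0.4):
    """First local extremum of |signal| scanning outward from ``start``.

    Returns (index, sign) or None.  ``floor`` suppresses noise extrema.
    """
    n = len(signal)
    i = start + step
    while 0 < i < n - 1:
        s = signal[i]
        if abs(s) >= floor:
            if (s >= signal[i - 1] and s >= signal[i + 1]) or (
                s <= signal[i - 1] and s <= signal[i + 1]
            ):
                return i, 1.0 if s > 0 else -1.0
        i += step
    return None


def _has_inner_edges(signal: np.ndarray) -> bool:
    """Whether the particle travels between the walls of a dark notch.

    The tangent field's rotation convention gives a fixed chirality to the
    perpendicular dot-product signal: travelling inside a *dark* notch
    between two bright arms, the strong lobes immediately left and right of
    the centre read (+, -); inside a bright ribbon they read (-, +).  Only
    the notch pattern is evidence of an axil approach -- a particle that
    strayed into leaf material shows the ribbon pattern and is abandoned by
    the caller's streak counter.
    """
    c = len(signal) // 2
    left = _first_extremum(signal, c, -1, floor=0.6)
    right = _first_extremum(signal, c, +1, floor=0.6)
    return left is not None and right is not None and left[1] > 0 and right[1] < 0


def check_axil(signal_now: np.ndarray, signal_prev: np.ndarray) -> bool:
    """Axil criterion: the inner-edge lobes adjacent to the particle vanished.

    True iff the first extremum on each side of the centre changed sign
    between the previous and current perpendicular signals (the +1-like
    inner-edge lobes are gone, leaving only the anti-aligned outer edges).
    Flat signals (no extremum) on either side give False.
    """
    if len(signal_now) != len(signal_prev):
        return False
    c = len(signal_now) // 2
    changed = 0
    for step in (-1, +1):
        now = _first_extremum(signal_now, c, step)
        prev = _first_extremum(signal_prev, c, step, floor=0.6)
        if prev is None:
            return False
        # inner and outer edges on the same side of the particle carry
        # opposite signs, so when the inner lobe disappears the first
        # extremum either vanishes or flips sign: the vertex was passed
        if now is None or now[1] != prev[1]:
            changed += 1
    return changed == 2


def _clamp_turn(v_prev: np.ndarray, v_new: np.ndarray, cap: float = MAX_TURN_RAD) -> np.ndarray:
    """Limit the change of heading per unit step to ``cap`` radians."""
    cross = v_prev[0] * v_new[1] - v_prev[1] * v_new[0]
    dot = float(np.clip(v_prev @ v_new, -1.0, 1.0))
    turn = np.arctan2(cross, dot)
    if abs(turn) <= cap:
        return v_new
    a = np.sign(turn) * cap
    rot = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
    return rot @ v_prev


def _contour_paths(contours: list[Contour]) -> dict[int, MplPath]:
    return {c.component_id: MplPath(c.points) for c in contours}


def classify_contour_entry(
    p: np.ndarray,
    contours: list[Contour],
    own_id: int,
    control_points: list[ControlPoint],
    w: int,
    paths: dict[int, MplPath] | None = None,
) -> tuple[StopReason, int, ControlPoint | None] | None:
    """EDGE/TWIST criterion: has the particle entered a foreign contour?

    Returns (TWIST, contour_id, matched control point) when ``p`` is inside
    another object's contour within w/2 of one of that contour's control
    points, (EDGE, contour_id, None) when inside but away from all of them,
    and None when in background or inside its own contour.
    """
    if paths is None:
        paths = _contour_paths(contours)
    p = np.asarray(p, float)
    for c in contours:
        if c.component_id == own_id:
            continue
        if not paths[c.component_id].contains_point((p[0], p[1])):
            continue
        best: ControlPoint | None = None
        best_d = np.inf
        for cp in control_points:
            if cp.contour_id != c.component_id:
                continue
            d = float(np.linalg.norm(cp.location - p))
            if d < best_d:
                best, best_d = cp, d
        if best is not None and best_d < w / 2.0:
            return StopReason.TWIST, c.component_id, best
        return StopReason.EDGE, c.component_id, None
    return None


def evolve_particle(
    cp: ControlPoint,
    field: OrientationField,
    contours: list[Contour],
    mask: np.ndarray,
    cfg: RefinementConfig,
    control_points: list[ControlPoint] | None = None,
    contour_by_id: dict[int, Contour] | None = None,
    paths: dict[int, MplPath] | None = None,
) -> EvolutionResult:
    """Evolve one control point until a stopping criterion fires.

    The particle starts at the control point with the trial-length initial
    direction; every iteration it takes a unit step, recomputes the window
    orientation histogram at its new position and derives the next step via
    the two dominant modes with the previous step as reference.  Criteria
    are checked in sequence TIP, AXIL, EDGE/TWIST.  Leaving the image or
    reaching the step cap yields ABORTED.
    """
    if contour_by_id is None:
        contour_by_id = {c.component_id: c for c in contours}
    if control_points is None:
        control_points = []
    if paths is None:
        paths = _contour_paths(contours)
    contour = contour_by_id[cp.contour_id]
    v, inward = initial_direction(contour, cp)
    p = cp.location.astype(float).copy()
    path = [p.copy()]
    max_steps = cfg.resolved_max_steps(field.shape)
    prev_signal: np.ndarray | None = None
    lost_streak = 0
    entered_id: int | None = None
    matched: ControlPoint | None = None
    reason = StopReason.ABORTED
    h, wid = field.shape

    for _ in range(max_steps):
        p = p + v
        path.append(p.copy())
        if not (0 <= p[0] < h and 0 <= p[1] < wid):
            reason = StopReason.ABORTED
            break
        try:
            hist = orientation_histogram(
                field, (p[0], p[1]), cfg.w, cfg.n_bins, cfg.weight_by_gradient
            )
            mode_a, mode_b = dominant_modes(hist)
        except ValueError:
            reason = StopReason.ABORTED
            break
        theta1, _theta2 = label_modes(mode_a, mode_b, v)
        v_next = _clamp_turn(v, step_direction(mode_a, mode_b, v))

        if not inward and check_tip(hist, theta1, cfg.epsilon):
            reason = StopReason.TIP
            break
        if inward:
            signal = axil_signal(field, p, v, cfg.w)
            if prev_signal is not None and check_axil(signal, prev_signal):
                reason = StopReason.AXIL
                break
            # a particle that keeps finding no inner-edge lobes is not
            # approaching an axil: abandon it rather than let it wander
            lost_streak = 0 if _has_inner_edges(signal) else lost_streak + 1
            if lost_streak >= 8:
                reason = StopReason.ABORTED
                break
            prev_signal = signal
        entry = classify_contour_entry(
            p, contours, cp.contour_id, control_points, cfg.w, paths
        )
        if entry is not None:
            reason, entered_id, matched = entry
            break
        v = v_next

    return EvolutionResult(
        control_point=cp,
        path=np.array(path),
        stop_reason=reason,
        inward=inward,
        entered_contour_id=entered_id,
        matched_control_point=matched,
    )
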