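"""Mask cleaning, contour extraction, curvature and control-point selection.

An inaccurate initial segmentation approximates the true plant shape, so the
boundary of each segmented object carries high curvature wherever a sharp
feature -- a leaf tip, a deep axil, a twist -- was clipped off.  This module
turns a binary mask into smoothed closed contours, computes their signed
curvature, and selects the curvature peaks as *control points*, each with
the pair of flanking curvature-valley anchors (p_L, p_R) whose separation D
approximates the local leaf width.

Conventions: positions are (row, col), 0-based, sub-pixel.  Contours are
closed polylines (first point adjacent to last, no duplicate endpoint)
oriented counter-clockwise in the (row, col) plane, i.e. positive shoelace
area with row as the first coordinate; with that orientation the outward
normal of a tangent (dr, dc) is (dc, -dr), up to normalization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import binary_opening, convolve1d
from skimage.measure import find_contours, label

__all__ = [
    "Contour",
    "ControlPoint",
    "clean_mask",
    "extract_contours",
    "smooth_contour",
    "contour_curvature",
    "detect_control_points",
    "anchor_points",
    "outward_normal",
]


@dataclass
class Contour:
    """Closed boundary polyline of one connected component."""

    points: np.ndarray  # (n, 2) float, (row, col), no duplicate closing point
    component_id: int

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, float)
        if len(self.points) < 8:
            raise ValueError("contour must have >= 8 points")
        if np.any(np.all(self.points == np.roll(self.points, -1, axis=0), axis=1)):
            raise ValueError("contour has consecutive duplicate points")

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class ControlPoint:
    """A curvature peak on a contour, with its snake anchors.

    ``anchor_left`` / ``anchor_right`` are the first curvature valleys on
    either side of the peak (p_L, p_R); ``leaf_width`` is their Euclidean
    separation D, used downstream as the local leaf-width estimate.
    """

    contour_id: int
    index: int
    location: np.ndarray
    outward_normal: np.ndarray
    anchor_left: np.ndarray
    anchor_right: np.ndarray
    left_index: int
    right_index: int
    kappa: float = 0.0
    leaf_width: float = field(default=0.0)

    def __post_init__(self) -> None:
        self.location = np.asarray(self.location, float)
        self.outward_normal = np.asarray(self.outward_normal, float)
        self.anchor_left = np.asarray(self.anchor_left, float)
        self.anchor_right = np.asarray(self.anchor_right, float)
        if abs(np.linalg.norm(self.outward_normal) - 1.0) > 1e-9:
            raise ValueError("outward_normal must be unit length")
        self.leaf_width = float(np.linalg.norm(self.anchor_left - self.anchor_right))
        if self.leaf_width <= 0:
            raise ValueError("anchors must be distinct (leaf_width > 0)")


def clean_mask(mask: np.ndarray, m: int) -> np.ndarray:
    """Remove small noise regions by morphological opening with an m x m square.

    Opening (erosion then dilation) deletes foreground features narrower than
    the element and never adds pixels outside the input's dilation.
    """
    if m % 2 == 0 or m < 1:
        raise ValueError("m must be odd and >= 1")
    mask = np.asarray(mask, bool)
    if m == 1:
        return mask.copy()
    return binary_opening(mask, np.ones((m, m), bool))


def _signed_area(points: np.ndarray) -> float:
    x, y = points[:, 0], points[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def _dedupe_consecutive(points: np.ndarray) -> np.ndarray:
    keep = np.any(points != np.roll(points, 1, axis=0), axis=1)
    if not keep.any():
        return points[:1]
    return points[keep]


def extract_contours(mask: np.ndarray) -> list[Contour]:
    """Trace the outer boundary of each 8-connected foreground component.

    Components touching the image border are traced along the border (the
    mask is conceptually embedded in a background frame).  Inner holes are
    ignored.  Components whose boundary has fewer than 8 points are skipped.
    """
    mask = np.asarray(mask, bool)
    labels = label(mask, connectivity=2)
    out: list[Contour] = []
    for comp_id in range(1, labels.max() + 1):
        comp = labels == comp_id
        padded = np.pad(comp, 1).astype(float)
        loops = find_contours(padded, 0.5, fully_connected="high")
        if not loops:
            continue
        # the outer boundary is the loop with the largest enclosed area
        outer = max(loops, key=lambda c: abs(_signed_area(c)))
        pts = outer - 1.0  # undo padding
        pts = np.clip(pts, 0, np.array(mask.shape, float) - 1)
        if np.allclose(pts[0], pts[-1]):
            pts = pts[:-1]
        pts = _dedupe_consecutive(pts)
        if len(pts) < 8:
            continue
        if _signed_area(pts) < 0:
            pts = pts[::-1]
        out.append(Contour(points=pts, component_id=comp_id))
    return out


def gaussian_weights(r: int) -> np.ndarray:
    """Normalized Gaussian weights over circular offsets -r..r, std r/2."""
    k = np.arange(-r, r + 1, dtype=float)
    w = np.exp(-(k**2) / (2.0 * (r / 2.0) ** 2))
    return w / w.sum()


def smooth_contour(contour: Contour, r: int) -> Contour:
    """Gaussian-weighted circular moving average of the contour points.

    Each point is replaced by the weighted mean of its neighbours at
    circular offsets -r..+r; the point count is unchanged.  Contours shorter
    than 2r + 1 are returned unchanged with a warning.
    """
    if r < 1:
        raise ValueError("r must be >= 1")
    n = len(contour)
    if n < 2 * r + 1:
        warnings.warn(
            f"contour of {n} points too short for smoothing radius {r}; left unchanged",
            stacklevel=2,
        )
        return contour
    w = gaussian_weights(r)
    pts = np.column_stack(
        [convolve1d(contour.points[:, i], w, mode="wrap") for i in (0, 1)]
    )
    pts = _dedupe_consecutive(pts)
    if len(pts) < 8:
        warnings.warn("smoothing collapsed the contour; left unchanged", stacklevel=2)
        return contour
    return Contour(points=pts, component_id=contour.component_id)


def contour_curvature(contour: Contour) -> np.ndarray:
    """Signed curvature at each contour point, by circular central differences.

    kappa = (x' y'' - y' x'') / (x'^2 + y'^2)^(3/2); for a counter-clockwise
    circle of radius R this is ~ +1/R everywhere.  Points with a zero-length
    tangent get kappa = 0 with a warning.
    """
    p = contour.points
    d1 = (np.roll(p, -1, axis=0) - np.roll(p, 1, axis=0)) / 2.0
    d2 = np.roll(p, -1, axis=0) - 2.0 * p + np.roll(p, 1, axis=0)
    num = d1[:, 0] * d2[:, 1] - d1[:, 1] * d2[:, 0]
    speed2 = d1[:, 0] ** 2 + d1[:, 1] ** 2
    denom = speed2**1.5
    bad = denom == 0
    if bad.any():
        warnings.warn("zero-length tangent on contour; curvature set to 0", stacklevel=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        kappa = np.where(bad, 0.0, num / np.where(bad, 1.0, denom))
    return kappa


def anchor_points(kappa: np.ndarray, peak_index: int) -> tuple[int, int]:
    """Locate the curvature valleys (p_L, p_R) flanking a curvature peak.

    Walking circularly left (decreasing index) and right from the peak,
    return the first index that is a local minimum of |kappa| or has
    |kappa| < 0.1.  The right walk stops one step short of the left anchor
    so that the two anchors are always distinct.
    """
    a = np.abs(np.asarray(kappa, float))
    n = len(a)

    def is_valley(i: int) -> bool:
        if a[i] < 0.1:
            return True
        lo, hi = a[(i - 1) % n], a[(i + 1) % n]
        # a flat plateau is not a valley (degenerate constant-curvature case)
        return a[i] <= lo and a[i] <= hi and (a[i] < lo or a[i] < hi)

    left = -1
    for step in range(1, n):
        i = (peak_index - step) % n
        if i == peak_index:
            break
        if is_valley(i):
            left = i
            break
    if left < 0:
        raise ValueError("degenerate contour: no curvature valley left of peak")

    prev = peak_index
    for step in range(1, n):
        i = (peak_index + step) % n
        if i == left:
            # full wrap into the left anchor: keep anchors distinct
            if prev == peak_index:
                raise ValueError("degenerate contour: anchors collapse onto peak")
            return left, prev
        if is_valley(i):
            return left, i
        prev = i
    raise ValueError("degenerate contour: no curvature valley right of peak")


def outward_normal(
    contour: Contour, index: int, mask: np.ndarray | None = None, probe: float = 2.0
) -> np.ndarray:
    """Unit normal at a contour point, oriented away from the foreground.

    The normal is perpendicular to the central-difference tangent.  When a
    mask is supplied, the orientation is fixed by probing the mask a short
    distance along both candidates; if the probes are uninformative (both
    inside or both outside), the counter-clockwise polygon convention
    (dr, dc) -> (dc, -dr) is used with a warning.
    """
    p = contour.points
    n = len(p)
    t = p[(index + 1) % n] - p[(index - 1) % n]
    norm = np.linalg.norm(t)
    if norm == 0:
        raise ValueError("zero-length tangent; cannot compute normal")
    t = t / norm
    cand = np.array([t[1], -t[0]])  # CCW convention: outward for positive-area loops
    if mask is not None:
        mask = np.asarray(mask, bool)

        def inside(q: np.ndarray) -> bool:
            r, c = int(round(q[0])), int(round(q[1]))
            if 0 <= r < mask.shape[0] and 0 <= c < mask.shape[1]:
                return bool(mask[r, c])
            return False

        out_a = not inside(p[index] + probe * cand)
        out_b = not inside(p[index] - probe * cand)
        if out_a and not out_b:
            return cand
        if out_b and not out_a:
            return -cand
        warnings.warn(
            "normal orientation probes uninformative; using polygon convention",
            stacklevel=2,
        )
    return cand


def detect_control_points(
    contour: Contour,
    kappa: np.ndarray,
    kappa_min: float,
    r: int,
    mask: np.ndarray | None = None,
    contour_id: int | None = None,
) -> list[ControlPoint]:
    """Select curvature peaks as control points, sorted by descending |kappa|.

    A point qualifies when |kappa| is a strict local maximum over the
    circular neighbourhood of +-r points and |kappa| >= kappa_min.  Each
    control point carries its outward normal and the flanking anchors.
    """
    a = np.abs(np.asarray(kappa, float))
    n = len(a)
    if n != len(contour):
        raise ValueError("curvature signal does not match contour length")
    is_peak = a >= kappa_min
    for off in range(1, min(r, n // 2) + 1):
        # strict toward lower indices, non-strict toward higher: a discrete
        # two-point plateau yields exactly one peak, a constant signal none
        is_peak &= (a > np.roll(a, off)) & (a >= np.roll(a, -off))
        if not is_peak.any():
            break
    cid = contour.component_id if contour_id is None else contour_id
    points: list[ControlPoint] = []
    for idx in np.flatnonzero(is_peak):
        try:
            li, ri = anchor_points(kappa, int(idx))
            nvec = outward_normal(contour, int(idx), mask)
        except ValueError:
            continue
        if np.allclose(contour.points[li], contour.points[ri]):
            continue
        points.append(
            ControlPoint(
                contour_id=cid,
                index=int(idx),
                location=contour.points[idx],
                outward_normal=nvec,
                anchor_left=contour.points[li],
                anchor_right=contour.points[ri],
                left_index=li,
                right_index=ri,
                kappa=float(kappa[idx]),
            )
        )
    points.sort(key=lambda cp: -abs(cp.kappa))
    return points
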