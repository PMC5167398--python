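"""Image orientation field, windowed orientation histograms and step direction.

The guiding signal for particle evolution is the *tangent field*: at every
pixel, the direction of the local iso-intensity line (the image gradient
rotated by 90 degrees), as an angle in [0, 2*pi).  Along a bright ribbon the
two edges have gradients pointing into the ribbon from opposite sides, so
their tangents are antipodal: a histogram of tangent angles over a window
straddling a leaf shows two dominant modes roughly pi apart, while textured
background contributes near-uniform counts.  Averaging one mode with the
reversal of the other yields the direction of travel along the leaf.

Angle convention: an angle theta corresponds to the unit vector
(cos theta, sin theta) in (row, col) components.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = [
    "OrientationField",
    "OrientationHistogram",
    "gaussian_smooth_image",
    "orientation_field",
    "orientation_histogram",
    "dominant_modes",
    "label_modes",
    "step_direction",
    "unit_vector",
]

TWO_PI = 2.0 * np.pi


def unit_vector(theta: float) -> np.ndarray:
    """Unit vector (row, col) for angle theta."""
    return np.array([np.cos(theta), np.sin(theta)])


@dataclass
class OrientationField:
    """Per-pixel edge-tangent angle and gradient magnitude."""

    theta: np.ndarray  # angles in [0, 2*pi)
    grad_mag: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.theta.shape


@dataclass
class OrientationHistogram:
    """Histogram of tangent angles inside one moving window."""

    counts: np.ndarray
    bin_width: float
    window_center: tuple[float, float]
    smoothed: bool = False

    @property
    def n_bins(self) -> int:
        return len(self.counts)

    def bin_of(self, theta: float) -> int:
        return int(np.floor((theta % TWO_PI) / self.bin_width)) % self.n_bins

    def bin_center(self, i: int) -> float:
        return (i + 0.5) * self.bin_width

    def count_at(self, theta: float) -> float:
        return float(self.counts[self.bin_of(theta)])


def gaussian_smooth_image(image: np.ndarray, sigma: float) -> np.ndarray:
    """Isotropic Gaussian smoothing with reflective boundary.

    A DC offset correction is applied after filtering so that the mean
    intensity is preserved exactly (reflective boundaries alone bias it by a
    tiny amount on finite images).
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    image = np.asarray(image, float)
    out = gaussian_filter(image, sigma, mode="reflect")
    return out + (image.mean() - out.mean())


def orientation_field(image: np.ndarray) -> OrientationField:
    """Edge-tangent angle and gradient magnitude at every pixel.

    Partial derivatives use central differences in the interior and
    single-sided differences at the image edges.  The tangent is the
    gradient rotated a quarter turn; where the gradient vanishes the angle
    is set to 0 and flagged unreliable via grad_mag = 0.
    """
    image = np.asarray(image, float)
    g_r = np.gradient(image, axis=0)
    g_c = np.gradient(image, axis=1)
    grad_mag = np.hypot(g_r, g_c)
    theta = np.arctan2(g_r, -g_c) % TWO_PI
    theta = np.where(grad_mag == 0, 0.0, theta)
    return OrientationField(theta=theta, grad_mag=grad_mag)


def orientation_histogram(
    field: OrientationField,
    center: tuple[float, float],
    w: int,
    n_bins: int,
    weight_by_gradient: bool = False,
) -> OrientationHistogram:
    """Histogram of tangent angles in the w x w window around ``center``.

    The window is clipped to the image; pixels with zero gradient magnitude
    carry no orientation information and are not counted.  The raw counts
    are circularly smoothed with a 3-bin moving average.
    """
    h, wid = field.shape
    r0 = int(round(center[0]))
    c0 = int(round(center[1]))
    half = w // 2
    r_lo, r_hi = max(0, r0 - half), min(h, r0 + half)
    c_lo, c_hi = max(0, c0 - half), min(wid, c0 + half)
    if r_lo >= r_hi or c_lo >= c_hi:
        raise ValueError("orientation window lies entirely outside the image")
    theta = field.theta[r_lo:r_hi, c_lo:c_hi]
    mag = field.grad_mag[r_lo:r_hi, c_lo:c_hi]
    valid = mag > 0
    bin_width = TWO_PI / n_bins
    bins = np.minimum((theta[valid] / bin_width).astype(int), n_bins - 1)
    weights = mag[valid] if weight_by_gradient else None
    counts = np.bincount(bins, weights=weights, minlength=n_bins).astype(float)
    # circular 3-bin moving average
    counts = (counts + np.roll(counts, 1) + np.roll(counts, -1)) / 3.0
    return OrientationHistogram(
        counts=counts,
        bin_width=bin_width,
        window_center=(float(center[0]), float(center[1])),
        smoothed=True,
    )


def dominant_modes(
    hist: OrientationHistogram, antipodal_tol: float = np.pi / 4
) -> tuple[float, float]:
    """Angles (bin centres) of the two dominant circular local maxima.

    The first mode is the largest local maximum.  The two modes are the
    tangents of *opposite leaf edges*, which are antipodal up to leaf
    curvature, so the second mode is the strongest local maximum within
    ``antipodal_tol`` of mode_a + pi; when none exists (a single free edge
    in the window) the exactly antipodal angle is returned.  This keeps
    unrelated structures at other orientations -- e.g. the end cap of a
    truncated object -- from hijacking the step direction.  An all-zero
    histogram raises ``ValueError``.
    """
    c = hist.counts
    if not np.any(c > 0):
        raise ValueError("all-zero orientation histogram: no orientation information")
    left, right = np.roll(c, 1), np.roll(c, -1)
    is_max = (c > left) & (c >= right) & (c > 0)
    idx = np.flatnonzero(is_max)
    if len(idx) == 0:  # plateaued histogram: fall back to global argmax
        idx = np.array([int(np.argmax(c))])
    order = idx[np.argsort(-c[idx], kind="stable")]
    a = int(order[0])
    mode_a = hist.bin_center(a)
    target = (mode_a + np.pi) % TWO_PI
    for b in order[1:]:
        angle = hist.bin_center(int(b))
        d = abs((angle - target + np.pi) % TWO_PI - np.pi)
        if d <= antipodal_tol:
            return mode_a, angle
    return mode_a, target


def label_modes(
    mode_a: float, mode_b: float, reference: np.ndarray
) -> tuple[float, float]:
    """Assign (theta1, theta2): theta2 is the mode differing most from ``reference``.

    The difference is the angle between unit vectors (smaller dot product =
    larger difference).  Ties keep mode_a as theta1.
    """
    ref = np.asarray(reference, float)
    dot_a = float(unit_vector(mode_a) @ ref)
    dot_b = float(unit_vector(mode_b) @ ref)
    if dot_a < dot_b:
        return mode_b, mode_a
    return mode_a, mode_b


def step_direction(mode_a: float, mode_b: float, reference: np.ndarray) -> np.ndarray:
    """Unit step vector from the two histogram modes and the travel reference.

    The mode pointing against the travel direction (theta2, the one whose
    direction differs most from ``reference``) is reversed, and the step is
    the angular mean of theta1 and the reversed theta2:
    theta_bar = (theta1 + theta2 + pi * sgn(theta1 - theta2)) / 2, sgn(0) = +1.
    """
    theta1, theta2 = label_modes(mode_a, mode_b, reference)
    sg = 1.0 if theta1 - theta2 >= 0 else -1.0
    theta_bar = (theta1 + theta2 + np.pi * sg) / 2.0
    return unit_vector(theta_bar)
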