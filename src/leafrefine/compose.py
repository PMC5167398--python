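"""Fusing converged snakes with the initial segmentation.

All plant boundaries -- the original contours plus the evolved snake
polylines -- are rasterized onto a blank grid, dilated by one pixel to close
sub-pixel gaps, flood-filled, eroded back, and unioned with the initial
mask.  Refinement therefore only ever adds or preserves foreground.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import binary_dilation, binary_erosion, binary_fill_holes
from skimage.draw import line

from .contours import Contour
from .evolution import EvolutionResult
from .snakes import SnakePair

__all__ = ["RefinementOutput", "compose_segmentation", "rasterize_polyline"]


@dataclass
class RefinementOutput:
    mask: np.ndarray
    snake_pairs: list[SnakePair] = field(default_factory=list)
    evolution_results: list[EvolutionResult] = field(default_factory=list)


def rasterize_polyline(points: np.ndarray, canvas: np.ndarray, closed: bool = False) -> None:
    """Draw a polyline onto a boolean canvas by nearest-pixel rounding.

    Consecutive rounded points are joined with Bresenham lines so the stroke
    has no gaps.  Out-of-bounds pixels are dropped.
    """
    h, w = canvas.shape
    pts = np.round(np.asarray(points, float)).astype(int)
    if closed and len(pts) > 1:
        pts = np.vstack([pts, pts[:1]])
    for (r0, c0), (r1, c1) in zip(pts[:-1], pts[1:]):
        rr, cc = line(r0, c0, r1, c1)
        ok = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
        canvas[rr[ok], cc[ok]] = True
    if len(pts) == 1:
        r0, c0 = pts[0]
        if 0 <= r0 < h and 0 <= c0 < w:
            canvas[r0, c0] = True


def compose_segmentation(
    initial: np.ndarray, pairs: list[SnakePair], contours: list[Contour]
) -> np.ndarray:
    """Improved binary mask from the initial mask, snakes and contours.

    The dilate-fill-erode sequence turns the rasterized boundary strokes
    into solid regions; a boundary chain that fails to enclose anything
    still contributes its stroke (with a warning).  The output is a
    superset of the initial mask.
    """
    initial = np.asarray(initial, bool)
    strokes = np.zeros_like(initial)
    for pair in pairs:
        # each pair forms a closed circuit: left snake, tail chord, right
        # snake reversed, head chord -- the region it bounds is the
        # recovered leaf material
        circuit = np.vstack(
            [pair.left.points, pair.right.points[::-1], pair.left.points[:1]]
        )
        rasterize_polyline(circuit, strokes)
    if not strokes.any():
        return initial.copy()
    se = np.ones((3, 3), bool)
    dilated = binary_dilation(strokes, se)
    filled = binary_fill_holes(dilated)
    if filled.sum() == dilated.sum() and pairs:
        warnings.warn(
            "boundary chains enclosed no region; strokes contribute alone",
            stacklevel=2,
        )
        return strokes | initial
    solid = binary_erosion(filled, se)
    return solid | initial
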