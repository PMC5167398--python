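"""Tunable parameters of the refinement algorithm.

All knobs that the method exposes live in :class:`RefinementConfig`.  The
defaults suit mid-resolution images (roughly 2000--2500 px on a side) with
leaves a few tens of pixels wide; for other resolutions scale ``m``, ``r``,
``w`` and ``sigma`` roughly proportionally to leaf width in pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml


@dataclass
class RefinementConfig:
    """Parameters controlling every stage of segmentation refinement.

    Parameters
    ----------
    m : int
        Width (pixels) of the square structuring element used to clean the
        initial mask by morphological opening.  Must be odd.
    r : int
        Radius (in contour points) of the Gaussian-weighted moving average
        applied to each object contour, and of the curvature-peak
        neighbourhood used for control-point selection.
    w : int
        Width (pixels) of the moving window used during particle evolution,
        and of the corner-search window.  Must be even; choose it large
        enough to contain background on both sides of a leaf but smaller
        than the spacing between leaves.
    sigma : float
        Standard deviation (pixels) of the isotropic Gaussian applied to the
        image before gradients are taken.  Over-smoothing is preferable to
        under-smoothing as long as leaf edges survive.
    alpha : float
        Snake length-penalty weight (dimensionless).
    lam : float
        Snake edge-attraction weight (dimensionless).
    epsilon : float
        Leaf-tip criterion: the particle stops when the (smoothed)
        orientation-histogram count at the travel mode drops to <= epsilon.
        Defaults to ``w / 4``.
    kappa_min : float
        Minimum |curvature| (1/pixel) for a contour point to qualify as a
        control point.
    max_steps : int
        Iteration cap for a single particle.  Defaults to
        ``4 * max(height, width)`` at run time when left at 0 -- a particle
        that has crossed the whole image several times has failed.
    n_bins : int
        Number of bins of the orientation histogram over [0, 2*pi).
    seed : int
        RNG seed for any stochastic component.
    weight_by_gradient : bool
        If True, histogram counts are weighted by gradient magnitude
        instead of counting each pixel once.  Off by default.
    """

    m: int = 5
    r: int = 10
    w: int = 20
    sigma: float = 1.0
    alpha: float = 7.0
    lam: float = 1000.0
    epsilon: float = -1.0  # sentinel: resolved to w/4
    kappa_min: float = 0.15
    max_steps: int = 0  # sentinel: resolved to 4*max(h, w) of the image
    n_bins: int = 90
    seed: int = 0
    weight_by_gradient: bool = field(default=False)

    def __post_init__(self) -> None:
        if self.epsilon < 0:
            self.epsilon = self.w / 4.0
        self.validate()

    def validate(self) -> None:
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if self.m % 2 == 0:
            raise ValueError("m must be odd (square element centred on a pixel)")
        if self.r < 1:
            raise ValueError("r must be >= 1")
        if self.w < 4:
            raise ValueError("w must be >= 4")
        if self.w % 2 != 0:
            raise ValueError("w must be even")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.alpha <= 0 or self.lam <= 0:
            raise ValueError("alpha and lam must be > 0")
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")
        if self.max_steps < 0:
            raise ValueError("max_steps must be >= 1 (or 0 for automatic)")
        if self.n_bins < 8:
            raise ValueError("n_bins must be >= 8")

    def resolved_max_steps(self, shape: tuple[int, int]) -> int:
        """Step budget for one particle (max_steps = 0 picks it automatically).

        A genuinely missed feature lies within a small fraction of the image
        of its control point (reported tip errors before refinement are a few
        percent of the image diagonal), so a particle that has walked a
        quarter of the image width has lost its way and only risks pairing
        snakes across unrelated structures.
        """
        if self.max_steps >= 1:
            return self.max_steps
        return max(64, max(shape) // 4)

    @classmethod
    def for_leaf_width(cls, leaf_width_px: float = 9.0, **overrides) -> "RefinementConfig":
        """Config scaled to the expected leaf width in pixels.

        The defaults above suit mid-resolution imagery; this constructor
        applies the scaling rules that govern the resolution-dependent
        parameters: the moving window spans about twice the leaf width (so
        it sees background on both sides of a leaf but not the neighbours),
        the contour-smoother radius is about half the leaf width, the
        curvature threshold is the reciprocal of the leaf width (half the
        curvature of a blunt leaf-end cap), and the tip threshold is half
        the window width (above the typical height of a spurious background
        orientation mode, below a genuine leaf-edge mode).
        """
        import math

        w = int(round(1.1 * leaf_width_px)) * 2
        params = dict(
            m=3,
            r=max(3, math.ceil(leaf_width_px / 2)),
            w=w,
            sigma=1.0,
            alpha=7.0,
            lam=1000.0,
            epsilon=w / 2.0,
            kappa_min=1.1 / leaf_width_px,
        )
        params.update(overrides)
        return cls(**params)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RefinementConfig":
        """Load a config from a YAML mapping of field names to values."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = {f.name: getattr(self, f.name) for f in fields(self)}
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)
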