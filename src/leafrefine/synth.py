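"""Synthetic plant scenes with ground truth, emulating thin-leaf failure modes.

Scenes contain a handful of thin, curved, tapering leaves fanning out from
a common base over a noisy background.  Two properties make a naive
threshold segmentation fail exactly the way colour-based segmenters fail on
real wheat:

* leaf intensity fades toward the tip (stressed/faint tips), so the
  thresholded mask terminates well short of the true tip;
* at a *twist* the apparent leaf width pinches to sub-pixel and the
  intensity drops (the leaf turns edge-on), so the thresholded mask splits
  one leaf into two disjoint fragments -- a breakage.

Ground truth (mask, per-leaf labels, tip coordinates) is exact because the
leaves are rendered analytically from parametric centerlines.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import binary_opening, gaussian_filter
from scipy.spatial import cKDTree

from . import io as lio

__all__ = ["LeafSpec", "SyntheticScene", "generate_scene", "degrade_to_initial_mask"]

BACKGROUND_MEAN = 0.35
LEAF_PEAK = 0.8


@dataclass
class LeafSpec:
    """Parametric description of one leaf ribbon.

    The centerline is a quadratic Bezier through ``control`` (3 points,
    (row, col)); ``base_width`` is the full width at the base in pixels;
    the width tapers linearly to ``taper`` * base_width at the tip.  At each
    arc-length fraction in ``twist_positions`` the width pinches to
    sub-pixel and the intensity dips (a twist).  Intensity is
    ``peak_intensity`` until ``fade_start``, then decays linearly to
    ``fade_end_intensity`` at the tip.
    """

    control: np.ndarray  # (3, 2) Bezier control points
    base_width: float = 9.0
    taper: float = 0.25
    twist_positions: list[float] = field(default_factory=list)
    peak_intensity: float = LEAF_PEAK
    fade_start: float = 0.6
    fade_end_intensity: float = 0.47
    twist_sigma: float = 0.015  # arc-length fraction
    twist_intensity: float = 0.47  # brightness of the edge-on sliver at a twist

    def __post_init__(self) -> None:
        self.control = np.asarray(self.control, float)
        if self.base_width < 3:
            raise ValueError("base_width must be >= 3 px")
        if not all(0 < t < 1 for t in self.twist_positions):
            raise ValueError("twist positions must lie in (0, 1)")
        if not 0 < self.fade_start <= 1:
            raise ValueError("fade_start must lie in (0, 1]")

    def sample(self, spacing: float = 0.35) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Centerline samples: positions, half-widths, pinched half-widths, intensities."""
        t = np.linspace(0.0, 1.0, 64)
        p = (
            (1 - t)[:, None] ** 2 * self.control[0]
            + 2 * (t * (1 - t))[:, None] * self.control[1]
            + t[:, None] ** 2 * self.control[2]
        )
        seg = np.linalg.norm(np.diff(p, axis=0), axis=1)
        arc = np.concatenate([[0.0], np.cumsum(seg)])
        total = arc[-1]
        n = max(int(round(total / spacing)) + 1, 8)
        s_arc = np.linspace(0.0, total, n)
        t_fine = np.interp(s_arc, arc, t)
        pos = (
            (1 - t_fine)[:, None] ** 2 * self.control[0]
            + 2 * (t_fine * (1 - t_fine))[:, None] * self.control[1]
            + t_fine[:, None] ** 2 * self.control[2]
        )
        s = s_arc / max(total, 1e-9)  # arc-length fraction
        half = 0.5 * self.base_width * (1.0 - (1.0 - self.taper) * s)
        # the pinch leaves a faint ~2 px sliver (the leaf seen edge-on),
        # which breaks a threshold segmentation but keeps the orientation
        # field informative across the twist
        pinch = np.ones_like(s)
        for ts in self.twist_positions:
            pinch *= 1.0 - 0.8 * np.exp(-((s - ts) ** 2) / (2 * self.twist_sigma**2))
        intensity = np.full_like(s, self.peak_intensity)
        fading = s > self.fade_start
        frac = (s[fading] - self.fade_start) / max(1.0 - self.fade_start, 1e-9)
        intensity[fading] = self.peak_intensity + frac * (
            self.fade_end_intensity - self.peak_intensity
        )
        # the intensity also dips through a twist (leaf turns edge-on)
        for ts in self.twist_positions:
            dip = np.exp(-((s - ts) ** 2) / (2 * (2 * self.twist_sigma) ** 2))
            intensity = intensity * (1 - dip) + self.twist_intensity * dip
        return pos, half, half * pinch, intensity


@dataclass
class SyntheticScene:
    image: np.ndarray
    gt_mask: np.ndarray
    leaf_labels: np.ndarray
    tips: np.ndarray
    initial_mask: np.ndarray | None = None
    leaves: list[LeafSpec] = field(default_factory=list)

    def export(self, out_dir: str | Path, prefix: str = "scene") -> dict[str, Path]:
        """Write the standard file set (image, gt, labels, tips, initial)."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "image": out / f"{prefix}_image.png",
            "gt": out / f"{prefix}_gt.png",
            "labels": out / f"{prefix}_labels.png",
            "tips": out / f"{prefix}_tips.csv",
        }
        import imageio.v3 as iio

        iio.imwrite(paths["image"], np.round(self.image * 255).astype(np.uint8))
        lio.write_mask(self.gt_mask, paths["gt"])
        lio.write_labels(self.leaf_labels, paths["labels"])
        lio.write_tips(self.tips, paths["tips"])
        if self.initial_mask is not None:
            paths["initial"] = out / f"{prefix}_initial.png"
            lio.write_mask(self.initial_mask, paths["initial"])
        return paths


def _random_leaves(
    rng: np.random.Generator, n_leaves: int, size: tuple[int, int]
) -> list[LeafSpec]:
    h, w = size
    margin = 24.0
    base = np.array([h - margin - rng.uniform(0, 20), w / 2 + rng.uniform(-40, 40)])
    leaves = []
    # evenly fanned about vertical-up with jitter, so leaves never coincide
    spread = np.linspace(-1.0, 1.0, n_leaves) if n_leaves > 1 else np.array([0.0])
    angles = np.sort(spread + rng.normal(0, 0.06, n_leaves))
    twist_leaves = set(
        rng.choice(n_leaves, size=max(1, n_leaves // 3), replace=False).tolist()
    )
    for i in range(n_leaves):
        ang = angles[i] + rng.normal(0, 0.08)
        length = rng.uniform(0.45, 0.72) * min(h, w)
        direction = np.array([-np.cos(ang), np.sin(ang)])  # upward fan
        # shrink the leaf (never bend it) so the whole curve stays in-canvas
        for axis, lim in ((0, h), (1, w)):
            if direction[axis] != 0:
                room_lo = (margin - base[axis]) / direction[axis]
                room_hi = (lim - margin - base[axis]) / direction[axis]
                room = max(room_lo, room_hi)
                length = min(length, room)
        length = max(length, 60.0)
        tip = base + length * direction
        bow = rng.uniform(-0.2, 0.2) * length
        perp = np.array([-direction[1], direction[0]])
        mid = (base + tip) / 2 + bow * perp
        mid = np.clip(mid, margin, [h - margin, w - margin])
        twists = [float(rng.uniform(0.38, 0.55))] if i in twist_leaves else []
        leaves.append(
            LeafSpec(
                control=np.array([base, mid, tip]),
                base_width=float(rng.uniform(7.0, 11.0)),
                taper=0.25,
                twist_positions=twists,
                fade_start=float(rng.uniform(0.55, 0.65)),
                fade_end_intensity=float(rng.uniform(0.45, 0.49)),
            )
        )
    return leaves


def generate_scene(
    n_leaves: int = 4,
    size: tuple[int, int] = (512, 512),
    seed: int = 0,
    noise_std: float = 0.03,
    texture: bool = False,
    leaves: list[LeafSpec] | None = None,
    initial_threshold: float | None = 0.55,
    crown: bool = True,
) -> SyntheticScene:
    """Render a deterministic synthetic plant scene with ground truth.

    Leaves (anti-aliased ribbons, peak intensity 0.8, fading tips, pinched
    twists) are composited over a background of mean 0.35 with Gaussian
    noise of std ``noise_std`` (optionally plus low-frequency "coarse soil"
    texture).  Tips are the free centerline endpoints.  When
    ``initial_threshold`` is set the degraded initial mask is attached.
    """
    if n_leaves < 1:
        raise ValueError("n_leaves must be >= 1")
    if size[0] < 128 or size[1] < 128:
        raise ValueError("size must be at least 128 x 128")
    rng = np.random.default_rng(seed)
    if leaves is None:
        leaves = _random_leaves(rng, n_leaves, size)

    h, w = size
    image = np.full(size, BACKGROUND_MEAN)
    if texture:
        soil = gaussian_filter(rng.normal(0, 1, size), 6)
        soil /= max(np.abs(soil).max(), 1e-9)
        image = image + 0.1 * soil
    gt = np.zeros(size, bool)
    labels = np.zeros(size, np.int32)
    tips = []

    rows, cols = np.mgrid[0:h, 0:w]

    if crown:
        # solid disc at the common leaf base (plant stem cluster); it keeps
        # the junctions between adjacent leaves gently curved, as in real shoots
        base_pts = np.array([leaf.control[0] for leaf in leaves])
        center = base_pts.mean(axis=0)
        crown_r = 1.4 * max(leaf.base_width for leaf in leaves)
        d_crown = np.hypot(rows - center[0], cols - center[1])
        cov_crown = np.clip(crown_r + 0.5 - d_crown, 0.0, 1.0)
        image = np.maximum(image, (1 - cov_crown) * image + cov_crown * LEAF_PEAK)
        gt |= d_crown <= crown_r

    for li, leaf in enumerate(leaves, start=1):
        pos, half, half_pinched, intensity = leaf.sample()
        pad = half.max() + 2.0
        r_lo = max(0, int(pos[:, 0].min() - pad))
        r_hi = min(h, int(pos[:, 0].max() + pad) + 1)
        c_lo = max(0, int(pos[:, 1].min() - pad))
        c_hi = min(w, int(pos[:, 1].max() + pad) + 1)
        pr = rows[r_lo:r_hi, c_lo:c_hi].ravel()
        pc = cols[r_lo:r_hi, c_lo:c_hi].ravel()
        pix = np.column_stack([pr, pc]).astype(float)
        d, idx = cKDTree(pos).query(pix)
        # anti-aliased coverage from the (pinched) width profile
        cov = np.clip(half_pinched[idx] + 0.5 - d, 0.0, 1.0)
        val = intensity[idx]
        flat = np.flatnonzero(cov > 0)
        rr, cc = pr[flat], pc[flat]
        blend = (1 - cov[flat]) * image[rr, cc] + cov[flat] * val[flat]
        image[rr, cc] = np.maximum(image[rr, cc], blend)
        # ground truth keeps a >= 1 px bridge through twists
        inside = d <= np.maximum(half[idx], 0.6)
        gt[pr[inside], pc[inside]] = True
        labels[pr[inside], pc[inside]] = li
        tips.append(pos[-1])

    image = np.clip(image + rng.normal(0.0, noise_std, size), 0.0, 1.0)
    scene = SyntheticScene(
        image=image,
        gt_mask=gt,
        leaf_labels=labels,
        tips=np.array(tips),
        leaves=list(leaves),
    )
    if initial_threshold is not None:
        scene.initial_mask = degrade_to_initial_mask(scene, initial_threshold)
    return scene


def degrade_to_initial_mask(scene: SyntheticScene, threshold: float = 0.55) -> np.ndarray:
    """Threshold-and-open initial segmentation that misses tips and twists.

    Pixels with intensity >= threshold, opened with a 3 x 3 element.  By
    construction this loses the faded tips and splits leaves at pinched
    twists, emulating colour-based segmentation failure.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    if threshold <= BACKGROUND_MEAN + 0.09:
        import warnings

        warnings.warn(
            "threshold close to the background level: initial mask will be noise",
            stacklevel=2,
        )
    raw = scene.image >= threshold
    return binary_opening(raw, np.ones((3, 3), bool))
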