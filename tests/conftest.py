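"""Shared fixture builders: parametric leaf scenes with exact ground truth."""

import numpy as np
import pytest

from leafrefine.config import RefinementConfig
from leafrefine.synth import LeafSpec, generate_scene


def straight_leaf(
    start,
    end,
    width=7.0,
    taper=1.0,
    fade_start=1.0,
    fade_end=0.5,
    twists=(),
    twist_intensity=0.47,
):
    """A straight ribbon LeafSpec from start to end (row, col)."""
    start = np.asarray(start, float)
    end = np.asarray(end, float)
    return LeafSpec(
        control=np.array([start, (start + end) / 2.0, end]),
        base_width=width,
        taper=taper,
        fade_start=fade_start,
        fade_end_intensity=fade_end,
        twist_positions=list(twists),
        twist_intensity=twist_intensity,
    )


def ribbon_scene(phi_deg, width=7.0, size=192, seed=7, fade_start=0.5, half_len=70.0):
    """A single straight fading ribbon through the canvas centre at phi_deg.

    Returns (scene, spec); the true tip is spec.control[2] and the initial
    mask terminates short of it because the intensity fades below the
    segmentation threshold.
    """
    a = np.deg2rad(phi_deg)
    c = np.array([size / 2.0, size / 2.0])
    d = np.array([np.cos(a), np.sin(a)])
    spec = straight_leaf(
        c - half_len * d, c + half_len * d, width=width, fade_start=fade_start
    )
    scene = generate_scene(leaves=[spec], size=(size, size), seed=seed, crown=False)
    return scene, spec


def crossing_scene(size=176, seed=11):
    """Bright horizontal leaf A truncated in the mask before vertical leaf B.

    The image shows A all the way through B; the initial mask of A stops at
    col 111, so its end-cap particle travels along strong edges and enters
    B's contour far from B's control points (an intersection, not a twist).
    Returns (scene, initial_mask).
    """
    A = straight_leaf([90.0, 10.0], [90.0, 150.0], width=7)
    B = straight_leaf([20.0, 136.0], [150.0, 136.0], width=7)
    scene = generate_scene(leaves=[A, B], size=(size, size), seed=seed, crown=False)
    initial = scene.initial_mask.copy()
    initial[80:101, 112:133] = False  # truncate A before B's near edge
    initial[80:101, 140:176] = False  # remove A's stub beyond B
    return scene, initial


def twist_scene(width=10.0, size=176, seed=12):
    """A single diagonal leaf pinched at mid-length: one true leaf, two mask
    fragments."""
    spec = straight_leaf(
        [150.0, 30.0], [30.0, 146.0], width=width, twists=(0.5,)
    )
    scene = generate_scene(leaves=[spec], size=(size, size), seed=seed, crown=False)
    return scene, spec


def axil_scene(size=192, seed=13):
    """Two arms of a deep V with the notch over-filled down to a concave cut.

    Returns (scene, initial_mask, cut_point, true_vertex): the initial mask
    covers the notch below the cut, the axil vertex (where the arms' inner
    edges meet) lies inside that wrongly-filled region.
    """
    v = np.array([150.0, 88.0])
    slope = 30.0 / 130.0
    L1 = straight_leaf(v, v + [-130.0, -30.0], width=8)
    L2 = straight_leaf(v, v + [-130.0, 30.0], width=8)
    scene = generate_scene(leaves=[L1, L2], size=(size, size), seed=seed, crown=False)
    rows, cols = np.mgrid[0:size, 0:size].astype(float)
    in_notch = (
        (np.abs(cols - 88) <= (150 - rows) * slope - 2.0) & (rows < 150) & (rows > 60)
    )
    cut = rows >= 120 - 0.5 * np.abs(cols - 88)  # concave dip deepest on the axis
    initial = scene.initial_mask | (in_notch & cut)
    vertex = np.array([150.0 - 8.0 / (2 * slope), 88.0])
    return scene, initial, np.array([120.0, 88.0]), vertex


def circle_contour_points(radius, n=400, center=(0.0, 0.0)):
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.column_stack(
        [center[0] + radius * np.cos(t), center[1] + radius * np.sin(t)]
    )


@pytest.fixture(scope="session")
def study_config():
    """Configuration scaled to the synthetic scenes' ~9 px leaves."""
    return RefinementConfig.for_leaf_width(9.0)


@pytest.fixture(scope="session")
def small_scene():
    """One deterministic 4-leaf scene with its degraded initial mask."""
    return generate_scene(n_leaves=4, seed=0)
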