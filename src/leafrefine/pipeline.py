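"""End-to-end segmentation refinement orchestration.

``refine`` wires the full method together: clean the initial mask, extract
and smooth contours, select curvature control points, evolve each as a
particle over the orientation field, localize tip/axil corners, build and
evolve the snake pair, and compose the improved mask.  A failure at any
single control point is logged and skipped; it never aborts the run.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .compose import RefinementOutput, compose_segmentation
from .config import RefinementConfig
from .contours import (
    Contour,
    ControlPoint,
    clean_mask,
    contour_curvature,
    detect_control_points,
    extract_contours,
    smooth_contour,
)
from .corners import harris_response, locate_feature_corner
from .evolution import EvolutionResult, StopReason, evolve_particle
from .orientation import gaussian_smooth_image, orientation_field
from .snakes import evolve_snake, external_energy, initialize_snake_pair

logger = logging.getLogger("leafrefine")

__all__ = ["RunManifest", "refine"]


@dataclass
class RunManifest:
    """Per-stage counts and configuration of one refinement run."""

    config: RefinementConfig
    n_contours: int = 0
    n_control_points: int = 0
    stop_reason_counts: dict = field(default_factory=dict)
    n_snakes_converged: int = 0
    n_skipped: int = 0
    log: list = field(default_factory=list)

    def record(self, stage: str, detail: str) -> None:
        self.log.append(f"{stage}: {detail}")
        logger.info("%s: %s", stage, detail)


def _max_drift(evolved: np.ndarray, initial: np.ndarray) -> float:
    """Largest distance from an evolved snake point to the initial polyline."""
    from scipy.spatial import cKDTree

    return float(np.max(cKDTree(initial).query(evolved)[0]))


def refine(
    image: np.ndarray,
    initial: np.ndarray,
    cfg: RefinementConfig | None = None,
) -> tuple[RefinementOutput, RunManifest]:
    """Refine an inaccurate binary segmentation of a thin-leaved plant.

    Returns the improved mask together with the snake pairs and particle
    paths that produced it, plus a manifest of per-stage counts.  The
    output mask is always a superset of ``initial``.
    """
    cfg = cfg or RefinementConfig()
    image = np.asarray(image, float)
    initial = np.asarray(initial, bool)
    if image.shape != initial.shape:
        raise ValueError(f"image {image.shape} and mask {initial.shape} shapes differ")
    manifest = RunManifest(config=cfg)

    cleaned = clean_mask(initial, cfg.m)
    contours = extract_contours(cleaned)
    manifest.n_contours = len(contours)
    manifest.record("contours", f"{len(contours)} object contours")

    smoothed_contours: list[Contour] = []
    control_points: list[ControlPoint] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for c in contours:
            sm = smooth_contour(c, cfg.r)
            smoothed_contours.append(sm)
            kappa = contour_curvature(sm)
            control_points.extend(
                detect_control_points(sm, kappa, cfg.kappa_min, cfg.r, mask=cleaned)
            )
    control_points.sort(key=lambda cp: -abs(cp.kappa))
    manifest.n_control_points = len(control_points)
    manifest.record("control_points", f"{len(control_points)} candidates")

    smooth_img = gaussian_smooth_image(image, cfg.sigma)
    field_ = orientation_field(smooth_img)
    harris = harris_response(smooth_img)
    energy = external_energy(image, cfg.sigma)

    contour_by_id = {c.component_id: c for c in smoothed_contours}
    from matplotlib.path import Path as MplPath

    paths = {c.component_id: MplPath(c.points) for c in smoothed_contours}

    counts = {r.value: 0 for r in StopReason}
    results: list[EvolutionResult] = []
    pairs = []
    for cp in control_points:
        try:
            res = evolve_particle(
                cp,
                field_,
                smoothed_contours,
                cleaned,
                cfg,
                control_points=control_points,
                contour_by_id=contour_by_id,
                paths=paths,
            )
            results.append(res)
            counts[res.stop_reason.value] += 1
            if res.stop_reason == StopReason.ABORTED:
                continue
            corner = None
            if res.stop_reason in (StopReason.TIP, StopReason.AXIL):
                corner = locate_feature_corner(
                    harris, tuple(res.terminal_point), cfg.w
                )
            pair = initialize_snake_pair(res, corner, cfg, contours=smoothed_contours)
            init_left = pair.left.points.copy()
            init_right = pair.right.points.copy()
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                pair.left = evolve_snake(pair.left, energy, cfg.alpha, cfg.lam)
                pair.right = evolve_snake(pair.right, energy, cfg.alpha, cfg.lam)
            # snakes refine locally; one that drifted far off its
            # initialization latched onto an unrelated edge -- discard it
            drift = max(
                _max_drift(pair.left.points, init_left),
                _max_drift(pair.right.points, init_right),
            )
            if drift > cfg.w / 2.0:
                manifest.n_skipped += 1
                manifest.record(
                    "skip", f"snake pair drifted {drift:.1f} px from initialization"
                )
                continue
            pairs.append(pair)
            manifest.n_snakes_converged += 2
        except Exception as exc:  # per-control-point fault isolation
            manifest.n_skipped += 1
            manifest.record(
                "skip", f"control point on contour {cp.contour_id} @ {cp.index}: {exc}"
            )
    manifest.stop_reason_counts = counts
    manifest.record("evolution", f"stop reasons {counts}")

    improved = compose_segmentation(initial, pairs, smoothed_contours)
    manifest.record("compose", f"{len(pairs)} snake pairs composed")
    return (
        RefinementOutput(mask=improved, snake_pairs=pairs, evolution_results=results),
        manifest,
    )
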