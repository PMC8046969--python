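"""Toy two-photon-like stacks with exact ground truth.

Real acute-brain-slice stacks cannot be redistributed, so this module
renders miniature stand-ins with the same structure: a noisy background,
blob-like somata of varying brightness placed on different z-planes,
depth-dependent dimming, and - crucially - only a fraction of the somata
"manually" annotated, emulating the incomplete human labeling the synthetic
data generator exists to work around.  Every generated soma carries an
exact polygonal contour, so the other modules can be tested end to end
without any external data.

Somata are modeled as Gaussian-blurred ellipses: the simplest shape family
that yields smooth boundaries while keeping an exact mask (the blurred
profile thresholded at half its peak) and hence an exact contour.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import asdict, dataclass

import numpy as np
from scipy import ndimage

from .errors import PlacementError
from .io_formats import AnnotationSet, ImageStack, SomaAnnotation, trace_boundary

logger = logging.getLogger(__name__)

__all__ = ["FixtureConfig", "make_toy_stack", "make_paired_protocols"]


@dataclass(frozen=True)
class FixtureConfig:
    """Geometry and photometry of one toy corpus; a pure function input."""

    image_size: tuple[int, int] = (64, 64)
    n_planes: int = 5
    z_step_um: float = 2.0
    pixel_size_um: float = 1.0
    n_somata: int = 8
    radius_range_px: tuple[float, float] = (3.0, 6.0)
    intensity_range: tuple[float, float] = (120.0, 220.0)
    background_mean: float = 20.0
    background_noise_sigma: float = 3.0
    depth_dimming: float = 0.05  # linear attenuation per plane
    annotated_fraction: float = 0.6
    blur_sigma: float = 1.0
    seed: int = 0

    def imaging_params(self) -> dict:
        d = asdict(self)
        d.pop("seed")
        return d


def _render_soma(
    shape: tuple[int, int],
    center: tuple[float, float],
    radii: tuple[float, float],
    angle: float,
    blur_sigma: float,
) -> tuple[np.ndarray, np.ndarray]:
    """(soft profile in [0, 1], exact truth mask) for one ellipse."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    dx, dy = xx - center[0], yy - center[1]
    u = dx * math.cos(angle) + dy * math.sin(angle)
    v = -dx * math.sin(angle) + dy * math.cos(angle)
    hard = (u / radii[0]) ** 2 + (v / radii[1]) ** 2 <= 1.0
    soft = ndimage.gaussian_filter(hard.astype(float), blur_sigma)
    peak = soft.max()
    if peak <= 0:
        return soft, hard
    mask = soft >= 0.5 * peak
    return soft / peak, mask


def make_toy_stack(
    config: FixtureConfig, image_id: str = "toy"
) -> tuple[ImageStack, AnnotationSet, AnnotationSet]:
    """Render one stack plus full (``truth``) and partial annotations.

    ``truth`` holds every soma's exact contour; ``partial`` is a seeded
    random subset of ``ceil(annotated_fraction * n_somata)`` of them,
    emulating incomplete human labeling.  Soma cores are pairwise disjoint
    across all planes (with a 2 px guard band) so maximum projections keep
    instances separable.
    """
    rng = np.random.default_rng(config.seed)
    h, w = config.image_size
    planes = np.clip(
        rng.normal(
            config.background_mean, config.background_noise_sigma,
            (config.n_planes, h, w),
        ),
        0, None,
    )
    occupancy = np.zeros((h, w), dtype=bool)
    truth = AnnotationSet()
    r_lo, r_hi = config.radius_range_px
    margin = r_hi + 3 * config.blur_sigma
    placed = 0
    tries_budget = 200 * max(config.n_somata, 1)
    while placed < config.n_somata:
        if tries_budget <= 0:
            raise PlacementError(
                f"could only place {placed}/{config.n_somata} somata; "
                "config too crowded"
            )
        tries_budget -= 1
        center = (
            float(rng.uniform(margin, w - margin)),
            float(rng.uniform(margin, h - margin)),
        )
        radii = (float(rng.uniform(r_lo, r_hi)), float(rng.uniform(r_lo, r_hi)))
        angle = float(rng.uniform(0, math.pi))
        plane = int(rng.integers(config.n_planes))
        soft, mask = _render_soma((h, w), center, radii, angle, config.blur_sigma)
        guard = ndimage.binary_dilation(mask, iterations=2)
        if (guard & occupancy).any() or not mask.any():
            continue
        occupancy |= guard
        dimming = max(0.0, 1.0 - config.depth_dimming * plane)
        peak = float(rng.uniform(*config.intensity_range)) * dimming
        planes[plane] += peak * soft
        truth.add(
            image_id,
            SomaAnnotation(
                contour=trace_boundary(mask),
                region_id=f"{image_id}_s{placed:03d}",
                plane_index=plane,
                annotator_id="truth",
                mask=mask,
            ),
        )
        placed += 1
    stack = ImageStack(
        planes, config.pixel_size_um, config.z_step_um, source_id=image_id
    )
    pool = list(truth.regions())
    k = math.ceil(config.annotated_fraction * len(pool)) if pool else 0
    keep = sorted(rng.choice(len(pool), size=k, replace=False)) if k else []
    partial = AnnotationSet()
    for i in keep:
        img, ann = pool[i]
        partial.add(img, ann)
    return stack, truth, partial


def make_paired_protocols(
    config_a: FixtureConfig,
    config_b: FixtureConfig,
    n_images: int = 2,
) -> tuple[list, list]:
    """Two corpora emulating acquisition on two different microscopes.

    Each corpus is a list of ``(stack, truth, partial)`` triples; the two
    configs should differ in at least one imaging parameter (noise,
    brightness, soma scale), otherwise the cross-protocol experiment is
    degenerate and a warning is issued.  Seeds are made disjoint across the
    corpora.
    """
    if config_a.imaging_params() == config_b.imaging_params():
        warnings.warn(
            "paired protocols have identical imaging parameters; the "
            "cross-protocol experiment is degenerate",
            stacklevel=2,
        )

    def corpus(config: FixtureConfig, tag: str, offset: int) -> list:
        out = []
        for i in range(n_images):
            sub = FixtureConfig(
                **{**asdict(config), "seed": offset + 2 * i + config.seed * 4096}
            )
            out.append(make_toy_stack(sub, image_id=f"{tag}_{i:02d}"))
        return out

    return corpus(config_a, "A", 0), corpus(config_b, "B", 1)
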