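"""Stack-to-model-input preprocessing chain.

The manual contouring workflow the package mirrors works on z-stacks that
are background-subtracted, median filtered plane by plane, and collapsed
into maximum-intensity projections every 10 um of depth.  Before feeding a
projection to the segmentation model it is contrast-normalized with CLAHE,
resized (aspect preserving, zero padded) to the model's square input size
and replicated onto three identical channels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import exposure, transform

from .errors import EstimationError
from .io_formats import AnnotationSet, ImageStack

logger = logging.getLogger(__name__)

__all__ = [
    "Projection",
    "ModelInput",
    "subtract_background",
    "estimate_background_level",
    "median_filter_planes",
    "max_project",
    "clahe_normalize",
    "prepare_model_input",
    "preprocess_stack",
]


@dataclass
class Projection:
    """A maximum-intensity projection over a contiguous run of planes."""

    image: np.ndarray
    source_planes: tuple[int, int]  # half-open [start, stop) plane indices
    pixel_size_um: float
    source_id: str = ""


@dataclass
class ModelInput:
    """Square 3-channel model frame plus the mapping back to native pixels.

    ``scale_factor = size / max(origin_shape)``; the resized image sits at
    the top-left of the square frame with zero padding on the short side, so
    native ``(x, y)`` maps to model ``(x, y) * scale_factor``.
    """

    image: np.ndarray  # (size, size, 3), float32 in [0, 1]
    scale_factor: float
    origin_shape: tuple[int, int]

    @property
    def size(self) -> int:
        return self.image.shape[0]

    def map_to_model(self, xy: np.ndarray) -> np.ndarray:
        return np.asarray(xy, dtype=float) * self.scale_factor

    def map_to_native(self, xy: np.ndarray) -> np.ndarray:
        return np.asarray(xy, dtype=float) / self.scale_factor

    def mask_to_native(self, mask: np.ndarray) -> np.ndarray:
        """Map a boolean mask in the model frame back to native pixels."""
        h, w = self.origin_shape
        mh = max(1, round(h * self.scale_factor))
        mw = max(1, round(w * self.scale_factor))
        cropped = mask[:mh, :mw]
        return (
            transform.resize(
                cropped.astype(float), (h, w), order=0, anti_aliasing=False
            )
            > 0.5
        )

    def mask_to_model(self, mask: np.ndarray) -> np.ndarray:
        """Forward-map a native-frame boolean mask into the model frame."""
        h, w = self.origin_shape
        mh = max(1, round(h * self.scale_factor))
        mw = max(1, round(w * self.scale_factor))
        out = np.zeros((self.size, self.size), dtype=bool)
        out[:mh, :mw] = (
            transform.resize(
                np.asarray(mask, dtype=float), (mh, mw), order=0,
                anti_aliasing=False,
            )
            > 0.5
        )
        return out


def subtract_background(stack: ImageStack, level: float) -> ImageStack:
    """Subtract a constant background level from every pixel, clamped at 0."""
    if not np.isfinite(level) or level < 0:
        raise ValueError("background level must be finite and >= 0")
    planes = np.clip(stack.planes.astype(float) - level, 0, None)
    return ImageStack(planes, stack.pixel_size_um, stack.z_step_um, stack.source_id)


def estimate_background_level(
    stack: ImageStack,
    annotations: AnnotationSet | None = None,
    percentile: float = 50.0,
) -> float:
    """Estimate the background as a percentile of unannotated pixels.

    The default (median) is robust to the sparse bright somata that remain
    unannotated; pixels inside any annotation mask are excluded on every
    plane.
    """
    h, w = stack.plane_shape
    excluded = np.zeros((h, w), dtype=bool)
    if annotations is not None:
        for _img, ann in annotations.regions():
            excluded |= ann.get_mask((h, w))
    free = ~excluded
    if not free.any():
        raise EstimationError("every pixel is annotated; no background left")
    return float(np.percentile(stack.planes[:, free], percentile))


def median_filter_planes(stack: ImageStack, kernel: int = 3) -> ImageStack:
    """2-D median filter each plane independently (reflective padding)."""
    if kernel < 1 or kernel % 2 == 0:
        raise ValueError("kernel must be an odd integer >= 1")
    if kernel == 1:
        return ImageStack(
            stack.planes.copy(), stack.pixel_size_um, stack.z_step_um,
            stack.source_id,
        )
    planes = np.stack(
        [
            ndimage.median_filter(p, size=kernel, mode="reflect")
            for p in stack.planes
        ]
    )
    return ImageStack(planes, stack.pixel_size_um, stack.z_step_um, stack.source_id)


def max_project(stack: ImageStack, window_um: float = 10.0) -> list[Projection]:
    """Maximum-intensity projections over contiguous depth windows.

    Planes are grouped into consecutive, non-overlapping windows of
    ``floor(window_um / z_step_um)`` planes (10 um of depth at a 2 um z-step
    gives 5-plane groups); a trailing partial window is kept.
    """
    if window_um < stack.z_step_um:
        raise ValueError("projection window must cover at least one z-step")
    group = int(window_um // stack.z_step_um)
    out = []
    for start in range(0, stack.n_planes, group):
        stop = min(start + group, stack.n_planes)
        out.append(
            Projection(
                image=stack.planes[start:stop].max(axis=0),
                source_planes=(start, stop),
                pixel_size_um=stack.pixel_size_um,
                source_id=f"{stack.source_id}_z{start:03d}",
            )
        )
    return out


def clahe_normalize(
    image: np.ndarray,
    clip_limit: float = 0.01,
    tile_grid: tuple[int, int] = (8, 8),
) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization.

    ``clip_limit`` is the clipping fraction in [0, 1] (scikit-image
    convention); ``tile_grid`` is the number of contextual tiles per axis.
    The output is rescaled to the input's value range so downstream code can
    keep treating intensities uniformly; a constant image is returned
    unchanged since it has no contrast to redistribute.
    """
    if clip_limit <= 0:
        raise ValueError("clip_limit must be > 0")
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError("expected a 2-D image")
    lo, hi = float(image.min()), float(image.max())
    if lo < 0:
        raise ValueError("intensities must be non-negative")
    if hi == lo:
        return image.astype(float).copy()
    kernel = (
        max(1, image.shape[0] // tile_grid[0]),
        max(1, image.shape[1] // tile_grid[1]),
    )
    normalized = (image.astype(float) - lo) / (hi - lo)
    eq = exposure.equalize_adapthist(
        normalized, kernel_size=kernel, clip_limit=clip_limit
    )
    return eq * (hi - lo) + lo


def prepare_model_input(image: np.ndarray, size: int = 1024) -> ModelInput:
    """Resize a 2-D image into the model's square 3-channel frame.

    The resize is aspect preserving (bilinear) with zero padding on the
    short side; the recorded ``scale_factor`` allows exact inverse mapping
    of detected contours back to native coordinates.  Intensities are
    rescaled to [0, 1] floats.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or image.size == 0:
        raise ValueError("expected a non-empty 2-D image")
    h, w = image.shape
    scale = size / max(h, w)
    mh, mw = max(1, round(h * scale)), max(1, round(w * scale))
    hi = image.max()
    norm = image / hi if hi > 0 else image
    if (mh, mw) == (h, w):
        resized = norm
    else:
        resized = transform.resize(
            norm, (mh, mw), order=1, anti_aliasing=scale < 1, mode="constant"
        )
    frame = np.zeros((size, size), dtype=np.float32)
    frame[:mh, :mw] = resized
    return ModelInput(
        image=np.repeat(frame[:, :, None], 3, axis=2),
        scale_factor=scale,
        origin_shape=(h, w),
    )


def preprocess_stack(
    stack: ImageStack,
    annotations: AnnotationSet | None = None,
    background_level: float | None = None,
    median_kernel: int = 3,
    window_um: float = 10.0,
) -> list[Projection]:
    """Full manual-pipeline chain: subtract, filter, project.

    ``background_level=None`` estimates the level from unannotated pixels.
    """
    if background_level is None:
        background_level = estimate_background_level(stack, annotations)
        logger.info("estimated background level %.2f", background_level)
    cleaned = subtract_background(stack, background_level)
    filtered = median_filter_planes(cleaned, median_kernel)
    return max_project(filtered, window_um)
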