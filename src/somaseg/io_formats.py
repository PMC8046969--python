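"""Image stacks, soma contours and the ImageJ ROI container format.

Stacks are multi-page grayscale TIFFs (two-photon z-stacks: 512x512 planes
acquired every 2 um in depth are the typical case).  Annotations are closed
polygon contours around neuronal cell bodies, exchanged with ImageJ through
its binary ``.roi`` record format (one record per contour, zipped when there
is more than one).

Coordinate convention, used everywhere in the package: 0-based, ``x``
rightward, ``y`` downward, vertices measured at pixel centers.  Pixel
``(r, c)`` of a raster therefore has center ``(x, y) = (c, r)`` and occupies
the square ``[c - 0.5, c + 0.5] x [r - 0.5, r + 0.5]``.
"""

from __future__ import annotations

import json
import logging
import struct
import zipfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import tifffile

from .errors import (
    BoundsError,
    CoordinateOverflowError,
    EmptyInputError,
    FormatError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ImageStack",
    "Contour",
    "SomaAnnotation",
    "AnnotationSet",
    "read_stack",
    "write_stack",
    "write_imagej_rois",
    "read_imagej_rois",
    "rasterize",
    "trace_boundary",
    "save_annotation_archive",
    "load_annotation_archive",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class ImageStack:
    """Ordered grayscale planes with physical pixel and z spacing.

    ``planes`` is a ``(n_planes, height, width)`` array; intensities must be
    finite and non-negative.  ``pixel_size_um`` assumes square pixels.
    """

    planes: np.ndarray
    pixel_size_um: float
    z_step_um: float
    source_id: str = ""

    def __post_init__(self) -> None:
        self.planes = np.asarray(self.planes)
        if self.planes.ndim != 3:
            raise ValueError("planes must be a (n, h, w) array")
        if self.planes.shape[0] == 0:
            raise EmptyInputError("stack has zero planes")
        if self.pixel_size_um <= 0 or self.z_step_um <= 0:
            raise ValueError("pixel_size_um and z_step_um must be > 0")
        if not np.all(np.isfinite(self.planes)) or self.planes.min() < 0:
            raise ValueError("intensities must be finite and >= 0")

    @property
    def n_planes(self) -> int:
        return self.planes.shape[0]

    @property
    def plane_shape(self) -> tuple[int, int]:
        return self.planes.shape[1], self.planes.shape[2]


@dataclass(frozen=True)
class Contour:
    """Closed polygon, implicitly joined from the last vertex to the first.

    ``vertices`` is an ``(n, 2)`` float array of ``(x, y)`` pixel-center
    coordinates with ``n >= 3`` and no two consecutive vertices identical.
    """

    vertices: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2:
            raise ValueError("vertices must be an (n, 2) array of (x, y)")
        if v.shape[0] < 3:
            raise ValueError("a contour needs at least 3 vertices")
        nxt = np.roll(v, -1, axis=0)
        if np.any(np.all(v == nxt, axis=1)):
            raise ValueError("consecutive duplicate vertices")
        object.__setattr__(self, "vertices", v)

    @property
    def n(self) -> int:
        return self.vertices.shape[0]

    def bbox(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) over the vertices."""
        v = self.vertices
        return v[:, 0].min(), v[:, 1].min(), v[:, 0].max(), v[:, 1].max()


@dataclass
class SomaAnnotation:
    """One contoured soma: a polygon plus (lazily) its filled binary mask."""

    contour: Contour
    region_id: str
    plane_index: int = 0
    annotator_id: str = ""
    mask: np.ndarray | None = None

    def get_mask(self, shape: tuple[int, int]) -> np.ndarray:
        """Rasterized mask on a raster of ``shape``, cached after first use."""
        if self.mask is None or self.mask.shape != tuple(shape):
            self.mask = rasterize(self.contour, shape)
        return self.mask


@dataclass
class AnnotationSet:
    """Annotations grouped by image, with per-image unique region ids."""

    by_image: dict[str, list[SomaAnnotation]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for image_id, anns in self.by_image.items():
            ids = [a.region_id for a in anns]
            if len(ids) != len(set(ids)):
                raise ValueError(f"duplicate region_id in image {image_id!r}")

    def add(self, image_id: str, annotation: SomaAnnotation) -> None:
        anns = self.by_image.setdefault(image_id, [])
        if any(a.region_id == annotation.region_id for a in anns):
            raise ValueError(f"duplicate region_id {annotation.region_id!r}")
        anns.append(annotation)

    def regions(self) -> Iterator[tuple[str, SomaAnnotation]]:
        for image_id, anns in self.by_image.items():
            for a in anns:
                yield image_id, a

    @property
    def n_regions(self) -> int:
        return sum(len(v) for v in self.by_image.values())

    def region_ids(self) -> set[tuple[str, str]]:
        return {(img, a.region_id) for img, a in self.regions()}


# ---------------------------------------------------------------------------
# TIFF stacks
# ---------------------------------------------------------------------------


def read_stack(
    path: str | Path,
    pixel_size_um: float = 1.0,
    z_step_um: float = 2.0,
) -> ImageStack:
    """Read a single- or multi-page grayscale TIFF into an :class:`ImageStack`.

    Physical spacings are taken from the arguments; the pixel size of the
    source micrographs is not recorded in plain TIFFs, so it must be supplied
    for areas in um^2 to be meaningful (1.0 keeps areas in pixel units).
    """
    path = Path(path)
    try:
        data = tifffile.imread(path)
    except (tifffile.TiffFileError, ValueError) as exc:
        raise FormatError(f"{path} is not a readable TIFF: {exc}") from exc
    data = np.asarray(data)
    if data.size == 0:
        raise EmptyInputError(f"{path} contains zero pages")
    if data.ndim == 2:
        data = data[None, :, :]
    elif data.ndim != 3:
        raise FormatError(f"{path}: expected grayscale pages, got shape {data.shape}")
    return ImageStack(data, pixel_size_um, z_step_um, source_id=path.stem)


def write_stack(stack: ImageStack, path: str | Path) -> None:
    """Write a stack as a multi-page TIFF (lossless)."""
    tifffile.imwrite(Path(path), stack.planes, photometric="minisblack")


# ---------------------------------------------------------------------------
# ImageJ ROI codec
#
# Binary layout (big-endian), per ImageJ's RoiDecoder: magic "Iout", a short
# version, a type byte (0 = polygon, 7 = freehand), a short bounding box
# (top, left, bottom, right), the vertex count, and after the 64-byte header
# the x offsets then y offsets as 16-bit integers relative to (left, top).
# ---------------------------------------------------------------------------

_ROI_MAGIC = b"Iout"
_ROI_VERSION = 227
_TYPE_POLYGON = 0
_TYPE_FREEHAND = 7
_TYPE_TRACED = 8
_POLYGONAL_TYPES = (_TYPE_POLYGON, _TYPE_FREEHAND, _TYPE_TRACED)


def _round_half_away(values: np.ndarray) -> np.ndarray:
    return np.copysign(np.floor(np.abs(values) + 0.5), values).astype(np.int64)


def _encode_roi(contour: Contour, name: str) -> bytes:
    v = contour.vertices
    iv = _round_half_away(v)
    if np.any(iv.astype(float) != v):
        logger.warning(
            "contour %s has sub-pixel vertices; rounded half-away-from-zero "
            "for ImageJ export",
            name,
        )
    left, top = int(iv[:, 0].min()), int(iv[:, 1].min())
    right, bottom = int(iv[:, 0].max()), int(iv[:, 1].max())
    xoff = iv[:, 0] - left
    yoff = iv[:, 1] - top
    if xoff.max() > 0x7FFF or yoff.max() > 0x7FFF or not (
        -0x8000 <= left <= 0x7FFF and -0x8000 <= top <= 0x7FFF
    ):
        raise CoordinateOverflowError(
            f"contour {name}: vertices exceed the 16-bit ImageJ offset range"
        )
    n = contour.n
    header = struct.pack(
        ">4sh b x 4h h 4f h i i i h h b b h i i",
        _ROI_MAGIC,
        _ROI_VERSION,
        _TYPE_POLYGON,
        top,
        left,
        bottom,
        right,
        n,
        0.0, 0.0, 0.0, 0.0,   # x1..y2 (unused for polygons)
        0,                    # stroke width
        0,                    # shape roi size
        0, 0,                 # stroke / fill color
        0, 0,                 # subtype, options
        0, 0,                 # arrow style, head size
        0,                    # rounded rect arc size
        0,                    # position
        0,                    # header2 offset
    )
    assert len(header) == 64
    coords = struct.pack(f">{n}h", *xoff.tolist()) + struct.pack(
        f">{n}h", *yoff.tolist()
    )
    return header + coords


def _decode_roi(blob: bytes, name: str) -> Contour | None:
    if len(blob) < 64 or blob[:4] != _ROI_MAGIC:
        raise FormatError(f"ROI {name}: bad magic bytes")
    roi_type = blob[6]
    if roi_type not in _POLYGONAL_TYPES:
        logger.warning("ROI %s: unsupported type %d, skipped", name, roi_type)
        return None
    top, left, _bottom, _right, n = struct.unpack(">4hh", blob[8:18])
    if n < 3:
        raise FormatError(f"ROI {name}: polygon with {n} vertices")
    end = 64 + 4 * n
    if len(blob) < end:
        raise FormatError(f"ROI {name}: truncated coordinate block")
    xoff = np.array(struct.unpack(f">{n}h", blob[64 : 64 + 2 * n]))
    yoff = np.array(struct.unpack(f">{n}h", blob[64 + 2 * n : end]))
    return Contour(np.stack([xoff + left, yoff + top], axis=1).astype(float))


def write_imagej_rois(
    annotations: Sequence[SomaAnnotation], path: str | Path
) -> Path:
    """Write contours as ImageJ ``.roi`` records.

    A single annotation may go to a bare ``.roi`` file; more than one is
    bundled into a ``.zip`` with one uniquely named entry per contour.
    Vertices round-trip exactly through :func:`read_imagej_rois` whenever
    they are integral and within the 16-bit offset range.
    """
    path = Path(path)
    if len(annotations) == 0:
        raise EmptyInputError("refusing to write an empty ROI archive")
    names: list[str] = []
    for i, ann in enumerate(annotations):
        base = ann.region_id or f"roi_{i:04d}"
        name = base
        k = 1
        while name in names:
            name = f"{base}-{k}"
            k += 1
        names.append(name)
    if path.suffix.lower() == ".roi":
        if len(annotations) != 1:
            raise ValueError("a bare .roi file holds exactly one contour; use .zip")
        path.write_bytes(_encode_roi(annotations[0].contour, names[0]))
        return path
    with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zf:
        for name, ann in zip(names, annotations):
            zf.writestr(f"{name}.roi", _encode_roi(ann.contour, name))
    return path


def read_imagej_rois(path: str | Path) -> list[SomaAnnotation]:
    """Read a ``.roi`` file or a ``.zip`` of them into annotations.

    Non-polygonal ROI types (lines, points) are skipped with a warning; masks
    are rasterized lazily by :meth:`SomaAnnotation.get_mask`.
    """
    path = Path(path)
    records: list[tuple[str, bytes]] = []
    if zipfile.is_zipfile(path):
        with zipfile.ZipFile(path) as zf:
            for entry in zf.namelist():
                records.append((Path(entry).stem, zf.read(entry)))
    else:
        blob = path.read_bytes()
        if not blob.startswith(_ROI_MAGIC):
            raise FormatError(f"{path}: neither a .roi record nor a zip archive")
        records.append((path.stem, blob))
    out = []
    for name, blob in records:
        contour = _decode_roi(blob, name)
        if contour is not None:
            out.append(SomaAnnotation(contour=contour, region_id=name))
    return out


# ---------------------------------------------------------------------------
# rasterization and boundary tracing
# ---------------------------------------------------------------------------


def rasterize(contour: Contour, shape: tuple[int, int]) -> np.ndarray:
    """Fill a contour into a boolean mask of ``shape``.

    A pixel is set exactly when its center lies strictly inside the polygon
    under the even-odd rule, or on the polygon boundary.  Degenerate
    (zero-area) polygons therefore still mark their boundary pixels.
    """
    h, w = int(shape[0]), int(shape[1])
    v = contour.vertices
    xmin, ymin, xmax, ymax = contour.bbox()
    # vertices may extend half a pixel past the outermost centers (contours
    # traced along pixel edges do), but no further
    if xmin < -0.5 or ymin < -0.5 or xmax > w - 0.5 or ymax > h - 0.5:
        raise BoundsError(
            f"contour bbox ({xmin},{ymin})-({xmax},{ymax}) exceeds raster {h}x{w}"
        )
    c0, c1 = max(int(np.floor(xmin)), 0), min(int(np.ceil(xmax)), w - 1)
    r0, r1 = max(int(np.floor(ymin)), 0), min(int(np.ceil(ymax)), h - 1)
    if c1 < c0 or r1 < r0:
        return np.zeros((h, w), dtype=bool)
    cx, cy = np.meshgrid(
        np.arange(c0, c1 + 1, dtype=float), np.arange(r0, r1 + 1, dtype=float)
    )
    inside = np.zeros(cx.shape, dtype=bool)
    boundary = np.zeros(cx.shape, dtype=bool)
    eps = 1e-9
    nxt = np.roll(v, -1, axis=0)
    for (x1, y1), (x2, y2) in zip(v, nxt):
        # even-odd crossing count, half-open in y to count shared vertices once
        crosses = (y1 > cy) != (y2 > cy)
        if np.any(crosses):
            xi = x1 + (cy - y1) * (x2 - x1) / (y2 - y1)
            inside ^= crosses & (cx < xi)
        # point-on-segment test
        dx, dy = x2 - x1, y2 - y1
        seg_len2 = dx * dx + dy * dy
        if seg_len2 == 0:
            boundary |= (np.abs(cx - x1) < eps) & (np.abs(cy - y1) < eps)
            continue
        cross = (cx - x1) * dy - (cy - y1) * dx
        t = ((cx - x1) * dx + (cy - y1) * dy) / seg_len2
        boundary |= (
            (np.abs(cross) < eps * np.sqrt(seg_len2))
            & (t >= -eps)
            & (t <= 1 + eps)
        )
    mask = np.zeros((h, w), dtype=bool)
    mask[r0 : r1 + 1, c0 : c1 + 1] = inside | boundary
    return mask


def trace_boundary(mask: np.ndarray) -> Contour:
    """Trace the outer boundary of a mask's pixel region as a closed polygon.

    The polygon follows pixel *edges* (vertices at half-integer coordinates),
    so rasterizing it reproduces the mask exactly for hole-free regions:
    mask-pixel centers are strictly inside, all other centers strictly
    outside.  If the mask has several connected components the outermost
    boundary with the largest enclosed area is returned.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise EmptyInputError("cannot trace an empty mask")
    rows, cols = np.nonzero(mask)
    padded = np.zeros((mask.shape[0] + 2, mask.shape[1] + 2), dtype=bool)
    padded[1:-1, 1:-1] = mask
    # directed edges with the region on the right in (x, y) display coords
    edges: dict[tuple[float, float], list[tuple[float, float]]] = {}

    def _add(a: tuple[float, float], b: tuple[float, float]) -> None:
        edges.setdefault(a, []).append(b)

    for r, c in zip(rows, cols):
        x0, y0, x1, y1 = c - 0.5, r - 0.5, c + 0.5, r + 0.5
        if not padded[r, c + 1]:       # neighbor above (r-1) is r, c+1 in padded
            _add((x0, y0), (x1, y0))   # top edge, rightward
        if not padded[r + 1, c + 2]:   # right neighbor
            _add((x1, y0), (x1, y1))   # right edge, downward
        if not padded[r + 2, c + 1]:   # below
            _add((x1, y1), (x0, y1))   # bottom edge, leftward
        if not padded[r + 1, c]:       # left
            _add((x0, y1), (x0, y0))   # left edge, upward
    loops: list[np.ndarray] = []
    while edges:
        start = next(iter(edges))
        loop = [start]
        cur = start
        prev_dir = None
        while True:
            candidates = edges[cur]
            if len(candidates) == 1 or prev_dir is None:
                nxt_pt = candidates[0]
            else:
                # at a pinch point prefer the sharpest right turn so each
                # loop stays on one side of the junction
                def turn(p: tuple[float, float]) -> float:
                    d = (p[0] - cur[0], p[1] - cur[1])
                    return prev_dir[0] * d[1] - prev_dir[1] * d[0]

                nxt_pt = max(candidates, key=turn)
            candidates.remove(nxt_pt)
            if not candidates:
                del edges[cur]
            prev_dir = (nxt_pt[0] - cur[0], nxt_pt[1] - cur[1])
            cur = nxt_pt
            if cur == start:
                break
            loop.append(cur)
        loops.append(np.array(loop, dtype=float))

    def _area(poly: np.ndarray) -> float:
        x, y = poly[:, 0], poly[:, 1]
        return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))

    outer = max(loops, key=_area)
    # collapse collinear runs
    keep = []
    m = len(outer)
    for i in range(m):
        prev_pt, pt, nxt_pt = outer[i - 1], outer[i], outer[(i + 1) % m]
        d1 = pt - prev_pt
        d2 = nxt_pt - pt
        if d1[0] * d2[1] - d1[1] * d2[0] != 0:
            keep.append(pt)
    return Contour(np.array(keep))


# ---------------------------------------------------------------------------
# internal JSON annotation archive
# ---------------------------------------------------------------------------


def save_annotation_archive(annotations: AnnotationSet, path: str | Path) -> None:
    """Provenance archive: image_id, annotator_id and vertex lists as JSON."""
    payload = {
        image_id: [
            {
                "region_id": a.region_id,
                "annotator_id": a.annotator_id,
                "plane_index": a.plane_index,
                "vertices": a.contour.vertices.tolist(),
            }
            for a in anns
        ]
        for image_id, anns in annotations.by_image.items()
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_annotation_archive(path: str | Path) -> AnnotationSet:
    payload = json.loads(Path(path).read_text())
    out = AnnotationSet()
    for image_id, anns in payload.items():
        for a in anns:
            out.add(
                image_id,
                SomaAnnotation(
                    contour=Contour(np.array(a["vertices"], dtype=float)),
                    region_id=a["region_id"],
                    annotator_id=a.get("annotator_id", ""),
                    plane_index=a.get("plane_index", 0),
                ),
            )
    return out
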