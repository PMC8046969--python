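"""Exchange soma outlines with ImageJ.

Manual annotations are most often drawn in ImageJ/Fiji as polygon ROIs and
saved in its binary ``.roi`` format.  This script builds a few annotations
programmatically, writes them as an ImageJ-readable ``.zip`` archive, reads
the archive back, and shows that integer polygons survive the round trip
exactly — including the rasterized pixel masks.
"""

import tempfile
from pathlib import Path

import numpy as np

from somaseg import (
    Contour,
    SomaAnnotation,
    rasterize,
    read_imagej_rois,
    trace_boundary,
    write_imagej_rois,
)

# Two hand-made polygons: a square soma and an irregular one.
square = Contour(np.array([[10, 10], [20, 10], [20, 20], [10, 20]], float))
blob = Contour(np.array([[30, 12], [38, 10], [42, 16], [37, 24], [29, 20]],
                        float))
annotations = [
    SomaAnnotation(contour=square, region_id="soma_a"),
    SomaAnnotation(contour=blob, region_id="soma_b"),
]

with tempfile.TemporaryDirectory() as tmp:
    archive = Path(tmp) / "somata.zip"
    write_imagej_rois(annotations, archive)
    print(f"wrote {archive.name}: {archive.stat().st_size} bytes")

    restored = read_imagej_rois(archive)

for original, back in zip(annotations, restored):
    same = np.array_equal(original.contour.vertices, back.contour.vertices)
    print(f"{back.region_id}: vertices identical after round trip -> {same}")

# Masks and contours are two views of the same region: tracing the boundary
# of a rasterized mask and re-rasterizing it reproduces the mask exactly.
mask = rasterize(blob, shape=(48, 48))
traced = trace_boundary(mask)
print("mask pixels:", int(mask.sum()))
print("trace/rasterize fixed point:",
      np.array_equal(rasterize(traced, (48, 48)), mask))
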