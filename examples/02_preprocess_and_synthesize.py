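"""From a partially annotated stack to a fully labeled synthetic corpus.

The central idea: even when only a fraction of the somata in a micrograph
are outlined, those outlines plus soma-free background tiles are enough to
compose an unlimited number of *fully* labeled training scenes — background
collages with annotated somata transplanted onto them under random
rotations, flips, scalings and brightness changes.
"""

import numpy as np

from somaseg import (
    AnnotationSet,
    FixtureConfig,
    SynthConfig,
    clahe_normalize,
    generate_dataset,
    make_toy_stack,
    max_project,
    median_filter_planes,
    subtract_background,
)

# A synthetic "acquisition": a 5-plane stack with 10 somata, 60% annotated.
stack, truth, partial = make_toy_stack(
    FixtureConfig(n_somata=10, annotated_fraction=0.6, seed=4)
)
print(f"stack: {stack.planes.shape}, "
      f"{truth.n_regions} somata present, {partial.n_regions} annotated")

# Standard preprocessing: despeckle, flatten, project, normalize contrast.
filtered = median_filter_planes(stack, kernel=3)
flattened = subtract_background(filtered, np.percentile(filtered.planes, 50))
projection = max_project(flattened)[0].image
normalized = clahe_normalize(projection)
print(f"projection range {projection.min():.0f}-{projection.max():.0f} "
      f"-> normalized {normalized.min():.0f}-{normalized.max():.0f}")

# Synthesize a small corpus from the partial annotations only.
annotations = AnnotationSet()
for _image_id, ann in partial.regions():
    annotations.add(stack.source_id, ann)
config = SynthConfig(n_tiles=10, tile_size=(16, 16), overlap_px=4,
                     n_backgrounds=4, scene_size=(64, 64),
                     n_train=6, n_val=2, somata_per_scene=(3, 6))
train_scenes, val_scenes = generate_dataset(
    {stack.source_id: normalized}, annotations, config, seed=0
)

print(f"\n{len(train_scenes)} training and {len(val_scenes)} validation scenes")
train_ids = {r for s in train_scenes for _m, r, _p in s.instances}
val_ids = {r for s in val_scenes for _m, r, _p in s.instances}
print("train/val soma identities disjoint:", train_ids.isdisjoint(val_ids))
for scene in train_scenes[:3]:
    params = [p for _m, _r, p in scene.instances if p is not None]
    scales = ", ".join(f"{p.scale:.2f}" for p in params[:4])
    print(f"  scene with {len(scene.instances)} somata, scales [{scales}, ...]")
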