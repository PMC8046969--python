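"""Quantify inter-annotator agreement and build a STAPLE consensus.

Two annotators outlining the same field rarely produce identical region
sets.  This script simulates two imperfect annotators of the same ground
truth, counts their union of distinct regions, measures pairwise overlap,
and estimates a consensus segmentation (with per-annotator sensitivity and
specificity) using STAPLE expectation-maximization.
"""

import numpy as np

from somaseg import (
    FixtureConfig,
    avg_overlapping,
    dice,
    make_toy_stack,
    match_regions,
    staple,
    union_count,
)

stack, truth, _partial = make_toy_stack(FixtureConfig(n_somata=9, seed=5))
shape = stack.planes.shape[1:]
truth_masks = [ann.get_mask(shape) for _img, ann in truth.regions()]


def simulate_annotator(found_fraction, flip_rate, seed):
    """Each annotator finds a subset of somata and draws them imperfectly."""
    rng = np.random.default_rng(seed)
    n_found = round(found_fraction * len(truth_masks))
    chosen = rng.choice(len(truth_masks), size=n_found, replace=False)
    masks = []
    for i in sorted(chosen):
        mask = truth_masks[i].copy()
        edge = mask ^ np.roll(mask, 1, axis=0) | (mask ^ np.roll(mask, 1, axis=1))
        flips = edge & (rng.random(shape) < flip_rate)
        masks.append(mask ^ flips)
    return sorted(chosen), masks


found_a, masks_a = simulate_annotator(0.9, 0.4, seed=1)
found_b, masks_b = simulate_annotator(0.7, 0.4, seed=2)
n_common = len(set(found_a) & set(found_b))
union = union_count(len(found_a), len(found_b), n_common)
print(f"annotator A: {len(found_a)} regions, B: {len(found_b)}, "
      f"{n_common} in common -> {union} distinct regions")

# Pairwise agreement on the regions both outlined.
manual_a = [ann for _img, ann in truth.regions()]
common_dices = [
    dice(masks_a[found_a.index(i)], masks_b[found_b.index(i)])
    for i in set(found_a) & set(found_b)
]
print(f"mean Dice on shared regions: {np.mean(common_dices):.3f}")

# Whole-field consensus: treat each annotator's field as one binary mask.
field_a = np.any(masks_a, axis=0)
field_b = np.any(masks_b, axis=0)
result = staple([field_a, field_b, np.any(truth_masks, axis=0)])
print(f"\nSTAPLE converged in {result.iterations} iterations")
for name, p, q in zip("ABT", result.sensitivity, result.specificity):
    print(f"  annotator {name}: sensitivity {p:.3f}, specificity {q:.3f}")
print("consensus foreground pixels:", int(result.consensus.sum()))
print("average overlap of all three fields:",
      f"{avg_overlapping([field_a, field_b, np.any(truth_masks, axis=0)]):.3f}")
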