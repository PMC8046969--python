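# Methods

This note records what somaseg computes, why the defaults are what they
are, and where the boundaries of validity lie. Nothing here claims an
empirical result the package does not itself compute.

## Problem setting

Input: a multi-plane two-photon micrograph (or its maximum-intensity
projection) in which a human has outlined *some* of the visible somata as
polygon ROIs. Output: a polygon + mask + score for every soma the model
finds, plus statistics comparing region sets (human vs machine, or human
vs human).

Partial annotation is the operative constraint. Treating unannotated
somata as negatives would poison a discriminative learner, so the package
never trains on the real image directly; it trains on synthetic scenes in
which every soma is labeled by construction.

## Synthetic scene generation

1. **Background tiles.** Rectangular tiles (default 64×64, 50 of them) are
   rejection-sampled from the source image so that no tile intersects any
   annotated region. Sampling fails loudly (`SamplingError`) after a
   budget of 200 tries per tile rather than silently accepting
   contaminated tiles.
2. **Collage composition.** Tiles are laid on a grid with `tile − overlap`
   stride (default overlap 8 px). In an overlap of width `w`, the incoming
   tile's weight ramps linearly as `k/w` at offset `k`, so seams blend
   linearly and the two tile orders average at corners. Each background
   (default 500 of 512×512) then gets a uniform brightness offset in
   ±10 DN and Gaussian noise (σ = 5), clipped at zero.
3. **Soma transplantation.** Each annotated soma is cut out with its mask
   dilated by `pad_px = 1`; the pad ring's alpha falls linearly from 1 at
   the boundary to 0 at the outer edge (a 1-px ring gets α = 0.5), which
   feathers the paste edge and avoids halo artifacts. Placement is
   rejection-sampled against the occupancy of already-placed instances.
4. **Transforms.** Per placement: a random member of the rotation/flip
   group of the square (rot90 × flips), isotropic scale in [0.8, 1.2]
   (bilinear for intensity, nearest for the mask), and a brightness factor
   in [0.95, 1.3]. Ranges outside these bounds are rejected at the API
   boundary rather than clamped.
5. **Splits.** The pool of annotated soma *identities* is split
   train/validation (default 3:1) before any synthesis, so no source soma
   appears in both splits — scene-level splitting alone would leak
   identities.

Default corpus: 3000 training and 1000 validation scenes, 5–25 somata per
scene. Tests and examples use reduced counts of the same design; the
defaults themselves are asserted in the acceptance suite.

Partial-annotation experiments use `subsample_annotations`, which keeps
`ceil(fraction · n)` regions — the ceiling is deliberate so the nominal
fractions 75/50/25/10/5% of a 653-region pool give 490, 327, 164, 66 and
33 regions respectively.

## The segmenter

The detector is a small fully-convolutional network implemented directly
in NumPy/SciPy (`scipy.signal.correlate2d`, manual backpropagation):
`convnet-small` is one 5×5 conv (8 channels, ReLU) followed by a 3×3
1-channel head; `convnet-large` stacks two hidden layers. The output map
passes through a sigmoid to give a per-pixel soma probability.

Training is SGD with momentum 0.9, weight decay 1e-4, learning rate 1e-3,
batch 4, 500 steps/epoch for 30 epochs by default — a standard recipe for
this family of models; desk-scale runs shrink all of these. The
optimization target is per-pixel binary cross-entropy with a
positive-class weight (default 3) to counter foreground sparsity. The
three-term detection loss `α·L_class + β·L_bbox + γ·L_mask` is implemented
exactly (`multitask_loss`, with smooth-L1 boxes normalized by the mask
diagonal) and reported per epoch for monitoring from ground-truth
proposals; the pixel loss is what is backpropagated, a deliberate
simplification that keeps the implementation dependency-free and
verifiable while preserving the training-signal semantics.

Inference thresholds the probability map (default 0.5), labels connected
components (8-connectivity), fills holes, scores each component by its
mean probability, filters by score (default 0.7) and minimum area
(4 px), maps masks back to native resolution, and traces each mask's
boundary into a polygon. Traced polygons re-rasterize to their masks
exactly.

Non-finite training losses raise `DivergenceError` carrying the last
finite checkpoint; they are never papered over.

## Geometry and formats

Coordinates are 0-based pixel centers, x right, y down. Rasterization
uses even–odd crossing counts plus explicit boundary-pixel inclusion;
`trace_boundary` walks the directed edges of the union of pixel squares
(vertices at half-integers), so `rasterize ∘ trace_boundary` is the
identity on hole-free masks and the shoelace area of a traced polygon
equals the pixel count exactly. ImageJ ROI records are written in the
big-endian binary layout ImageJ expects (polygon type, 16-bit vertex
offsets); sub-pixel vertices are rounded half-away-from-zero with a
warning, and coordinates outside the 16-bit range are an error, not a
silent wrap.

## Agreement statistics

- `dice`: 2|A∩B| / (|A|+|B|); undefined (an error) when both masks are
  empty.
- `match_regions`: for each manual region, the detection with the highest
  Dice; a match requires Dice *strictly* greater than 0.5. The search is
  per manual region, so collisions (one detection best for two manual
  regions) are possible and are counted.
- `yield_rate` (100·matched/manual), `precision_from_counts`
  (TP/detected), `union_count` (|A|+|B|−|A∩B|) operate on integer counts.
- `compile_report` pairs shoelace areas of matched manual/detected
  polygons and reports mean/SD of the differences and their Pearson
  correlation.
- `staple`: the standard STAPLE EM. Prior = mean rater foreground
  fraction; sensitivities/specificities initialized at 0.9999 and clamped
  to [1e-6, 1−1e-6]; the E-step runs in log space for numerical safety;
  consensus is posterior ≥ 0.5. The implementation is tested against an
  independent straight-line EM oracle.

## Fixtures: what they emulate and what they do not

`make_toy_stack` renders Gaussian-blurred ellipses on a noisy background
with depth-dependent dimming, thresholded at half peak intensity so the
ground-truth masks are exact by construction. This captures the features
the pipeline depends on — compact bright blobs, background texture, depth
attenuation, partial annotation — but **not** real tissue: no dendrites or
neuropil, no motion artifacts, no overlapping somata in z, no photon
(Poisson) noise statistics, no bleaching. Conclusions drawn on fixtures
are statements about the machinery, not about biological performance;
validating on real micrographs requires real annotated data.

`make_paired_protocols` builds two corpora with different imaging
parameters (and warns when they are degenerate, i.e. identical), for
cross-protocol train-on-A/test-on-B experiments via
`pipeline.cross_evaluate`.

## Numerical choices

- All stochastic code takes explicit seeds; independent random streams are
  spawned with `numpy.random.SeedSequence`, so changing the number of
  scenes does not perturb unrelated draws.
- CLAHE uses scikit-image's `equalize_adapthist` convention
  (`clip_limit` ∈ [0, 1], default 0.01) and rescales back to the input
  range; constant images pass through unchanged.
- Image resizing is bilinear for intensities and order-0 for masks;
  model-frame ↔ native coordinate maps are exact affine inverses.
- Checkpoints are `.npz` weight archives with a JSON sidecar and a SHA-256
  checksum; pipelines record checksums of every artifact in a manifest.

## Limitations

- The segmenter is a deliberately small CPU model; it demonstrates and
  tests the training methodology at desk scale but is not a
  state-of-the-art architecture, and no claim is made about parity with
  large pretrained detectors.
- Semantic-then-connected-components instance extraction merges somata
  that touch after thresholding; the synthetic generator's
  non-overlapping placement limits but does not eliminate this.
- STAPLE assumes conditionally independent raters and a scalar prior;
  correlated annotator errors bias its sensitivity/specificity estimates.
- ImageJ export supports polygonal ROI types only (polygon, freehand,
  traced); other types are skipped with a warning on import.
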