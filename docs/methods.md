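# Methods

This note documents the models and procedures implemented in `fruitpick`,
the parameter defaults and their rationale, what the synthetic-scene
generator does and does not emulate, and the numerical conventions.

## Scene representation

A scene is a pixel-aligned triplet: an 8-bit RGB image, a 16-bit depth map
in millimetres with 0 as the invalid-depth sentinel, and a semantic label
map over the eight-class crop ontology (background, mature fruit, immature
fruit, peduncle, stem, branch/petiole, wire, cut), optionally extended by a
ninth `leaf` class for synthetic-style ground truth. Coordinates are 0-based
`(row, col)` with row 0 at the top. Label PNGs are indexed-color and
round-trip losslessly; polygon annotations rasterize with a pixel-center
even-odd rule (a pixel belongs to a polygon iff its center is inside or on
the boundary), painted in annotation order so front objects, annotated last,
win on overlap.

Downsampling by an integer factor takes the top-left label of each block and
the median of the *valid* depths of each block (sentinel if none). The
median-of-valid rule matters: depth cameras drop out near depth
discontinuities and on far/featureless background, and the median over the
valid subset keeps block depths on-object instead of mixing foreground and
background.

## SFM: strip-pooling spatial attention

Slender near-axis-aligned structures — stems and support wires — occupy few
pixels but whole rows or columns. The SFM operator summarizes a C×H×W
feature map along each spatial axis:

    mask_h[h] = ReLU( mean_c ( mean_w F[c,h,w] ) )        (length H)
    mask_v[w] = ReLU( mean_c ( mean_h F[c,h,w] ) )        (length W)
    F_h = F ⊙ mask_h,   F_v = F ⊙ mask_v
    F_t = Conv(Concat(F, F_h, F_v))                       (3C → C fusion)

A row (column) containing a bright slender structure pools to a large mask
weight, so the multiplication re-allocates attention to the whole row
(column). The operator is stateless here; training-time integration after a
segmentation backbone is an adapter concern for the host framework. The
fusion kernel size is configurable (default 1×1, the cheapest choice; the
default weights average the three concatenated blocks, and an
identity-on-first-block configuration is provided for testing).

**FLOPs convention.** One FLOP per scalar add, multiply, divide, or ReLU
comparison; no multiply-add fusing. The two directional branches cost
`4CHW + C(H+W) + (H+W)`; the fusion convolution is excluded from the budget
by default (flag to include). The SCNN-style baseline — per direction,
slice i receives `slice_i + conv(slice_{i-1})` with a channel-mixing kernel
of width k, over all slices, in four directions — costs `2·C·k` ops per
output scalar per updated slice, i.e. `2(H−1)·CW·2Ck + 2(W−1)·CH·2Ck` for a
full pass. At C=128, H=W=64, k=9 this is 4756.3 MFLOPs versus 2.1 MFLOPs
for the SFM branches: the attention mechanism replaces sequential slice
convolutions with two global pools and two broadcasts.

## Instance clustering

Pixels of one fruit are compact in the image and share a depth band even
when an occluder splits the mask, so mature-fruit pixels are clustered in
joint (position, depth) space with loss

    L = Σ_j Σ_{i∈S_j} ‖p(X_i) − p(Z_j)‖² + α‖d(X_i) − d(Z_j)‖².

Defaults and units: clustering runs at working resolution (downsample
factor 4, 600×800 → 150×200) for noise suppression and speed; positions are
working-resolution pixels; depth enters in centimetres (`depth_scale` 0.1
from millimetres) so that with `α = 1` a 1 cm depth difference weighs like a
1 px offset — commensurate scales for fruits tens of pixels and tens of
centimetres apart. Both the scale and α are configurable.

The adaptive loop: K starts at `K0 = 8` (an upper bound on mature fruits in
one view); after each seeded Lloyd run, center pairs closer than
`merge_dist = 12` working pixels in the combined metric
`√(‖Δp‖² + αΔd²)` merge (smallest distance first, ties to the lowest index
pair), and clustering repeats at the reduced K until K stabilizes. K only
shrinks, so at most K0 rounds run. Two deliberate choices:

- **Seeding** is D²-weighted sampling of data points without replacement
  (k-means++ style). Uniform seeding occasionally leaves a well-separated
  fruit without a center, and the shrink-only loop cannot recover from the
  resulting two-fruits-one-cluster local optimum.
- **Dust dissolution**: after stabilization, clusters with fewer than
  `min_cluster_size = 20` samples are absorbed into their nearest neighbour.
  Mixed-depth pixels at object borders (a block median straddling fruit and
  occluder) can sit tens of working units off in depth and hold a center of
  their own; the smallest fruit under the study conditions occupies ~50
  working-resolution samples, so a 20-sample floor separates artifact from
  fruit by more than a factor of two. This mirrors the connected-region
  noise floor in the perception stage.

Empty clusters during Lloyd iterations re-seed at the sample farthest from
the empty center (deterministic, bounded). Assignment ties go to the lowest
cluster index; all randomness is driven by one seed, so identical inputs
give identical states. Full-resolution instance masks assign every mature
pixel to the nearest center (positions rescaled by the downsample factor;
pixels with invalid depth use the position term only), yielding a partition
of the mature mask.

A consistency bound worth knowing: with surplus K, the centers K-means
places inside a single fruit of working radius r are ~1.0–1.2·r apart, so
fruits with r > merge_dist never re-merge. With `merge_dist = 12` the
pipeline is consistent for fruits up to ~48 px radius at full resolution;
larger fruits need a proportionally larger `merge_dist`.

## Obstacle perception and pickability

A fruit instance that forms one connected region (8-connectivity, components
under `min_area = 20` px discarded as noise) is unobstructed. Otherwise, for
every pair of disconnected regions, `n_samples = 10` blind-spot
quadrilaterals are drawn: two seeded-random points from each region, ordered
by angle around their centroid so the polygon is simple; near-degenerate
draws are retried a bounded number of times. The spot's pixel support is the
even-odd fill of the quad plus its Bresenham outline (a near-collinear quad
is thinner than a pixel along most of its length, and the outline keeps the
support connected across the gap being probed), minus the instance's own
pixels. Each region pair consumes an independent RNG stream derived from
(seed, instance, pair), so detected classes grow monotonically with
`n_samples` and results are reproducible.

Classes covering at least `min_class_pixels = 3` of a spot are reported.
Stems, wires and branches/petioles veto picking (strong mechanical
resistance); peduncles and other fruits are reported but non-blocking by
default (configurable). A spot containing only background triggers the leaf
test: Otsu's threshold (between-class variance maximization over the value
histogram, ties to the smallest maximizer) on the excess-green index
`ExG = 2g − r − b` of the scene's background pixels; if the majority of the
spot's background pixels lie above the threshold they are vegetation — a
leaf, which does not block picking — otherwise the occluder stays `unknown`
(also non-blocking, since no hard-obstacle class was seen). A constant-color
background has nothing green to find and resolves to `unknown`.

Known limitation: an obstacle that touches a fruit's silhouette without
splitting the mask into separate regions produces a single connected region
and is invisible to this scheme.

## Target selection and metrics

For each pickable instance the pick circle is the minimum enclosing circle
(Welzl's randomized incremental algorithm, 1e-6 radius tolerance) over
visible plus blind-spot pixels — the occluded part of the fruit belongs to
the fruit, so the circle estimates the full fruit extent. Mean depth is
taken over the instance's valid visible pixels; a candidate with no valid
depth cannot be localized and is skipped. Candidates are ranked by

    score = w_a · area/area_max + w_d · depth_min/depth,   (w_a, w_d) = (0.5, 0.5)

which is scale-invariant in both factors and gives exactly 1.0 to a fruit
that is simultaneously the largest and the closest; ties break by smaller
mean depth, then larger area, then lower id.

Evaluation metrics: pixel accuracy and per-class IoU are computed per image
and averaged over the image set (classes absent from both prediction and
truth in an image are skipped for that image); mIoU is the unweighted class
mean. Detection precision/recall/F1 match predictions to ground truth
greedily by descending overlap ratio, one-to-one, counting a true positive
when the overlap exceeds 0.5 of the *ground-truth* area. Positioning error
is `‖C_p − C_g‖₂ / R · 100` with R the ground-truth radius — a relative
center offset in percent.

## Synthetic scenes

The generator emulates the statistical structure the pipeline relies on, not
photometry: 600×800 scenes with 1–5 mature fruits drawn as disks
(radius 24–48 px, centers ≥ 150 px apart, depths 400–1200 mm in bands
≥ 100 mm apart, Gaussian depth noise σ = 5 mm), full-height stems (2–6 px),
near-horizontal wires (1–2 px), short oblique branch segments, green leaf
bands, plus non-occluding background clutter. Each planned occluder is drawn
over its fruit and verified to split the visible mask into ≥ 2 components of
≥ 20 px (scenes retry with a fresh substream otherwise). Leaves follow the
empirical annotation policy by default — green in RGB, labeled background —
so the Otsu fallback is genuinely exercised; a `leaf`-labeled variant
supports synthetic-style ground truth.

Depth model: background depth is the invalid sentinel (far, featureless
background beyond reliable stereo range), and a 2 px invalid band surrounds
every object boundary (the occlusion-shadow dropout of stereo depth
cameras). Both are standard artifacts of commodity RGB-D sensors and are
exactly the regime the median-of-valid downsampling is designed for.

Simplifications, hence what passing tests do *not* show about real data:
fruits are perfect disks with constant depth; there is no texture, lighting
or color variation beyond what the ExG test needs; occluders are painted
only outside other fruits' dilated disks (every other fruit wins the
z-fight), which keeps per-fruit ground truth exact but does not model
fruit-on-fruit occlusion; depth noise is i.i.d. Gaussian. Real segmentation
maps also carry network errors the generator does not model — the pipeline
consumes any segmenter's output, and its robustness to segmentation noise is
not claimed by these tests.

## Problem sizes and determinism

The test suite runs the clustering-recovery check on 100 seeded scenes, the
occlusion-verdict check on 200, and the end-to-end selection check on 50,
all at the generator's native 600×800 — sizes at which the full suite
completes in under two minutes on one CPU while the binomial bounds being
asserted (≥ 95%) remain meaningful. Every stochastic component (scene
generation, K-means seeding, blind-spot sampling) is driven by explicit
seeds; identical inputs and seeds give bit-identical outputs, and the staged
CLI reproduces the in-memory pipeline exactly.
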