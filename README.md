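# fruitpick

Occlusion-aware fruit selection and localization for single-fruit harvesting
robots, from RGB images, depth maps and semantic segmentation maps.

A harvesting robot must not reach for a tomato that has a stem, a support
wire or a branch in front of it: the end effector collides, the plant is
damaged, the pick fails. `fruitpick` turns a per-pixel semantic map (fruit /
stem / wire / branch / peduncle / cut / background) and an aligned depth map
into a ranked, obstacle-checked picking decision:

1. **Instance clustering** — mature-fruit pixels are split into individual
   fruits by adaptive K-means over joint (position, depth) space, minimizing

   `L = Σ_j Σ_{i∈S_j} ‖p(X_i) − p(Z_j)‖² + α‖d(X_i) − d(Z_j)‖²`

   where `p` is the pixel position, `d` the depth and `α` balances the two
   terms. The cluster count adapts per scene: start at an upper bound K₀,
   merge centers closer than a threshold, re-cluster until K stabilizes.
   Depth separates adjacent fruits that touch in the image.
2. **Blind-spot obstacle perception** — a fruit whose binary mask is a single
   connected region is unobstructed. If the mask splits, the occluder lies
   between the parts: quadrilaterals ("blind spots") spanned by two random
   points from each of two disconnected regions are checked against the
   semantic map. Stems, wires and branches/petioles veto the pick; blind
   spots containing only background are resolved by an Otsu threshold on the
   excess-green index `ExG = 2g − r − b` — mostly-green means a leaf, which
   is soft and does not block mechanical picking.
3. **Target selection** — every pickable fruit gets a minimum circumscribed
   circle over its visible plus blind-spot pixels (center, radius and mean
   depth are what the robot needs) and a closest-and-largest score
   `w_a·area/area_max + w_d·depth_min/depth`; the best-scoring fruit is the
   harvesting target.

The package also ships the **spatial-relationship feature module (SFM)**, a
strip-pooling spatial attention operator for the segmentation stage that
sharpens slender structures (stems, wires): 1-D masks
`mask = ReLU(channel-mean(strip-pool(F)))` re-weight a C×H×W feature map
along rows and columns, and the three maps `(F, F_h, F_v)` are fused by a
convolution. An analytic FLOPs counter compares it with the SCNN-style
slice-by-slice message-passing baseline it replaces.

Everything is exercisable end to end on deterministic synthetic scenes — no
dataset download, no GPU.

## Worked example

Generate the packaged demo scene (two tomatoes: one clear, one split by a
stem) and run the full pipeline:

```python
import fruitpick as fp

rgb, depth, sem, gt = fp.fixture_scene()
pal = fp.ClassPalette.default()
fp.write_label_png(sem, pal, "labels.png")
fp.write_depth_png(depth, "depth.png")
fp.write_rgb_png(rgb, "rgb.png")
```

```
$ fruitpick -v run --labels labels.png --depth depth.png --rgb rgb.png --out result.json
fruitpick: extracted 771 working-resolution fruit samples
fruitpick: adaptive K-means settled at K=2 (loss 51282.1)
fruitpick: instance 0: regions=1 occluded=False classes=[] pickable=True
fruitpick: instance 1: regions=2 occluded=True classes=['stem'] pickable=False
fruitpick: target: instance 0 center=(496.2, 591.3) r=48.0 depth=1099 mm score=1.000
selected instance 0
```

Reading the log: the two fruits were recovered as two instances (K settled
at 2); instance 1 fell into two connected regions and its blind spots hit
`stem` pixels, so it is discarded; instance 0 is whole and becomes the
target. Its circle center (496.2, 591.3) is within 0.03 px of the ground
truth fruit center, the radius 48.0 px matches the drawn disk, and the mean
depth 1099 mm matches the fruit's depth band. `result.json` holds the same
information as machine-readable instance runs, occlusion reports and target.

The attention operator's cost comparison, on a 128×64×64 feature:

```
$ fruitpick sfm-flops --shape 128,64,64
2113664 FLOPs (2.113664 MFLOPs)
$ fruitpick sfm-flops --shape 128,64,64 --scnn --kernel 9
4756340736 FLOPs (4756.340736 MFLOPs)
```

Other subcommands: `synth` (batch scene generation with a ground-truth
manifest), `cluster` / `perceive` / `select` (the pipeline stages as
file-in/file-out steps), `eval` (pixel accuracy, per-class IoU and mIoU for
label maps; precision/recall/F1 and positioning error for targets).

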