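# myoseg

Automatic segmentation of individual muscle fibers in transverse H&E
histology images, built for large (whole-slide-scale) inputs.

Skeletal-muscle morphometry — fiber size distributions, counts, shape —
starts from a per-cell segmentation, and annotating thousands of densely
packed fibers by hand is impractical. `myoseg` implements a
region-selection pipeline for this problem:

1. **Contour detection.** A *structured random forest* (SRF) slides over
   the image and predicts, for each 32×32 feature window (13 channels:
   CIE-LAB color, gradient magnitude at two blur levels, oriented gradient
   energy at 4 orientations × 2 scales), a 16×16 binary contour patch;
   averaging all overlapping patch votes yields a per-pixel contour
   probability map.
2. **Region candidates.** A deterministic watershed of the contour map
   produces an over-segmented candidate map whose regions are 4-connected,
   enclosed by single-pixel-wide boundary lines, and nested under
   boundary-strength thresholding (an ultrametric contour hierarchy).
3. **Hierarchical region selection.** The `N` base regions are merged
   (weakest shared boundary first) into a binary tree with `2N − 1` nodes;
   every node is a candidate cell. A random-forest scorer assigns each
   node a probability `s_i` of being a complete fiber, and the final
   segmentation is the antichain of tree nodes minimizing the CRF energy

   ```
   E = Σ_i U_i + Σ_{(i,j) adjacent} V_ij,
   U_i = −log(s_i + ε)          if node i is selected,
         −log(1 − s_i + ε)      otherwise,
   V_ij = μ · exp(−B_ij) · L_ij  when regions i, j get different labels,
   ```

   where `B_ij` and `L_ij` are the mean strength and length of the shared
   boundary. The antichain constraint (no selected node an ancestor of
   another) makes selected cells pairwise disjoint. Trees are cut at
   strong contours into small independent subtrees, solved exactly by
   enumeration (or by dynamic programming plus local search when large).
4. **Tile-parallel driver.** Large images are split into disjoint cores
   padded by 300 px, processed concurrently by a worker pool, and
   stitched: a cell belongs to the tile containing its centroid, and
   duplicates in overlap zones are removed by mask IoU. The output is
   bit-identical for any worker count and matches the standalone run.

Because no public dataset accompanies the method, the package ships a
synthetic generator (`myoseg.synthetic`) that emulates H&E muscle
morphology — convex, space-filling Voronoi fibers, thin pale interstitial
bands with optional broken segments, stain jitter, blur and noise — with
exact ground truth, so the whole pipeline is trainable and testable
offline. Cell-wise evaluation (per-cell precision, recall, F1 averaged
over cells) and score-threshold PR sweeps are in `myoseg.evaluation`.

## Worked example

```python
import dataclasses
from myoseg import (PipelineConfig, SyntheticSpec, generate_image,
                    train_models, segment_image, evaluate_rasters)

spec = SyntheticSpec(height=512, width=512, n_cells=30,
                     boundary_contrast=0.6, boundary_break_prob=0.0, seed=7)
image, gt = generate_image(spec)

config = PipelineConfig()
train = [generate_image(dataclasses.replace(spec, seed=s)) for s in (8, 9)]
models = train_models(train, config)

seg, cells = segment_image(image, models, config)
print(len(cells), "cells")
print("P=%.3f R=%.3f F1=%.3f" % evaluate_rasters(seg, gt.labels))
```

Output:

```
30 cells
P=0.936 R=0.974 F1=0.954
```

All 30 fibers are recovered; mean per-cell precision 0.936 means detected
masks extend slightly past the ground-truth fiber outlines (they include
about half of the interstitial band), while recall 0.974 means almost all
fiber pixels are covered. The same flow is available from the shell:

```bash
myoseg synth --height 512 --width 512 --n-cells 30 --seed 7 \
       --out-image img.png --out-labels gt.png
myoseg train-srf  --image t1.png --labels g1.png --image t2.png --labels g2.png --out srf.bin
myoseg train-scorer --image t1.png --labels g1.png --image t2.png --labels g2.png \
       --srf srf.bin --out scorer.bin
myoseg segment --image img.png --srf srf.bin --scorer scorer.bin \
       --tile-size 1024 --pad 300 --workers 4 --out seg.png
myoseg evaluate --seg seg.png --gt gt.png
```

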