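# Methods

This note records the models, parameter choices and numerical conventions
behind `myoseg`, and what the synthetic experiments do and do not show.

## Synthetic muscle images

Transverse H&E muscle sections show convex, space-filling fibers separated
by thin, pale endomysium. The generator draws `n_cells` seed points
uniformly, applies one Lloyd relaxation pass (pixel-assignment centroids)
for realistic size uniformity, and labels each pixel with its nearest
seed. The interstitial band is the set of pixels whose second-nearest and
nearest seed distances differ by less than `boundary_thickness` — a
band of roughly that width along every Voronoi edge — plus a thin rim
(≈ `boundary_thickness/2`) along the image border, standing in for the
tissue edge (and guaranteeing background pixels even in the single-cell
case). Cells that would vanish or disconnect under erosion trigger a
reseeding attempt; generation fails loudly if the density is infeasible.

Rendering: per-cell color = `cell_color_mean` + N(0, `cell_color_std`)
jitter; band pixels are blended toward a pale interstitial tone with
weight `boundary_contrast`; each Voronoi edge independently "breaks" with
probability `boundary_break_prob` (its band keeps the cell color,
emulating the faint/missing contours that cause false merges in real
slides); Gaussian blur `blur_sigma` then pixel noise `noise_std`. Ground
truth is purely geometric and independent of rendering noise. Defaults
(512×512, 50 cells, thickness 3 px, contrast 0.6, break 0.1, color
(200,120,150) ± 12, noise 6, blur 1) were chosen once as a plausible
mid-difficulty H&E appearance; typical transverse muscle crops run
600²–2000² pixels with tens to hundreds of fibers, which these match in
cell scale.

**What passing on synthetic data shows — and not.** The generator gives
exact ground truth, controlled difficulty and full determinism, so it can
verify the machinery end to end (training signal flows, inference is
exact, tiling is seamless) and measure recovery under known conditions. It
does not capture out-of-focus regions, stain variation across slides,
freezing artifacts, fiber-type intensity classes, or annotation noise;
absolute precision/recall on real slides will be lower and must be
measured on real annotated data.

## Feature channels

13 per-pixel channels: CIE-LAB color (3); gradient magnitude of lightness
at blur σ = 0 and σ = 1.5 (2); oriented gradient energy
|cos θ · gx + sin θ · gy| at θ ∈ {0°, 45°, 90°, 135°} at full and half
resolution (block-mean downsample, nearest upsample) (8). Gradients are
centered finite differences (one-sided at borders). The 4-orientation set
is closed under 90° rotation, so the orientation-channel sum is invariant
under rotating the image and unrotating the stack (exact for even
dimensions; block means at odd sizes edge-pad).

## Structured random forest

Training samples are (flattened `d_in×d_in×13` window, binary
`d_out×d_out` contour patch) pairs; contour targets mark both sides of
every label interface (thick boundaries), and sampling is stratified so at
least 25% of patches contain a contour pixel in their center window.
Defaults `d_in=32`, `d_out=16` follow the structured-edge literature.

At each node the structured labels are mapped to two discrete classes:
256 pixel pairs are sampled, each label yields a binary same/different
vector, vectors are centered and projected on their first principal
direction (SVD, sign-fixed), and the projection sign is the class. Note
an all-zeros and an all-ones patch are deliberately equivalent under this
mapping (identical pair structure). Splits are axis-aligned
`1[x(k) < τ]` (x < τ goes right), maximizing Gini information gain over
256 candidate features per node × 16 interior quantile thresholds; ties
break to the lowest feature then lowest threshold. Stopping: depth 32,
fewer than 2×8 samples, pure node, or no positive gain. Leaves store the
member patch closest to the element-wise mean. Each of the 8 trees draws
50% of samples and 25% of features with seed `base_seed + tree_index`.
Tree count and sampling fractions have no canonical values in the
structured-edge literature; these defaults are exposed in
`ForestParams`/`PipelineConfig`.

Prediction anchors the patch grid to **global** image coordinates
(`grid_origin`): a tile crop therefore reproduces the full-image contour
values away from its borders, which is what makes tile-parallel output
bit-identical to the standalone run. Borders are mirror-padded by
`(d_in − d_out)/2`; per-pixel output is the mean of all tree votes
covering the pixel.

## Region candidates: deterministic watershed

Off-the-shelf flood-order watersheds break ties between equal-valued
ridge pixels by global queue order, so a crop can differ from the full
image by a pixel or two — enough to break the exact tiling contract.
`myoseg` instead uses a steepest-descent watershed built from local rules
only: (1) plateaus are lower-completed (each plateau pixel raised by
10⁻¹⁰ per BFS step from a descending exit, far below the contour-vote
quantum of ~1/32); (2) every non-minimum pixel points to its lowest
4-neighbor, ties broken by a fixed direction order, and pointer chains
are resolved by path doubling; (3) regional-minimum plateaus are the
markers; (4) for each 4-adjacent pair from different basins the higher
pixel (ties: the up/left one) becomes a 0-labeled line pixel. Redundant
line pixels (single distinct neighboring region) are absorbed in raster
order; 2×2 zero blocks at pinwheel junctions are repaired by shaving one
provably non-disconnecting region pixel (3×3 simple-point test). Regions
are then the 4-connected components of the nonzero mask, which guarantees
closedness and single-pixel-wide boundaries by construction.

Regions smaller than `min_region_area` (default 30 px, suppressing noise
minima) merge into the neighbor with the weakest shared boundary;
geometrically pinched fragments that cannot merge without joining two
regions dissolve into the boundary. Boundary statistics: each 0-pixel
contributes once to every unordered pair of distinct 4-neighbor regions;
`L` counts pixels, `B` is the mean contour value over them. Greedy
weakest-first merging with length-weighted `B` updates gives the
threshold hierarchy; partitions at increasing thresholds are nested
because lower thresholds are prefixes of the same merge sequence.

## Hierarchical CRF region selection

The merge tree (2N−1 nodes, ties by smallest label pair, disconnected
components joined last with virtual strength-1 edges) is cut at contours
stronger than `cut_threshold` (default 0.5) into independent subtrees;
cross-subtree pairwise terms are dropped — the approximation that makes
subtree minimizations independent and parallelizable.

Node features (14, fixed order): area; perimeter; circularity 4πA/P²
clamped to ≤ 1 (degenerate 1-px regions defined as 1); solidity;
eccentricity; mean and std of L, a, b inside; mean contour value on the
one-pixel ring around the region; mean contour value inside; their
guarded ratio (ε = 10⁻³). A 100-tree random forest (min_samples_leaf 2,
seeded) is trained on all merge-tree nodes of the training images —
the same candidate population scored at inference, so leaf fragments and
root-level giants appear as negatives and cell-sized merges as positives
(positive iff best IoU against a ground-truth cell ≥ 0.7, the standard
detection convention) — plus the regions of threshold merges at levels
(0.15, 0.3, 0.45, 0.6) and one empty interstitial field of view as hard
negatives (tissue-free tiles are common at whole-slide scale and would
otherwise be scored as one giant "cell").

Energy: unary `−log(s_i + ε)` selected / `−log(1 − s_i + ε)` unselected
(ε = 10⁻⁶ guards log 0), summed over **all** nodes (the convention for
unselected nodes is a choice; it shifts all energies by a labeling-
dependent amount and is flagged here for anyone comparing absolute
values). Pairwise `μ·e^{−B}·L` is paid for every adjacent base-region
pair whose induced labels (owning selected node, else background) differ:
splitting across a weak boundary is expensive, across a strong one cheap.
μ trades a per-boundary-pixel penalty against per-node log-probabilities;
μ = 0.01 keeps a typical cell's perimeter cost (~1) below typical unary
gains (~3) while still discouraging spurious splits — at μ = 0.1 the
perimeter term dominates and the empty labeling becomes optimal, which is
why the default deviates from round numbers.

Inference: subtrees with ≤ `max_exhaustive_leaves` (default 10) are
solved by exhaustive antichain enumeration (ties to the lexicographically
smallest selected set). Larger subtrees use a unary-only dynamic program
(exact for μ = 0) followed by steepest-descent local search over
single-node moves — flip off, flip on with eviction of conflicting
selections, demote to children, promote to parent — from three starts
(DP result, empty, all leaves), accepting only strict energy decreases;
the returned energy never exceeds the DP energy. Selected nodes become
output cells (boundary pixels strictly between a cell's own merged
regions are filled in); cells scoring below `score_threshold` (default
0.26, the PR operating point) are dropped.

## Tile-parallel processing

Cores form a `ceil(H/t) × ceil(W/t)` grid (default t = 1024), padded by
300 px per side and clipped at image borders; the padding absorbs every
cell whose diameter is under 300 px. Tiles are processed by an in-process
thread pool (numpy/scikit releases the GIL in the heavy kernels); results
are collected in tile order, so output is independent of scheduling. A
cell is kept iff its centroid lies in its tile's core; kept cells from
different tiles with mask IoU > 0.5 are deduplicated (deeper centroid
wins, ties to the earlier tile); masks are written in (tile, cell) order
with residual overlaps resolved in favor of the earlier cell. Per-tile
seeds are derived as `hash(base_seed, row, col)` for scheduling-
independent reproducibility, although inference itself consumes no
randomness.

## Evaluation

Greedy one-to-one matching by descending intersection area (ties to the
smaller id pair). Per-cell precision |S∩G|/|S|, recall |S∩G|/|G|,
F1 = 2PR/(P+R). Image-level averages penalize unmatched cells by default
(precision over all segmented cells, recall over all ground-truth cells,
F1 over max of the two counts); averaging matched pairs only is also
supported, because the convention changes absolute numbers and published
cell-wise averages often leave it unstated. PR sweeps re-threshold the per-cell scores of a single
pipeline run; the default grid includes 0.26.

## Problem sizes and numerical conventions

- Tests and the acceptance script train on two sibling 512×512 30-cell
  images (600 patches each, 8 trees) and evaluate on a held-out 512×512
  30-cell image; the tiling contract is checked on a 1200×1200 100-cell
  image with tile 600/pad 300 and 1, 2 and 4 workers. These sizes keep a
  full from-scratch run to a few CPU-minutes while matching the cell
  scale of the real data the method targets.
- Determinism: every stochastic step (generation, patch sampling, tree
  subsampling, node randomness, scorer) is driven by explicit
  `numpy.random.default_rng` seeds; identical configs and seeds give
  byte-identical images, models and segmentations.
- Degenerate inputs: flat contour maps give a single region; all-identical
  structured labels map to one class (the node becomes a leaf); empty
  boundary rings contribute 0 to contour features; regions above 65535
  cells are refused by the 16-bit label writer.

## Known limitations

- The pairwise term uses spatial adjacency of base regions; energies are
  therefore not comparable with implementations restricting pairs to
  sibling leaves.
- The local-search stage of `infer_fast` is a heuristic: it is exact for
  μ = 0 and lands within 5% of the exact energy on randomized 10-leaf
  trees, but carries no global guarantee for μ > 0.
- Oriented-watershed boundary reweighting and richer region descriptors
  from the wider literature are intentionally out of scope; the watershed
  here is unoriented and the 14 region features are a documented
  substitute.
- Synthetic-to-real transfer is untested by construction (no public
  dataset); retraining on annotated real tiles is expected before any
  biological use.
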