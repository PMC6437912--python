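"""Synthetic H&E-like skeletal muscle images with exact ground truth.

Muscle fibers in transverse H&E sections appear as convex, space-filling
polygons separated by thin, pale interstitial bands (endomysium).  The
generator emulates this morphology with a seeded Voronoi tessellation
(one Lloyd relaxation pass for size uniformity): each cell is the Voronoi
polygon eroded along its edges so an interstitial band of configurable
thickness separates adjacent cells.  Boundary bands are rendered at a
configurable contrast, individual boundary arcs can be "broken" (faded
towards the cell color) to emulate weak or missing contours, and per-cell
color jitter, Gaussian blur and pixel noise complete the rendering.  The
ground-truth label raster is purely geometric and unaffected by rendering
noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage.segmentation import find_boundaries

from .channels import compute_channels

# pale pink-white tone of interstitial tissue under H&E
INTERSTITIAL_RGB = np.array([238.0, 232.0, 240.0])


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic muscle image.

    Identical specs (including ``seed``) produce bit-identical outputs.
    """

    height: int = 512
    width: int = 512
    n_cells: int = 50
    boundary_thickness: float = 3.0
    boundary_contrast: float = 0.6
    boundary_break_prob: float = 0.1
    cell_color_mean: tuple = (200.0, 120.0, 150.0)
    cell_color_std: float = 12.0
    noise_std: float = 6.0
    blur_sigma: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.height < 64 or self.width < 64:
            raise ValueError(
                f"image dimensions must be >= 64, got {self.height}x{self.width}"
            )
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.boundary_thickness < 1:
            raise ValueError("boundary_thickness must be >= 1 pixel")
        if not 0.0 <= self.boundary_contrast <= 1.0:
            raise ValueError("boundary_contrast must be in [0, 1]")
        if not 0.0 <= self.boundary_break_prob <= 1.0:
            raise ValueError("boundary_break_prob must be in [0, 1]")
        if self.blur_sigma < 0:
            raise ValueError("blur_sigma must be >= 0")


@dataclass(frozen=True)
class GroundTruth:
    """Integer label raster: 0 = interstitial/background, k >= 1 = cell id."""

    labels: np.ndarray
    n_cells: int


@dataclass(frozen=True)
class PatchSample:
    """One training sample for the structured forest.

    ``x`` is the flattened d_in x d_in x 13 feature window, ``y`` the
    binary d_out x d_out contour patch at its center.
    """

    x: np.ndarray
    y: np.ndarray
    top_left: tuple


def _cell_connected(labels: np.ndarray, k: int, sl) -> bool:
    mask = labels[sl] == k
    if not mask.any():
        return False
    _, n = ndimage.label(mask)
    return n == 1


def _tessellate(spec: SyntheticSpec, rng: np.random.Generator):
    """Voronoi tessellation (1 Lloyd pass) -> (full labels, gt labels, pair ids)."""
    h, w = spec.height, spec.width
    n = spec.n_cells
    yy, xx = np.mgrid[0:h, 0:w]
    grid = np.column_stack([yy.ravel(), xx.ravel()]).astype(np.float64)

    for _ in range(20):
        pts = rng.uniform([0.0, 0.0], [h, w], size=(n, 2))
        # one Lloyd relaxation pass: move each seed to the centroid of its cell
        if n > 1:
            _, idx = cKDTree(pts).query(grid, k=1, workers=1)
            sums_y = np.bincount(idx, weights=grid[:, 0], minlength=n)
            sums_x = np.bincount(idx, weights=grid[:, 1], minlength=n)
            cnt = np.bincount(idx, minlength=n)
            nonempty = cnt > 0
            pts[nonempty, 0] = sums_y[nonempty] / cnt[nonempty]
            pts[nonempty, 1] = sums_x[nonempty] / cnt[nonempty]

        if n == 1:
            full = np.ones((h, w), dtype=np.int32)
            band = np.zeros((h, w), dtype=bool)
            pair = np.zeros((h, w), dtype=np.int64)
        else:
            dist, idx = cKDTree(pts).query(grid, k=2, workers=1)
            full = (idx[:, 0] + 1).astype(np.int32).reshape(h, w)
            band = (dist[:, 1] - dist[:, 0] < spec.boundary_thickness).reshape(h, w)
            a = np.minimum(idx[:, 0], idx[:, 1])
            b = np.maximum(idx[:, 0], idx[:, 1])
            pair = (a * n + b).reshape(h, w)

        # thin interstitial rim along the image border (tissue edge)
        m = max(1, int(round(spec.boundary_thickness / 2.0)))
        border = np.zeros((h, w), dtype=bool)
        border[:m, :] = border[-m:, :] = True
        border[:, :m] = border[:, -m:] = True
        band = band | border

        gt = np.where(band, 0, full).astype(np.int32)

        # every cell must survive erosion and stay connected
        slices = ndimage.find_objects(gt, max_label=n)
        ok = all(
            sl is not None and _cell_connected(gt, k + 1, sl)
            for k, sl in enumerate(slices)
        )
        if ok:
            return full, gt, pair
    raise RuntimeError(
        "failed to tessellate: too many cells for the image size "
        f"({n} cells in {h}x{w})"
    )


def generate_image(spec: SyntheticSpec):
    """Render a synthetic muscle image.

    Returns
    -------
    (image, gt):
        ``image`` is an ``H x W x 3`` uint8 RGB array, ``gt`` a
        :class:`GroundTruth` whose labels are unaffected by rendering noise.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    full, gt_labels, pair = _tessellate(spec, rng)
    h, w, n = spec.height, spec.width, spec.n_cells

    colors = np.asarray(spec.cell_color_mean, dtype=np.float64) + rng.normal(
        0.0, spec.cell_color_std, size=(n, 3)
    )
    img = colors[full - 1].reshape(h, w, 3)

    band = gt_labels == 0
    # decide which boundary arcs (adjacent cell pairs) are broken/faded
    if n > 1:
        band_pairs = np.unique(pair[band & (full > 0)])
        broken_draw = rng.random(band_pairs.size) < spec.boundary_break_prob
        broken_ids = set(band_pairs[broken_draw].tolist())
        broken_px = band & np.isin(pair, list(broken_ids) or [-1])
    else:
        broken_px = np.zeros((h, w), dtype=bool)

    tinted = band & ~broken_px
    c = spec.boundary_contrast
    img[tinted] = (1.0 - c) * img[tinted] + c * INTERSTITIAL_RGB

    if spec.blur_sigma > 0:
        for ch in range(3):
            img[..., ch] = ndimage.gaussian_filter(img[..., ch], spec.blur_sigma)
    if spec.noise_std > 0:
        img = img + rng.normal(0.0, spec.noise_std, size=img.shape)

    img = np.clip(img, 0, 255).astype(np.uint8)
    return img, GroundTruth(labels=gt_labels, n_cells=n)


def boundary_map(gt: GroundTruth) -> np.ndarray:
    """Binary contour target: 1 on cell/background and cell/cell interfaces.

    A pixel is marked when its 8-neighborhood contains a label different
    from its own (skimage ``find_boundaries`` in "thick" mode), so both
    sides of every interface are positive.  An all-background raster maps
    to an all-zero image.
    """
    labels = np.asarray(gt.labels)
    if labels.max() == 0:
        return np.zeros_like(labels, dtype=np.uint8)
    return find_boundaries(labels, connectivity=2, mode="thick").astype(np.uint8)


def sample_patches(
    image: np.ndarray,
    gt: GroundTruth,
    d_in: int = 32,
    d_out: int = 16,
    n: int = 500,
    seed: int = 0,
):
    """Sample ``n`` feature/label patch pairs for structured-forest training.

    Sampling is stratified so that at least 25% of patches contain a
    contour pixel in their d_out x d_out center window (positive patches
    are centered on contour pixels).  Features are the flattened
    d_in x d_in window of the 13-channel stack, computed once per image.
    """
    if d_out > d_in:
        raise ValueError("d_out must be <= d_in")
    if d_in % 2 or d_out % 2:
        raise ValueError("d_in and d_out must be even")
    if n < 1:
        raise ValueError("n must be >= 1")
    h, w = image.shape[:2]
    if min(h, w) < d_in:
        raise ValueError(f"image smaller than d_in={d_in}: {h}x{w}")

    stack = compute_channels(image).values.astype(np.float32)
    bmap = boundary_map(gt)
    rng = np.random.default_rng(seed)
    off = (d_in - d_out) // 2

    n_pos = math.ceil(0.25 * n)
    half = d_in // 2
    ys, xs = np.nonzero(
        bmap[half : h - half + 1, half : w - half + 1]
        if h - half + 1 > half and w - half + 1 > half
        else np.zeros((0, 0), dtype=np.uint8)
    )
    tops = []
    if ys.size > 0:
        pick = rng.integers(0, ys.size, size=n_pos)
        tops.extend(zip((ys[pick]).tolist(), (xs[pick]).tolist()))
    n_rand = n - len(tops)
    ry = rng.integers(0, h - d_in + 1, size=n_rand)
    rx = rng.integers(0, w - d_in + 1, size=n_rand)
    tops.extend(zip(ry.tolist(), rx.tolist()))

    samples = []
    for (ty, tx) in tops:
        x = stack[ty : ty + d_in, tx : tx + d_in, :].ravel().copy()
        y = bmap[ty + off : ty + off + d_out, tx + off : tx + off + d_out].copy()
        samples.append(PatchSample(x=x, y=y, top_left=(int(ty), int(tx))))
    return samples


def sample_region_training_set(
    region_map,
    gt: GroundTruth,
    image: np.ndarray,
    contour,
    iou_pos: float = 0.7,
):
    """Label candidate regions against ground truth for scorer training.

    A region is positive when its best IoU against any ground-truth cell
    is at least ``iou_pos`` (default 0.7, the usual object-detection
    convention).  Features are those of
    :func:`myoseg.hierarchy.region_features`.

    Returns a list of ``(feature_vector, binary_label)`` pairs, one per
    region of ``region_map``.
    """
    from skimage.color import rgb2lab

    from .hierarchy import region_features

    labels = region_map.labels
    if region_map.n_regions < 1:
        raise ValueError("empty region map")
    if labels.shape != gt.labels.shape:
        raise ValueError("region map and ground truth must be aligned")

    n_r = int(labels.max())
    n_g = int(gt.labels.max())
    both = (labels > 0) & (gt.labels > 0)
    keys = labels[both].astype(np.int64) * (n_g + 1) + gt.labels[both]
    inter = np.bincount(keys, minlength=(n_r + 1) * (n_g + 1)).reshape(
        n_r + 1, n_g + 1
    )
    area_r = np.bincount(labels.ravel(), minlength=n_r + 1)
    area_g = np.bincount(gt.labels.ravel(), minlength=n_g + 1)

    img = np.asarray(image, dtype=np.float64)
    lab = rgb2lab(img / 255.0 if image.dtype == np.uint8 else img)
    cvals = contour.values

    out = []
    for r in range(1, n_r + 1):
        ious = inter[r, 1:] / (
            area_r[r] + area_g[1:] - inter[r, 1:] + 1e-12
        )
        label = int(ious.size > 0 and float(ious.max()) >= iou_pos)
        feats = region_features(labels == r, lab, cvals)
        out.append((feats, label))
    return out
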