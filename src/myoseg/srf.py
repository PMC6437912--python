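"""Structured random forest (SRF) contour detector.

Each tree maps a flattened d_in x d_in x 13 feature window to a binary
d_out x d_out contour patch stored at its leaves.  Node splitting follows
the usual axis-aligned rule h(x, theta) = 1[x(k) < tau] with (k, tau)
chosen by maximizing Gini information gain; since labels are structured
patches, they are first mapped into two discrete classes at every node by
comparing sampled pixel pairs and projecting the comparison vectors onto
their first principal direction.  Prediction slides the forest over a
stride grid and averages all overlapping patch votes per pixel.
"""

from __future__ import annotations

from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .channels import N_CHANNELS, compute_channels
from .regions import ContourMap


@dataclass(frozen=True)
class ForestParams:
    """Structured-forest hyperparameters.

    ``d_in``/``d_out`` are the feature/label window sizes (even pixels).
    Each tree draws ``sample_frac`` of the samples and ``feature_frac`` of
    the features; at each node ``n_split_features`` candidate features and
    ``n_thresholds`` quantile thresholds are tried.  The structured-label
    class mapping uses ``n_map_pairs`` sampled pixel pairs per node.
    """

    n_trees: int = 8
    d_in: int = 32
    d_out: int = 16
    feature_frac: float = 0.25
    sample_frac: float = 0.5
    max_depth: int = 32
    min_samples_leaf: int = 8
    n_split_features: int = 256
    n_thresholds: int = 16
    n_map_pairs: int = 256

    def validate(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.d_out > self.d_in or self.d_in % 2 or self.d_out % 2:
            raise ValueError("require even d_out <= d_in")
        if not (0 < self.feature_frac <= 1 and 0 < self.sample_frac <= 1):
            raise ValueError("fractions must be in (0, 1]")


@dataclass
class TreeNode:
    """Split node (feature, threshold, children) or leaf (stored patch)."""

    feature: Optional[int] = None
    threshold: Optional[float] = None
    left: Optional["TreeNode"] = None
    right: Optional["TreeNode"] = None
    leaf_label: Optional[np.ndarray] = None

    @property
    def is_leaf(self) -> bool:
        return self.leaf_label is not None


@dataclass
class ForestModel:
    trees: list
    params: ForestParams
    seed: int
    n_channels: int = N_CHANNELS


# ---------------------------------------------------------------------------
# structured-label machinery


def map_labels_to_classes(labels: np.ndarray, n_pairs: int, seed: int) -> np.ndarray:
    """Map structured binary label patches to two discrete classes.

    For every label patch, ``n_pairs`` pixel pairs are sampled (the same
    pairs for all patches) and compared (same value / different value);
    the resulting binary vectors are centered and projected onto their
    first principal direction, and the sign of the projection defines the
    class.  Identical labels always land in one class.
    """
    labels = np.asarray(labels)
    if labels.ndim > 2:
        labels = labels.reshape(labels.shape[0], -1)
    if labels.shape[0] < 2:
        raise ValueError("need at least 2 labels")
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    rng = np.random.default_rng(seed)
    m = labels.shape[1]
    p1 = rng.integers(0, m, size=n_pairs)
    p2 = rng.integers(0, m, size=n_pairs)
    z = (labels[:, p1] == labels[:, p2]).astype(np.float64)
    zc = z - z.mean(axis=0, keepdims=True)
    if not np.any(zc):
        return np.zeros(labels.shape[0], dtype=np.int64)
    _, _, vt = np.linalg.svd(zc, full_matrices=False)
    v = vt[0]
    nz = np.nonzero(np.abs(v) > 1e-12)[0]
    if nz.size and v[nz[0]] < 0:
        v = -v
    proj = zc @ v
    return (proj >= 0).astype(np.int64)


def gini_impurity(class_proportions) -> float:
    """Gini impurity sum_l c_l (1 - c_l) of a class-proportion vector."""
    p = np.asarray(class_proportions, dtype=np.float64)
    if np.any(p < -1e-12):
        raise ValueError("proportions must be nonnegative")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("proportions must sum to 1")
    return float(np.sum(p * (1.0 - p)))


def _gini_from_counts(counts: np.ndarray) -> float:
    n = counts.sum()
    if n == 0:
        return 0.0
    p = counts / n
    return float(np.sum(p * (1.0 - p)))


def information_gain(parent_classes, left_classes, right_classes) -> float:
    """Gini information gain of splitting ``parent`` into ``left``/``right``."""
    parent = np.sort(np.asarray(parent_classes))
    left = np.asarray(left_classes)
    right = np.asarray(right_classes)
    if parent.size == 0:
        raise ValueError("empty parent")
    if not np.array_equal(np.sort(np.concatenate([left, right])), parent):
        raise ValueError("left and right must partition the parent multiset")
    k = int(parent.max()) + 1 if parent.size else 1
    h_p = _gini_from_counts(np.bincount(parent, minlength=k))
    h = h_p
    for side in (left, right):
        if side.size:
            h -= (side.size / parent.size) * _gini_from_counts(
                np.bincount(side, minlength=k)
            )
    return float(h)


def best_split(
    X: np.ndarray,
    classes: np.ndarray,
    candidate_features,
    n_thresholds: int = 16,
    seed: int = 0,
):
    """Best (feature, threshold) over quantile candidates by Gini gain.

    Thresholds are ``n_thresholds`` interior quantiles of each candidate
    feature's observed values.  Ties break toward the lowest feature index,
    then the lowest threshold.  Returns ``None`` when no split has positive
    gain.  ``seed`` is accepted for interface stability; the search itself
    is deterministic.
    """
    classes = np.asarray(classes)
    n = classes.size
    if n < 2 or np.unique(classes).size < 2:
        return None
    k_classes = int(classes.max()) + 1
    onehot = np.zeros((n, k_classes), dtype=np.float64)
    onehot[np.arange(n), classes] = 1.0
    total = onehot.sum(axis=0)
    h_parent = _gini_from_counts(total)

    qs = (np.arange(1, n_thresholds + 1)) / (n_thresholds + 1)
    best = None  # (gain, k, tau)
    for k in sorted(int(f) for f in candidate_features):
        col = X[:, k].astype(np.float64)
        taus = np.unique(np.quantile(col, qs))
        if taus.size == 0:
            continue
        mask = col[:, None] < taus[None, :]  # n x T; True -> right branch
        n_right = mask.sum(axis=0)
        valid = (n_right > 0) & (n_right < n)
        if not valid.any():
            continue
        cnt_right = onehot.T @ mask  # k_classes x T
        cnt_left = total[:, None] - cnt_right
        with np.errstate(invalid="ignore", divide="ignore"):
            pr = cnt_right / np.maximum(n_right, 1)
            nl = n - n_right
            pl = cnt_left / np.maximum(nl, 1)
            h_r = np.sum(pr * (1 - pr), axis=0)
            h_l = np.sum(pl * (1 - pl), axis=0)
        gain = h_parent - (n_right / n) * h_r - (nl / n) * h_l
        gain[~valid] = -np.inf
        for t_idx in range(taus.size):
            g = gain[t_idx]
            if g > 1e-12 and (best is None or g > best[0] + 1e-15):
                best = (float(g), k, float(taus[t_idx]))
    if best is None:
        return None
    return best[1], best[2], best[0]


def select_representative_label(labels: np.ndarray) -> np.ndarray:
    """The member label closest (squared distance) to the element-wise mean."""
    labels = np.asarray(labels)
    flat = labels.reshape(labels.shape[0], -1).astype(np.float64)
    if flat.shape[0] == 0:
        raise ValueError("need at least one label")
    mean = flat.mean(axis=0)
    d2 = ((flat - mean) ** 2).sum(axis=1)
    return labels[int(np.argmin(d2))].copy()


# ---------------------------------------------------------------------------
# training


def train_tree(
    X: np.ndarray,
    Y: np.ndarray,
    params: ForestParams,
    seed: int,
    feature_subset: Optional[np.ndarray] = None,
) -> TreeNode:
    """Train one structured tree by recursive splitting.

    The structured-to-discrete class mapping is recomputed at every node.
    Stopping: max depth, fewer than 2 x min_samples_leaf samples, a pure
    node, or no split with positive gain.
    """
    X = np.asarray(X)
    Y = np.asarray(Y)
    if X.shape[0] == 0:
        raise ValueError("empty training set")
    params.validate()
    if feature_subset is None:
        feature_subset = np.arange(X.shape[1])
    rng = np.random.default_rng(seed)

    def build(idx: np.ndarray, depth: int) -> TreeNode:
        node_seed = int(rng.integers(0, 2**31 - 1))
        if depth >= params.max_depth or idx.size < 2 * params.min_samples_leaf:
            return TreeNode(leaf_label=select_representative_label(Y[idx]))
        classes = map_labels_to_classes(
            Y[idx].reshape(idx.size, -1), params.n_map_pairs, seed=node_seed
        )
        if np.unique(classes).size < 2:
            return TreeNode(leaf_label=select_representative_label(Y[idx]))
        n_cand = min(params.n_split_features, feature_subset.size)
        cand = rng.choice(feature_subset, size=n_cand, replace=False)
        split = best_split(X[idx], classes, cand, params.n_thresholds)
        if split is None:
            return TreeNode(leaf_label=select_representative_label(Y[idx]))
        k, tau, _ = split
        go_right = X[idx, k] < tau
        left_idx, right_idx = idx[~go_right], idx[go_right]
        if (
            left_idx.size < params.min_samples_leaf
            or right_idx.size < params.min_samples_leaf
        ):
            return TreeNode(leaf_label=select_representative_label(Y[idx]))
        return TreeNode(
            feature=int(k),
            threshold=float(tau),
            left=build(left_idx, depth + 1),
            right=build(right_idx, depth + 1),
        )

    return build(np.arange(X.shape[0]), 0)


def train_forest(X: np.ndarray, Y: np.ndarray, params: ForestParams, seed: int = 0):
    """Train ``params.n_trees`` trees, each on its own sample/feature subset.

    Tree ``j`` uses seed ``seed + j`` for its subsampling and its node
    randomness, so training is fully reproducible.
    """
    X = np.asarray(X, dtype=np.float32)
    Y = np.asarray(Y)
    params.validate()
    if X.shape[0] < params.min_samples_leaf:
        raise ValueError("not enough training samples")
    n, n_feat = X.shape
    trees = []
    for j in range(params.n_trees):
        tree_seed = seed + j
        rng = np.random.default_rng(tree_seed)
        n_rows = max(2, int(round(params.sample_frac * n)))
        rows = np.sort(rng.choice(n, size=min(n_rows, n), replace=False))
        n_feats = max(1, int(round(params.feature_frac * n_feat)))
        feats = np.sort(rng.choice(n_feat, size=n_feats, replace=False))
        trees.append(train_tree(X[rows], Y[rows], params, tree_seed, feats))
    return ForestModel(trees=trees, params=params, seed=seed)


def predict_patches(tree: TreeNode, X: np.ndarray) -> np.ndarray:
    """Apply one tree to a matrix of flattened feature vectors."""
    X = np.asarray(X)
    out = []
    for row in X:
        node = tree
        while not node.is_leaf:
            node = node.right if row[node.feature] < node.threshold else node.left
        out.append(node.leaf_label)
    return np.stack(out)


# ---------------------------------------------------------------------------
# prediction


def _tree_votes(tree, padded, ypos, xpos, d_in, d_out, n_ch, acc_shape):
    """Accumulate one tree's leaf patches over all patch positions."""
    acc = np.zeros(acc_shape, dtype=np.float64)
    stack = [(tree, np.arange(ypos.size))]
    while stack:
        node, idx = stack.pop()
        if idx.size == 0:
            continue
        if node.is_leaf:
            patch = node.leaf_label.astype(np.float64)
            for i in idx:
                y, x = ypos[i], xpos[i]
                acc[y : y + d_out, x : x + d_out] += patch
            continue
        k = node.feature
        ch = k % n_ch
        rest = k // n_ch
        pc = rest % d_in
        pr = rest // d_in
        vals = padded[ypos[idx] + pr, xpos[idx] + pc, ch]
        go_right = vals < node.threshold
        stack.append((node.right, idx[go_right]))
        stack.append((node.left, idx[~go_right]))
    return acc


def predict_contours(
    image: np.ndarray,
    model: ForestModel,
    stride: Optional[int] = None,
    n_workers: int = 1,
    grid_origin: tuple = (0, 0),
) -> ContourMap:
    """Slide the forest over the image and average all patch votes.

    The image border is mirror-padded so every pixel is covered; the
    per-pixel output is the mean of all tree votes covering it, hence in
    [0, 1].  Results are identical for any ``n_workers >= 1``.

    ``grid_origin`` is the global coordinate of the image's top-left pixel
    when the image is a crop of a larger one: the patch grid is anchored
    to global multiples of ``stride`` so that crop predictions match the
    full-image prediction away from the crop borders.
    """
    params = model.params
    d_in, d_out = params.d_in, params.d_out
    if stride is None:
        stride = d_out
    if stride > d_out:
        raise ValueError("stride must be <= d_out (coverage gaps otherwise)")
    h, w = image.shape[:2]
    if min(h, w) < d_in:
        raise ValueError(f"image min side must be >= d_in={d_in}")

    stack = compute_channels(image).values.astype(np.float32)
    pad = (d_in - d_out) // 2
    padded = np.pad(stack, ((pad, pad), (pad, pad), (0, 0)), mode="reflect")

    def grid(size, origin):
        first = (-int(origin)) % stride
        pos = list(range(first, size - d_out + 1, stride))
        if not pos or pos[0] != 0:
            pos.insert(0, 0)
        if pos[-1] != size - d_out:
            pos.append(size - d_out)
        return pos

    ys, xs = grid(h, grid_origin[0]), grid(w, grid_origin[1])
    ypos, xpos = np.meshgrid(ys, xs, indexing="ij")
    ypos, xpos = ypos.ravel(), xpos.ravel()

    coverage = np.zeros((h, w), dtype=np.float64)
    one = np.ones((d_out, d_out))
    for y, x in zip(ypos, xpos):
        coverage[y : y + d_out, x : x + d_out] += one

    args = (padded, ypos, xpos, d_in, d_out, model.n_channels, (h, w))
    if n_workers <= 1 or len(model.trees) == 1:
        accs = [_tree_votes(t, *args) for t in model.trees]
    else:
        with ThreadPoolExecutor(max_workers=n_workers) as pool:
            accs = list(pool.map(lambda t: _tree_votes(t, *args), model.trees))
    total = np.sum(accs, axis=0)
    values = total / (coverage * len(model.trees))
    return ContourMap(values=np.clip(values, 0.0, 1.0))
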