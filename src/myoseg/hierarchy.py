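"""Hierarchical tree-based region selection.

The N base regions of an over-segmented candidate map are pair-wise merged
(weakest shared boundary first) into a binary merge tree with 2N-1 nodes;
every node is a candidate region.  A random-forest scorer assigns each
node a probability s_i of being a complete cell, and the final segments
are the antichain of tree nodes (no selected node an ancestor of another,
so selected regions are pairwise disjoint) minimizing the energy

    E = sum_i U_i + sum_{(i,j) adjacent leaves} V_ij,

with U_i = -log(s_i + eps) for selected nodes and -log(1 - s_i + eps)
otherwise, and V_ij = mu * exp(-B_ij) * L_ij applied whenever the two
adjacent base regions end up with different induced labels: splitting
across a weak boundary (small B, long L) is penalized.

Large trees are cut top-down at strong contours (shared boundary strength
above ``cut_threshold``) into independent subtrees, each minimized
separately: exhaustively for small subtrees, by a unary-only dynamic
program plus greedy local search for large ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional

import numpy as np
from skimage import measure
from scipy import ndimage
from sklearn.ensemble import RandomForestClassifier

from .regions import ContourMap, RegionAdjacency, RegionMap, merge_sequence

FEATURE_NAMES = (
    "area",
    "perimeter",
    "circularity",
    "solidity",
    "eccentricity",
    "mean_L",
    "mean_a",
    "mean_b",
    "std_L",
    "std_a",
    "std_b",
    "contour_boundary_mean",
    "contour_interior_mean",
    "contour_boundary_interior_ratio",
)


class SubtreeTooLarge(Exception):
    """Raised when a subtree exceeds the exact-inference leaf budget."""


@dataclass
class Node:
    id: int
    left: Optional[int] = None
    right: Optional[int] = None
    region_label: Optional[int] = None
    merge_b: float = 0.0

    @property
    def is_leaf(self) -> bool:
        return self.left is None


@dataclass
class RegionTree:
    """Binary merge tree; leaves carry base-region labels."""

    nodes: Dict[int, Node]
    root: int

    def __post_init__(self):
        self._parent = {}
        self._leaves_under = {}
        for n in self.nodes.values():
            if not n.is_leaf:
                self._parent[n.left] = n.id
                self._parent[n.right] = n.id

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def leaf_ids(self) -> List[int]:
        return sorted(n.id for n in self.nodes.values() if n.is_leaf)

    @property
    def n_leaves(self) -> int:
        return sum(1 for n in self.nodes.values() if n.is_leaf)

    def parent(self, node_id: int) -> Optional[int]:
        return self._parent.get(node_id)

    def ancestors(self, node_id: int):
        p = self.parent(node_id)
        while p is not None:
            yield p
            p = self.parent(p)

    def leaves_under(self, node_id: int) -> frozenset:
        cached = self._leaves_under.get(node_id)
        if cached is not None:
            return cached
        node = self.nodes[node_id]
        if node.is_leaf:
            res = frozenset([node_id])
        else:
            res = self.leaves_under(node.left) | self.leaves_under(node.right)
        self._leaves_under[node_id] = res
        return res


@dataclass
class EnergyModel:
    """Unary scores per node and pairwise (B, L) per adjacent leaf pair."""

    scores: Dict[int, float]
    pairwise: List[tuple]  # (leaf_i, leaf_j, B, L)
    mu: float = 0.01
    epsilon: float = 1e-6


@dataclass(frozen=True)
class Labeling:
    """Antichain of selected node ids (complete-cell regions)."""

    selected: frozenset


# ---------------------------------------------------------------------------
# tree construction


def _clusters_to_forest(adjacency: RegionAdjacency, leaf_ids, stop_b: float):
    """Run the greedy merge sequence and build one tree per final cluster."""
    merges = merge_sequence(adjacency, stop_b)
    nodes = {i: Node(id=i, region_label=i) for i in leaf_ids}
    cluster_node = {i: i for i in leaf_ids}
    next_id = max(leaf_ids) + 1 if leaf_ids else 1
    for keep, drop, b in merges:
        node = Node(
            id=next_id,
            left=min(cluster_node[keep], cluster_node[drop]),
            right=max(cluster_node[keep], cluster_node[drop]),
            merge_b=b,
        )
        nodes[next_id] = node
        cluster_node[keep] = next_id
        del cluster_node[drop]
        next_id += 1
    return nodes, cluster_node, next_id


def _collect_subtree(nodes: Dict[int, Node], root: int) -> Dict[int, Node]:
    out = {}
    stack = [root]
    while stack:
        nid = stack.pop()
        node = nodes[nid]
        out[nid] = node
        if not node.is_leaf:
            stack.extend([node.left, node.right])
    return out


def build_tree(regions: RegionMap, adjacency: RegionAdjacency) -> RegionTree:
    """Agglomerate the N base regions into a single 2N-1-node merge tree.

    The adjacent pair with the weakest current boundary merges first (ties
    by smallest label pair); merged boundaries take the length-weighted
    mean strength.  Disconnected adjacency components are joined at the
    end, in ascending representative order, with virtual strength-1 edges.
    """
    leaf_ids = list(range(1, regions.n_regions + 1))
    if not leaf_ids:
        raise ValueError("region map has no regions")
    nodes, cluster_node, next_id = _clusters_to_forest(
        adjacency, leaf_ids, stop_b=np.inf
    )
    reps = sorted(cluster_node)
    while len(reps) > 1:  # disconnected components: join with B=1 virtual edges
        a, b = reps[0], reps[1]
        nodes[next_id] = Node(
            id=next_id,
            left=min(cluster_node[a], cluster_node[b]),
            right=max(cluster_node[a], cluster_node[b]),
            merge_b=1.0,
        )
        cluster_node[a] = next_id
        del cluster_node[b]
        next_id += 1
        reps = sorted(cluster_node)
    root = cluster_node[reps[0]]
    return RegionTree(nodes=nodes, root=root)


def cut_tree(
    tree: RegionTree, adjacency: RegionAdjacency, cut_threshold: float
) -> List[RegionTree]:
    """Cut the hierarchy at strong contours into independent subtrees.

    Equivalent to re-running the agglomeration while forbidding any merge
    whose current boundary strength exceeds ``cut_threshold``; the leaf
    sets of the returned subtrees partition the base regions, and energy
    minimization on different subtrees is independent (cross-subtree
    pairwise terms are dropped).
    """
    if not 0.0 <= cut_threshold <= 1.0:
        raise ValueError("cut_threshold must be in [0, 1]")
    leaf_ids = sorted(tree.leaves_under(tree.root))
    nodes, cluster_node, _ = _clusters_to_forest(
        adjacency, leaf_ids, stop_b=np.nextafter(cut_threshold, np.inf)
    )
    forest = []
    for rep in sorted(cluster_node):
        root = cluster_node[rep]
        forest.append(RegionTree(nodes=_collect_subtree(nodes, root), root=root))
    return forest


# ---------------------------------------------------------------------------
# region features and scoring


def region_features(
    mask: np.ndarray, lab_image: np.ndarray, contour_values: np.ndarray
) -> np.ndarray:
    """Fixed-order feature vector of one candidate region (see FEATURE_NAMES).

    Shape cues (area, perimeter, circularity 4*pi*A/P^2 clamped to <= 1,
    solidity, eccentricity), CIE-LAB color statistics inside the region,
    and contour-map statistics: mean contour value on the one-pixel ring
    around the region, mean in the interior, and their guarded ratio.
    """
    mask = np.asarray(mask, dtype=bool)
    area = int(mask.sum())
    if area == 0:
        raise ValueError("empty region")
    perimeter = float(measure.perimeter(mask))
    circularity = 1.0 if perimeter <= 0 else min(
        4.0 * math.pi * area / perimeter**2, 1.0
    )
    props = measure.regionprops(mask.astype(np.uint8))[0]
    solidity = float(props.solidity)
    eccentricity = float(props.eccentricity)
    inside = lab_image[mask]
    means = inside.mean(axis=0)
    stds = inside.std(axis=0)
    ring = ndimage.binary_dilation(mask, structure=np.ones((3, 3), bool)) & ~mask
    b_mean = float(contour_values[ring].mean()) if ring.any() else 0.0
    i_mean = float(contour_values[mask].mean())
    ratio = (b_mean + 1e-3) / (i_mean + 1e-3)
    return np.array(
        [
            float(area),
            perimeter,
            circularity,
            solidity,
            eccentricity,
            *means,
            *stds,
            b_mean,
            i_mean,
            ratio,
        ],
        dtype=np.float64,
    )


@dataclass
class RegionScorer:
    """Probability-outputting cell classifier over region features."""

    model: RandomForestClassifier
    feature_names: tuple = FEATURE_NAMES

    def score(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        proba = self.model.predict_proba(X)
        return proba[:, list(self.model.classes_).index(1)]


def train_region_scorer(
    X: np.ndarray, y: np.ndarray, seed: int = 0, n_estimators: int = 100
) -> RegionScorer:
    """Train the random-forest cell scorer; requires both classes present."""
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.int64)
    if np.unique(y).size < 2:
        raise ValueError("training set must contain positives and negatives")
    rf = RandomForestClassifier(
        n_estimators=n_estimators,
        min_samples_leaf=2,
        random_state=int(seed),
        n_jobs=1,
    )
    rf.fit(X, y)
    return RegionScorer(model=rf)


def _postorder(tree: RegionTree) -> List[int]:
    visit = []
    st = [(tree.root, False)]
    while st:
        nid, done = st.pop()
        node = tree.nodes[nid]
        if node.is_leaf or done:
            visit.append(nid)
        else:
            st.append((nid, True))
            st.append((node.right, False))
            st.append((node.left, False))
    return visit


def node_masks(tree: RegionTree, region_map: RegionMap):
    """Yield ``(node_id, bbox, mask)`` in post-order, cropped to bounding boxes.

    ``bbox`` is ``(y0, x0, y1, x1)`` half-open and ``mask`` covers exactly
    that window.  Parents union their children into the merged bounding
    box; masks of consumed children are released, so peak memory is one
    mask per level of the current root-to-leaf path.
    """
    labels = region_map.labels
    slices = ndimage.find_objects(labels, max_label=region_map.n_regions)
    store = {}
    for nid in _postorder(tree):
        node = tree.nodes[nid]
        if node.is_leaf:
            sl = slices[node.region_label - 1]
            if sl is None:
                raise ValueError(f"region {node.region_label} missing from map")
            bbox = (sl[0].start, sl[1].start, sl[0].stop, sl[1].stop)
            mask = labels[sl] == node.region_label
        else:
            (ly0, lx0, ly1, lx1), lmask = store.pop(node.left)
            (ry0, rx0, ry1, rx1), rmask = store.pop(node.right)
            bbox = (min(ly0, ry0), min(lx0, rx0), max(ly1, ry1), max(lx1, rx1))
            y0, x0, y1, x1 = bbox
            mask = np.zeros((y1 - y0, x1 - x0), dtype=bool)
            mask[ly0 - y0 : ly1 - y0, lx0 - x0 : lx1 - x0] |= lmask
            mask[ry0 - y0 : ry1 - y0, rx0 - x0 : rx1 - x0] |= rmask
        store[nid] = (bbox, mask)
        yield nid, bbox, mask


def node_features(
    tree: RegionTree,
    region_map: RegionMap,
    lab_image: np.ndarray,
    contour: ContourMap,
):
    """Feature matrix for every node of a tree, in post-order.

    Features are computed on bounding-box crops expanded by one pixel so
    the boundary ring statistics match a full-image computation.  Returns
    ``(node_ids, X)``.
    """
    h, w = region_map.labels.shape
    ids, feats = [], []
    for nid, (y0, x0, y1, x1), mask in node_masks(tree, region_map):
        gy0, gx0 = max(0, y0 - 1), max(0, x0 - 1)
        gy1, gx1 = min(h, y1 + 1), min(w, x1 + 1)
        win = np.zeros((gy1 - gy0, gx1 - gx0), dtype=bool)
        win[y0 - gy0 : y1 - gy0, x0 - gx0 : x1 - gx0] = mask
        ids.append(nid)
        feats.append(
            region_features(
                win,
                lab_image[gy0:gy1, gx0:gx1],
                contour.values[gy0:gy1, gx0:gx1],
            )
        )
    return ids, np.stack(feats)


def node_iou_labels(
    tree: RegionTree,
    region_map: RegionMap,
    gt_labels: np.ndarray,
    iou_pos: float = 0.7,
) -> Dict[int, int]:
    """Binary cell label per node: best IoU against any ground-truth cell.

    Intersection vectors are accumulated bottom-up from the leaf/GT
    contingency table, so the cost is independent of node sizes.
    """
    labels = region_map.labels
    n_r, n_g = region_map.n_regions, int(gt_labels.max())
    both = (labels > 0) & (gt_labels > 0)
    inter = np.zeros((n_r + 1, n_g + 1), dtype=np.int64)
    if n_g > 0 and both.any():
        keys = labels[both].astype(np.int64) * (n_g + 1) + gt_labels[both]
        inter = np.bincount(keys, minlength=(n_r + 1) * (n_g + 1)).reshape(
            n_r + 1, n_g + 1
        )
    area_r = np.bincount(labels.ravel(), minlength=n_r + 1)
    area_g = np.bincount(gt_labels.ravel(), minlength=n_g + 1)

    out = {}
    vec, area = {}, {}
    for nid in _postorder(tree):
        node = tree.nodes[nid]
        if node.is_leaf:
            vec[nid] = inter[node.region_label, 1:].astype(np.float64)
            area[nid] = float(area_r[node.region_label])
        else:
            vec[nid] = vec[node.left] + vec[node.right]
            area[nid] = area[node.left] + area[node.right]
        if n_g == 0:
            out[nid] = 0
            continue
        ious = vec[nid] / (area[nid] + area_g[1:] - vec[nid] + 1e-12)
        out[nid] = int(ious.size > 0 and float(ious.max()) >= iou_pos)
    return out


def score_nodes(
    tree: RegionTree,
    scorer: RegionScorer,
    region_map: RegionMap,
    lab_image: np.ndarray,
    contour: ContourMap,
) -> Dict[int, float]:
    """Score every node of a tree; deterministic given the scorer's seed."""
    ids, X = node_features(tree, region_map, lab_image, contour)
    scores = scorer.score(X)
    return {nid: float(s) for nid, s in zip(ids, scores)}


# ---------------------------------------------------------------------------
# energy and inference


def is_antichain(tree: RegionTree, selected) -> bool:
    sel = set(selected)
    for nid in sel:
        if any(a in sel for a in tree.ancestors(nid)):
            return False
    return True


def _leaf_owners(tree: RegionTree, selected) -> Dict[int, int]:
    owners = {}
    for nid in selected:
        for leaf in tree.leaves_under(nid):
            owners[leaf] = nid
    return owners


def energy(labeling: Labeling, tree: RegionTree, model: EnergyModel) -> float:
    """CRF energy of an antichain labeling (see module docstring).

    Every node contributes a unary term for its own binary label; the
    pairwise penalty mu * exp(-B) * L is added for each adjacent base-region
    pair whose induced labels (owning selected node, or background) differ.
    """
    sel = labeling.selected
    if not is_antichain(tree, sel):
        raise ValueError("labeling violates the antichain (non-overlap) constraint")
    eps = model.epsilon
    e = 0.0
    for nid in tree.nodes:
        s = model.scores[nid]
        e += -math.log(s + eps) if nid in sel else -math.log(1.0 - s + eps)
    if model.mu != 0.0 and model.pairwise:
        owners = _leaf_owners(tree, sel)
        for i, j, b, l in model.pairwise:
            if owners.get(i, 0) != owners.get(j, 0):
                e += model.mu * math.exp(-b) * l
    return float(e)


def _enumerate_antichains(tree: RegionTree, nid: int) -> List[frozenset]:
    node = tree.nodes[nid]
    if node.is_leaf:
        return [frozenset(), frozenset([nid])]
    out = [frozenset([nid])]
    lefts = _enumerate_antichains(tree, node.left)
    rights = _enumerate_antichains(tree, node.right)
    for a in lefts:
        for b in rights:
            out.append(a | b)
    return out


def infer_exact(
    subtree: RegionTree, model: EnergyModel, max_leaves: int = 16
) -> Labeling:
    """Global minimizer by exhaustive antichain enumeration.

    Ties break toward the lexicographically smallest selected set.  Raises
    :class:`SubtreeTooLarge` beyond ``max_leaves`` leaves; callers fall
    back to :func:`infer_fast`.
    """
    if subtree.n_leaves > max_leaves:
        raise SubtreeTooLarge(
            f"{subtree.n_leaves} leaves exceeds max_leaves={max_leaves}"
        )
    eps = model.epsilon
    u0 = {n: -math.log(1.0 - model.scores[n] + eps) for n in subtree.nodes}
    u1 = {n: -math.log(model.scores[n] + eps) for n in subtree.nodes}
    base = sum(u0.values())
    use_pair = model.mu != 0.0 and bool(model.pairwise)
    best_e, best_sel = None, None
    for sel in _enumerate_antichains(subtree, subtree.root):
        e = base + sum(u1[n] - u0[n] for n in sel)
        if use_pair:
            owners = _leaf_owners(subtree, sel)
            for i, j, b, l in model.pairwise:
                if owners.get(i, 0) != owners.get(j, 0):
                    e += model.mu * math.exp(-b) * l
        key = tuple(sorted(sel))
        if (
            best_e is None
            or e < best_e - 1e-15
            or (abs(e - best_e) <= 1e-15 and key < best_sel)
        ):
            best_e, best_sel = e, key
    return Labeling(selected=frozenset(best_sel))


def _dp_unary(subtree: RegionTree, model: EnergyModel) -> frozenset:
    """Exact unary-only minimizer: per node, min(select, best of children)."""
    eps = model.epsilon
    u0 = {n: -math.log(1.0 - model.scores[n] + eps) for n in subtree.nodes}
    u1 = {n: -math.log(model.scores[n] + eps) for n in subtree.nodes}
    s0 = {}  # all-unselected cost of the subtree below each node
    best = {}  # minimal cost of the subtree below each node
    take = {}
    order = []
    stack = [(subtree.root, False)]
    while stack:
        nid, done = stack.pop()
        node = subtree.nodes[nid]
        if node.is_leaf or done:
            order.append(nid)
        else:
            stack.append((nid, True))
            stack.append((node.right, False))
            stack.append((node.left, False))
    for nid in order:
        node = subtree.nodes[nid]
        if node.is_leaf:
            s0[nid] = u0[nid]
            cost_sel = u1[nid]
            cost_not = u0[nid]
        else:
            s0[nid] = u0[nid] + s0[node.left] + s0[node.right]
            cost_sel = u1[nid] + s0[nid] - u0[nid]
            cost_not = u0[nid] + best[node.left] + best[node.right]
        take[nid] = cost_sel < cost_not
        best[nid] = min(cost_sel, cost_not)
    sel = set()
    stack = [subtree.root]
    while stack:
        nid = stack.pop()
        if take[nid]:
            sel.add(nid)
        else:
            node = subtree.nodes[nid]
            if not node.is_leaf:
                stack.extend([node.left, node.right])
    return frozenset(sel)


def _local_search(subtree: RegionTree, model: EnergyModel, start: frozenset):
    """Steepest-descent over single-node moves; strict decreases only."""
    cur = frozenset(start)
    cur_e = energy(Labeling(selected=cur), subtree, model)
    node_ids = sorted(subtree.nodes)
    anc = {n: set(subtree.ancestors(n)) for n in node_ids}
    for _ in range(1000):
        best = None  # (energy, selection)
        for nid in node_ids:
            node = subtree.nodes[nid]
            candidates = []
            if nid in cur:
                candidates.append(cur - {nid})  # flip off
                if not node.is_leaf:  # demote to children
                    candidates.append((cur - {nid}) | {node.left, node.right})
                parent = subtree.parent(nid)
                if parent is not None:  # promote: parent replaces its subtree
                    below = {s for s in cur if s == parent or parent in anc[s]}
                    candidates.append((cur - below) | {parent})
            else:
                # force on: evict any selected ancestor or descendant
                conflicts = (anc[nid] & cur) | {s for s in cur if nid in anc[s]}
                candidates.append((cur - conflicts) | {nid})
            for cand in candidates:
                lab = Labeling(selected=frozenset(cand))
                e = energy(lab, subtree, model)
                if e < cur_e - 1e-12 and (best is None or e < best[0] - 1e-15):
                    best = (e, lab.selected)
        if best is None:
            break
        cur_e, cur = best
    return cur, cur_e


def infer_fast(subtree: RegionTree, model: EnergyModel) -> Labeling:
    """Scalable surrogate minimizer for large subtrees.

    Stage 1 solves the unary-only problem exactly by dynamic programming
    on the tree (hence equals :func:`infer_exact` when mu = 0); stage 2
    runs a steepest-descent local search over single-node moves (flip
    on/off with conflict eviction, demote to children, promote to parent)
    from three starts — the DP solution, the empty labeling and the
    all-leaves labeling — and keeps the lowest-energy result, so the
    returned energy never exceeds the stage-1 energy.
    """
    dp_sel = _dp_unary(subtree, model)
    starts = [dp_sel, frozenset(), frozenset(subtree.leaf_ids)]
    best_sel, best_e = None, None
    for start in starts:
        sel, e = _local_search(subtree, model, start)
        if best_e is None or e < best_e - 1e-12:
            best_sel, best_e = sel, e
    return Labeling(selected=best_sel)


# ---------------------------------------------------------------------------
# final segment extraction


def select_segments(
    forest: List[RegionTree],
    labelings: List[Labeling],
    region_map: RegionMap,
    scores: Optional[Dict[int, float]] = None,
    score_threshold: Optional[float] = None,
):
    """Paint each selected node's pixel set as one output cell.

    Cells are pairwise disjoint (guaranteed by the antichain constraint
    within subtrees and disjoint leaf sets across subtrees).  Boundary
    pixels strictly between merged base regions of the same cell are
    filled in.  When ``score_threshold`` is given, selected nodes scoring
    below it are dropped (the precision/recall operating point).

    Returns ``(label_raster, cells)`` where ``cells`` is a list of dicts
    with the output id, node id, score and area of each cell.
    """
    labels = region_map.labels
    out = np.zeros_like(labels, dtype=np.int32)
    cells = []
    cid = 0
    for subtree, labeling in zip(forest, labelings):
        for nid in sorted(labeling.selected):
            s = None if scores is None else scores.get(nid)
            if (
                score_threshold is not None
                and s is not None
                and s < score_threshold
            ):
                continue
            leaf_labels = sorted(
                subtree.nodes[l].region_label for l in subtree.leaves_under(nid)
            )
            mask = np.isin(labels, leaf_labels)
            mask |= _internal_boundary_fill(labels, mask)
            cid += 1
            out[mask & (out == 0)] = cid
            cells.append(
                {
                    "id": cid,
                    "node": int(nid),
                    "score": None if s is None else float(s),
                    "area": int(mask.sum()),
                }
            )
    return out, cells


def _internal_boundary_fill(labels: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """0-pixels with >= 2 in-mask 4-neighbors and no out-of-mask region neighbor."""
    zero = labels == 0
    in_cnt = np.zeros(labels.shape, dtype=np.int8)
    out_any = np.zeros(labels.shape, dtype=bool)
    other = (labels > 0) & ~mask
    for shift in ((1, 0), (-1, 0), (0, 1), (0, -1)):
        in_cnt += _shift(mask, shift).astype(np.int8)
        out_any |= _shift(other, shift)
    return zero & (in_cnt >= 2) & ~out_any


def _shift(a: np.ndarray, delta) -> np.ndarray:
    dy, dx = delta
    out = np.zeros_like(a)
    src_y = slice(max(0, -dy), a.shape[0] - max(0, dy))
    src_x = slice(max(0, -dx), a.shape[1] - max(0, dx))
    dst_y = slice(max(0, dy), a.shape[0] - max(0, -dy))
    dst_x = slice(max(0, dx), a.shape[1] - max(0, -dx))
    out[dst_y, dst_x] = a[src_y, src_x]
    return out
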