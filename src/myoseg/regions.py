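"""Region candidate generation from contour probability maps.

A watershed transform of the (optionally smoothed) contour map yields an
over-segmented region map whose watershed lines are 0-labeled boundary
pixels: every region is 4-connected, enclosed by boundary pixels or the
image border, and the boundary skeleton is single-pixel wide.  The shared
boundary between adjacent regions carries the two statistics used by the
region-selection energy: its mean contour strength B and its length L.
Greedy merging of the weakest boundaries below a threshold produces the
coarser, nested partitions of an ultrametric contour hierarchy.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

FOUR_CONN = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)

# lower-completion step per plateau BFS level; small enough never to override
# a genuine value difference of the contour votes, large enough for float64
_PLATEAU_DELTA = 1e-10


@dataclass(frozen=True)
class ContourMap:
    """Per-pixel contour probability in [0, 1]."""

    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2:
            raise ValueError("contour map must be 2-D")
        if not np.all(np.isfinite(v)):
            raise ValueError("contour map must be finite")
        if v.min() < -1e-9 or v.max() > 1 + 1e-9:
            raise ValueError("contour values must lie in [0, 1]")
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class RegionMap:
    """Integer raster: 0 = boundary pixels, 1..n_regions = base regions."""

    labels: np.ndarray
    n_regions: int


@dataclass(frozen=True)
class RegionAdjacency:
    """Edges (i, j, B, L) with i < j: boundary strength and length."""

    edges: tuple


# ---------------------------------------------------------------------------
# invariant checking


def check_region_map(rm: RegionMap, raise_on_fail: bool = True) -> bool:
    """Verify closedness, label completeness and single-pixel-wide boundaries."""
    labels = rm.labels

    def fail(msg):
        if raise_on_fail:
            raise ValueError(f"invalid region map: {msg}")
        return False

    present = np.unique(labels)
    expected = np.arange(0, rm.n_regions + 1)
    nonzero = present[present > 0]
    if not np.array_equal(nonzero, expected[1:]):
        return fail("labels must be exactly 1..n_regions")
    comp, n_comp = ndimage.label(labels > 0, structure=FOUR_CONN)
    if n_comp != rm.n_regions:
        return fail(
            f"{n_comp} connected components for {rm.n_regions} regions "
            "(regions disconnected or not separated)"
        )
    # bijection components <-> labels
    mask = labels > 0
    pairs = np.unique(
        comp[mask].astype(np.int64) * (int(labels.max()) + 1) + labels[mask]
    )
    if pairs.size != n_comp:
        return fail("a region spans multiple components")
    z = labels == 0
    if np.any(z[:-1, :-1] & z[1:, :-1] & z[:-1, 1:] & z[1:, 1:]):
        return fail("boundary is not single-pixel wide (2x2 zero block)")
    return True


# ---------------------------------------------------------------------------
# boundary-pixel bookkeeping


def _neighbor_columns(labels: np.ndarray, pts: np.ndarray) -> np.ndarray:
    """4-neighbor labels of the given pixel coordinates (0 outside image)."""
    h, w = labels.shape
    out = np.zeros((pts.shape[0], 4), dtype=labels.dtype)
    r, c = pts[:, 0], pts[:, 1]
    m = r > 0
    out[m, 0] = labels[r[m] - 1, c[m]]
    m = r < h - 1
    out[m, 1] = labels[r[m] + 1, c[m]]
    m = c > 0
    out[m, 2] = labels[r[m], c[m] - 1]
    m = c < w - 1
    out[m, 3] = labels[r[m], c[m] + 1]
    return out


def _absorb_redundant_zeros(labels: np.ndarray) -> None:
    """Assign 0-pixels with exactly one distinct nonzero 4-neighbor label.

    Removes junction clumps, dangling boundary spurs and walls left behind
    by region merging while never joining two distinct regions.  Pixels
    are processed in raster order against the updated array, so two zero
    pixels separating different regions are never absorbed simultaneously.
    """
    h, w = labels.shape
    while True:
        pts = np.argwhere(labels == 0)
        if pts.size == 0:
            return
        changed = 0
        for r, c in pts:
            uniq = 0
            ok = True
            for rr, cc in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)):
                if 0 <= rr < h and 0 <= cc < w:
                    v = labels[rr, cc]
                    if v > 0:
                        if uniq == 0:
                            uniq = v
                        elif v != uniq:
                            ok = False
                            break
            if ok and uniq > 0:
                labels[r, c] = uniq
                changed += 1
        if changed == 0:
            return


def _neighbor_stack(v: np.ndarray, fill) -> np.ndarray:
    """4 x H x W stack of 4-neighbor values (up, down, left, right)."""
    out = np.full((4,) + v.shape, fill, dtype=v.dtype)
    out[0, 1:, :] = v[:-1, :]
    out[1, :-1, :] = v[1:, :]
    out[2, :, 1:] = v[:, :-1]
    out[3, :, :-1] = v[:, 1:]
    return out


def _lower_complete(v: np.ndarray) -> np.ndarray:
    """Raise plateau pixels by a tiny amount per BFS step from a descent exit.

    After completion every pixel outside a true (regional) minimum has a
    strictly lower 4-neighbor, so steepest descent is well defined.  The
    transform is local: it depends only on each plateau's shape.
    """
    nb = _neighbor_stack(v, np.inf)
    has_equal = (nb == v[None]).any(axis=0)
    has_lower = (nb < v[None]).any(axis=0)
    plateau = has_equal
    dist = np.zeros(v.shape, dtype=np.int64)
    frontier = plateau & has_lower
    visited = frontier.copy()
    level = 0
    while frontier.any():
        level += 1
        grown = np.zeros_like(frontier)
        grown[1:, :] |= frontier[:-1, :] & (v[1:, :] == v[:-1, :])
        grown[:-1, :] |= frontier[1:, :] & (v[:-1, :] == v[1:, :])
        grown[:, 1:] |= frontier[:, :-1] & (v[:, 1:] == v[:, :-1])
        grown[:, :-1] |= frontier[:, 1:] & (v[:, :-1] == v[:, 1:])
        frontier = grown & plateau & ~visited
        dist[frontier] = level
        visited |= frontier
    return v + dist * _PLATEAU_DELTA


def _descent_watershed(v: np.ndarray) -> np.ndarray:
    """Deterministic, crop-invariant watershed with 0-labeled ridge lines.

    Each pixel descends to its lowest 4-neighbor (ties broken by a fixed
    direction order) until it reaches a regional minimum; minima plateaus
    are the markers.  Afterwards, for every 4-adjacent pixel pair from
    different basins the higher pixel (ties: the up/left one) becomes a
    0-labeled line pixel.  Every step is a local rule, so the result on a
    crop matches the full image away from the crop borders.
    """
    h, w = v.shape
    vc = _lower_complete(v)
    nb = _neighbor_stack(vc, np.inf)
    best_dir = nb.argmin(axis=0)  # first minimum wins: fixed tie order
    best_val = np.take_along_axis(nb, best_dir[None], axis=0)[0]
    is_marker = best_val >= vc

    markers, n_markers = ndimage.label(is_marker, structure=FOUR_CONN)
    if n_markers <= 1:
        return np.ones((h, w), dtype=np.int32) * max(n_markers, 1)

    # descent pointers as flat indices, then path-double to the root marker
    idx = np.arange(h * w, dtype=np.int64).reshape(h, w)
    offsets = np.array([-w, w, -1, 1], dtype=np.int64)
    ptr = idx + offsets[best_dir]
    ptr[is_marker] = idx[is_marker]
    ptr = ptr.ravel()
    while True:
        nxt = ptr[ptr]
        if np.array_equal(nxt, ptr):
            break
        ptr = nxt
    labels = markers.ravel()[ptr].reshape(h, w).astype(np.int32)

    # carve single-pixel ridge lines between basins (zero the higher pixel;
    # exact ties zero the up/left pixel of the pair)
    zero = np.zeros((h, w), dtype=bool)
    du = labels[:-1, :] != labels[1:, :]
    upper_wins = vc[:-1, :] >= vc[1:, :]
    zero[:-1, :] |= du & upper_wins
    zero[1:, :] |= du & ~upper_wins
    dl = labels[:, :-1] != labels[:, 1:]
    left_wins = vc[:, :-1] >= vc[:, 1:]
    zero[:, :-1] |= dl & left_wins
    zero[:, 1:] |= dl & ~left_wins
    labels[zero] = 0
    return labels


def _is_simple_pixel(labels: np.ndarray, r: int, c: int) -> bool:
    """True when zeroing (r, c) cannot disconnect its region locally.

    The region's pixels in the 3x3 neighborhood (center excluded) must form
    a single 4-connected component within the window; conservative but safe.
    """
    h, w = labels.shape
    v = labels[r, c]
    win = np.zeros((3, 3), dtype=bool)
    for dy in (-1, 0, 1):
        for dx in (-1, 0, 1):
            if dy == 0 and dx == 0:
                continue
            rr, cc = r + dy, c + dx
            if 0 <= rr < h and 0 <= cc < w and labels[rr, cc] == v:
                win[dy + 1, dx + 1] = True
    if not win.any():
        return False  # single-pixel region: never shave away
    _, n = ndimage.label(win, structure=FOUR_CONN)
    return n == 1


def _resolve_zero_blocks(labels: np.ndarray, max_iter: int = 100) -> None:
    """Break up residual 2x2 zero blocks at multi-region junctions.

    Watershed lines can meet in a pinwheel whose junction is a 2x2 zero
    block with every pixel adjacent to two distinct regions.  The repair
    shaves one adjacent region pixel (only where that provably keeps the
    region connected), which frees a block pixel for absorption, then
    re-runs the absorption pass.
    """
    h, w = labels.shape

    def distinct_neighbors(r, c):
        vals = set()
        for rr, cc in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)):
            if 0 <= rr < h and 0 <= cc < w and labels[rr, cc] > 0:
                vals.add(int(labels[rr, cc]))
        return vals

    for _ in range(max_iter):
        z = labels == 0
        blocks = np.argwhere(
            z[:-1, :-1] & z[1:, :-1] & z[:-1, 1:] & z[1:, 1:]
        )
        if blocks.size == 0:
            return
        repaired = False
        for br, bc in blocks:
            for pr, pc in ((br, bc), (br, bc + 1), (br + 1, bc), (br + 1, bc + 1)):
                if labels[pr, pc] != 0 or repaired:
                    continue
                for qr, qc in ((pr - 1, pc), (pr + 1, pc), (pr, pc - 1), (pr, pc + 1)):
                    if not (0 <= qr < h and 0 <= qc < w) or labels[qr, qc] <= 0:
                        continue
                    if not _is_simple_pixel(labels, qr, qc):
                        continue
                    saved = labels[qr, qc]
                    labels[qr, qc] = 0
                    remaining = distinct_neighbors(pr, pc)
                    if len(remaining) == 1:
                        labels[pr, pc] = remaining.pop()
                        repaired = True
                        break
                    labels[qr, qc] = saved
            if repaired:
                break
        if not repaired:
            return  # give up; the invariant check reports any residue
        _absorb_redundant_zeros(labels)


def _relabel_components(labels: np.ndarray) -> RegionMap:
    """Region map whose regions are the 4-connected components of labels > 0.

    Guarantees the connectivity and closedness invariants: distinct
    components are never 4-adjacent, and a basin pinched to diagonal
    connectivity becomes two candidate regions.
    """
    comp, n = ndimage.label(labels > 0, structure=FOUR_CONN)
    return RegionMap(labels=comp.astype(np.int32), n_regions=int(n))


# ---------------------------------------------------------------------------
# adjacency


def build_adjacency(regions: RegionMap, contour: ContourMap) -> RegionAdjacency:
    """Shared-boundary statistics of every adjacent region pair.

    Each 0-pixel contributes once to every unordered pair of distinct
    region labels in its 4-neighborhood; L counts those pixels and B is
    the mean contour value over them.
    """
    labels = regions.labels
    if labels.shape != contour.values.shape:
        raise ValueError("region map and contour map shapes differ")
    check_region_map(regions)
    pts = np.argwhere(labels == 0)
    if pts.size == 0:
        return RegionAdjacency(edges=())
    nb = _neighbor_columns(labels, pts).astype(np.int64)
    nb.sort(axis=1)
    # zero out duplicates so each distinct label appears once per pixel
    for col in range(1, 4):
        dup = nb[:, col] == nb[:, col - 1]
        nb[dup, col - 1] = 0
    vals = contour.values[pts[:, 0], pts[:, 1]]
    nmax = int(labels.max()) + 1
    keys_all = []
    w_all = []
    for a in range(4):
        for b in range(a + 1, 4):
            i, j = nb[:, a], nb[:, b]
            m = (i > 0) & (j > 0)
            if not m.any():
                continue
            keys_all.append(i[m] * nmax + j[m])
            w_all.append(vals[m])
    if not keys_all:
        return RegionAdjacency(edges=())
    keys = np.concatenate(keys_all)
    w = np.concatenate(w_all)
    uk, inv = np.unique(keys, return_inverse=True)
    L = np.bincount(inv)
    Bsum = np.bincount(inv, weights=w)
    edges = tuple(
        (int(k // nmax), int(k % nmax), float(bs / l), int(l))
        for k, bs, l in zip(uk, Bsum, L)
    )
    return RegionAdjacency(edges=edges)


# ---------------------------------------------------------------------------
# watershed over-segmentation


def oversegment(
    contour: ContourMap,
    smoothing_sigma: float = 1.0,
    min_region_area: int = 30,
) -> RegionMap:
    """Watershed the contour map into an over-segmented region candidate map.

    The map is optionally Gaussian-smoothed to suppress noise minima;
    watershed lines become the 0-labeled boundary pixels.  Regions smaller
    than ``min_region_area`` are merged into the neighbor with the weakest
    shared boundary (smallest mean contour value on the original map).
    """
    vals = contour.values
    sm = ndimage.gaussian_filter(vals, smoothing_sigma) if smoothing_sigma > 0 else vals
    labels = _descent_watershed(sm)
    _absorb_redundant_zeros(labels)
    _resolve_zero_blocks(labels)
    rm = _relabel_components(labels)
    # merge to a fixpoint: absorbing walls can pinch a merged union into
    # components, re-creating sub-minimum fragments; fragments that cannot
    # merge (pinched between regions that must stay separated) dissolve
    # into the boundary
    for _ in range(50):
        if rm.n_regions <= 1 or min_region_area <= 0:
            break
        areas = np.bincount(rm.labels.ravel())[1:]
        if areas.min() >= min_region_area:
            break
        merged = _merge_small_regions(rm, contour, min_region_area)
        if merged.n_regions < rm.n_regions:
            rm = merged
            continue
        small_ids = np.nonzero(areas < min_region_area)[0] + 1
        lbl = rm.labels.copy()
        lbl[np.isin(lbl, small_ids)] = 0
        _absorb_redundant_zeros(lbl)
        _resolve_zero_blocks(lbl)
        nxt = _relabel_components(lbl)
        if np.array_equal(nxt.labels, rm.labels):
            break
        rm = nxt
    return rm


def _edge_dicts(adjacency: RegionAdjacency):
    edges = {}
    nbrs = {}
    for i, j, b, l in adjacency.edges:
        edges[(i, j)] = (float(b), int(l))
        nbrs.setdefault(i, set()).add(j)
        nbrs.setdefault(j, set()).add(i)
    return edges, nbrs


def _merge_edge_maps(edges, nbrs, keep, drop):
    """Merge cluster ``drop`` into ``keep``, combining edges length-weighted."""
    for k in list(nbrs.get(drop, ())):
        if k == keep:
            continue
        key_old = (min(drop, k), max(drop, k))
        b2, l2 = edges.pop(key_old)
        nbrs[k].discard(drop)
        key_new = (min(keep, k), max(keep, k))
        if key_new in edges:
            b1, l1 = edges[key_new]
            edges[key_new] = ((b1 * l1 + b2 * l2) / (l1 + l2), l1 + l2)
        else:
            edges[key_new] = (b2, l2)
        nbrs[k].add(keep)
        nbrs.setdefault(keep, set()).add(k)
    edges.pop((min(keep, drop), max(keep, drop)), None)
    nbrs.get(keep, set()).discard(drop)
    nbrs.pop(drop, None)


def _merge_small_regions(
    rm: RegionMap, contour: ContourMap, min_area: int
) -> RegionMap:
    adjacency = build_adjacency(rm, contour)
    edges, nbrs = _edge_dicts(adjacency)
    areas = np.bincount(rm.labels.ravel(), minlength=rm.n_regions + 1).astype(
        np.int64
    )
    parent = {}

    def find(x):
        while x in parent:
            x = parent[x]
        return x

    while True:
        roots = sorted(set(find(r) for r in range(1, rm.n_regions + 1)))
        small = [
            (areas[r], r) for r in roots if areas[r] < min_area and nbrs.get(r)
        ]
        if not small:
            break
        _, r = min(small)
        cand = sorted((edges[(min(r, k), max(r, k))][0], k) for k in nbrs[r])
        _, k = cand[0]
        keep, drop = (r, k) if r < k else (k, r)
        parent[drop] = keep
        areas[keep] += areas[drop]
        _merge_edge_maps(edges, nbrs, keep, drop)

    if not parent:
        return rm
    lut = np.arange(rm.n_regions + 1, dtype=np.int32)
    for r in range(1, rm.n_regions + 1):
        lut[r] = find(r)
    labels = lut[rm.labels]
    _absorb_redundant_zeros(labels)
    return _relabel_components(labels)


# ---------------------------------------------------------------------------
# greedy boundary-strength merging (UCM thresholding)


def merge_sequence(adjacency: RegionAdjacency, stop_b: float):
    """Greedy sequence of merges with current boundary strength < ``stop_b``.

    Pops the globally weakest edge first (ties by smallest label pair);
    merged edges get the length-weighted mean strength of their parts.
    Cluster representatives are the smallest member labels.  Returns the
    list of merges ``(rep_kept, rep_dropped, B)`` in order.
    """
    edges, nbrs = _edge_dicts(adjacency)
    heap = [(b, i, j) for (i, j), (b, _) in edges.items()]
    heapq.heapify(heap)
    merges = []
    while heap:
        b, i, j = heapq.heappop(heap)
        cur = edges.get((i, j))
        if cur is None or abs(cur[0] - b) > 1e-12:
            continue  # stale entry
        if b >= stop_b:
            break
        keep, drop = (i, j) if i < j else (j, i)
        merges.append((keep, drop, b))
        _merge_edge_maps(edges, nbrs, keep, drop)
        for k in nbrs.get(keep, ()):
            key = (min(keep, k), max(keep, k))
            heapq.heappush(heap, (edges[key][0], key[0], key[1]))
    return merges


def threshold_merge(
    regions: RegionMap, adjacency: RegionAdjacency, ucm_threshold: float
) -> RegionMap:
    """Merge adjacent regions while the weakest boundary is below threshold.

    Output partitions are nested across thresholds: the same greedy merge
    sequence is simply stopped earlier for lower thresholds.
    """
    if not 0.0 <= ucm_threshold <= 1.0 + 1e-9:
        raise ValueError("ucm_threshold must be in [0, 1]")
    merges = merge_sequence(adjacency, ucm_threshold)
    if not merges:
        return RegionMap(labels=regions.labels.copy(), n_regions=regions.n_regions)
    lut = np.arange(regions.n_regions + 1, dtype=np.int32)
    for keep, drop, _ in merges:
        lut[lut == lut[drop]] = lut[keep]
    labels = lut[regions.labels]
    _absorb_redundant_zeros(labels)
    return _relabel_components(labels)
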