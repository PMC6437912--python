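"""Region tree, features, scoring, CRF energy and inference."""

import itertools
import math

import numpy as np
import pytest
from skimage import morphology

from myoseg.hierarchy import (
    EnergyModel,
    Labeling,
    Node,
    RegionTree,
    SubtreeTooLarge,
    build_tree,
    cut_tree,
    energy,
    infer_exact,
    infer_fast,
    is_antichain,
    region_features,
    select_segments,
    train_region_scorer,
)
from myoseg.regions import ContourMap, RegionAdjacency, RegionMap, build_adjacency


def _strip_map(n, wall_bs):
    """n vertical strip regions with given wall strengths (len n-1)."""
    width = 4 * n - 1
    labels = np.zeros((6, width), dtype=np.int32)
    v = np.zeros((6, width))
    for i in range(n):
        labels[:, 4 * i : 4 * i + 3] = i + 1
    for i, b in enumerate(wall_bs):
        v[:, 4 * i + 3] = b
    rm = RegionMap(labels=labels, n_regions=n)
    adj = build_adjacency(rm, ContourMap(values=v))
    return rm, adj


# ---------------------------------------------------------------------------
# tree construction


class TestBuildTree:
    def test_single_region_tree(self):
        rm, adj = _strip_map(1, [])
        tree = build_tree(rm, adj)
        assert tree.n_nodes == 1 and tree.n_leaves == 1

    def test_two_n_minus_one_nodes(self):
        rm, adj = _strip_map(4, [0.2, 0.5, 0.8])
        tree = build_tree(rm, adj)
        assert tree.n_nodes == 7
        assert tree.n_leaves == 4

    def test_weakest_boundary_merges_first(self):
        rm, adj = _strip_map(3, [0.1, 0.9])
        tree = build_tree(rm, adj)
        first_internal = tree.nodes[4]
        assert {first_internal.left, first_internal.right} == {1, 2}

    def test_disconnected_adjacency_joined(self):
        rm, _ = _strip_map(3, [0.5, 0.5])
        adj = RegionAdjacency(edges=())  # no adjacency information at all
        tree = build_tree(rm, adj)
        assert tree.n_nodes == 5
        assert {tree.nodes[l].region_label for l in tree.leaves_under(tree.root)} == {
            1,
            2,
            3,
        }


class TestCutTree:
    def test_threshold_one_single_tree(self):
        rm, adj = _strip_map(4, [0.2, 0.8, 0.3])
        tree = build_tree(rm, adj)
        forest = cut_tree(tree, adj, 1.0)
        assert len(forest) == 1
        assert forest[0].n_leaves == 4

    def test_threshold_zero_all_singletons(self):
        rm, adj = _strip_map(4, [0.2, 0.8, 0.3])
        tree = build_tree(rm, adj)
        forest = cut_tree(tree, adj, 0.0)
        assert len(forest) == 4
        assert all(t.n_leaves == 1 for t in forest)

    def test_cut_at_strong_edge(self):
        rm, adj = _strip_map(4, [0.2, 0.8, 0.3])
        tree = build_tree(rm, adj)
        forest = cut_tree(tree, adj, 0.5)
        assert len(forest) == 2
        leaf_sets = sorted(
            sorted(t.nodes[l].region_label for l in t.leaves_under(t.root))
            for t in forest
        )
        assert leaf_sets == [[1, 2], [3, 4]]

    def test_leaf_sets_partition(self):
        rm, adj = _strip_map(6, [0.1, 0.6, 0.2, 0.9, 0.4])
        tree = build_tree(rm, adj)
        forest = cut_tree(tree, adj, 0.5)
        all_leaves = sorted(
            tree.nodes[l].region_label
            for t in forest
            for l in t.leaves_under(t.root)
        )
        assert all_leaves == [1, 2, 3, 4, 5, 6]


# ---------------------------------------------------------------------------
# region features


class TestRegionFeatures:
    def test_disk_circularity(self):
        mask = morphology.disk(20).astype(bool)
        lab = np.zeros(mask.shape + (3,))
        feats = region_features(mask, lab, np.zeros(mask.shape))
        circ = feats[2]
        assert 0.85 <= circ <= 1.0

    def test_uniform_image_zero_std(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[5:15, 5:15] = True
        lab = np.full((20, 20, 3), 7.0)
        feats = region_features(mask, lab, np.zeros((20, 20)))
        assert np.allclose(feats[8:11], 0.0)  # std_L, std_a, std_b
        assert np.allclose(feats[5:8], 7.0)

    def test_five_by_five_square_hand_counts(self):
        mask = np.zeros((9, 9), dtype=bool)
        mask[2:7, 2:7] = True
        contour = np.zeros((9, 9))
        contour[1, 2:7] = 1.0  # part of the ring
        feats = region_features(mask, np.zeros((9, 9, 3)), contour)
        assert feats[0] == 25.0  # area
        assert feats[1] == 16.0  # perimeter estimator on an axis-aligned square
        ring_size = 7 * 7 - 25  # one-pixel ring with corners (8-dilation)
        assert feats[11] == pytest.approx(5 / ring_size)
        assert feats[12] == 0.0

    def test_empty_region_rejected(self):
        with pytest.raises(ValueError):
            region_features(np.zeros((5, 5), bool), np.zeros((5, 5, 3)), np.zeros((5, 5)))


# ---------------------------------------------------------------------------
# scorer


class TestRegionScorer:
    def test_single_class_rejected(self):
        X = np.random.default_rng(0).normal(size=(10, 14))
        with pytest.raises(ValueError):
            train_region_scorer(X, np.ones(10))

    def test_conflicting_duplicates_score_strictly_between(self):
        X = np.tile(np.ones((1, 14)), (20, 1))
        y = np.array([0, 1] * 10)
        scorer = train_region_scorer(X, y, seed=0)
        s = scorer.score(X[:1])[0]
        assert 0.0 < s < 1.0

    def test_overfit_scorer_rates_training_positive(self):
        rng = np.random.default_rng(1)
        X = np.concatenate([rng.normal(0, 1, (20, 14)), rng.normal(5, 1, (20, 14))])
        y = np.array([0] * 20 + [1] * 20)
        scorer = train_region_scorer(X, y, seed=0)
        assert scorer.score(X[25:26])[0] >= 0.5

    def test_fixed_seed_identical_scores(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(30, 14))
        y = rng.integers(0, 2, size=30)
        y[:2] = [0, 1]
        s1 = train_region_scorer(X, y, seed=3).score(X)
        s2 = train_region_scorer(X, y, seed=3).score(X)
        assert np.array_equal(s1, s2)


# ---------------------------------------------------------------------------
# energy


def _chain_tree_3():
    """3 leaves merged ((1,2),3); node ids: leaves 1..3, internals 4, 5."""
    nodes = {
        1: Node(id=1, region_label=1),
        2: Node(id=2, region_label=2),
        3: Node(id=3, region_label=3),
        4: Node(id=4, left=1, right=2),
        5: Node(id=5, left=3, right=4),
    }
    return RegionTree(nodes=nodes, root=5)


class TestEnergy:
    def test_symmetric_scores_constant_energy(self):
        tree = _chain_tree_3()
        eps = 1e-6
        model = EnergyModel(scores={n: 0.5 for n in tree.nodes}, pairwise=[], mu=0.0,
                            epsilon=eps)
        expected = 5 * (-math.log(0.5 + eps))
        for sel in [frozenset(), frozenset([1]), frozenset([5]), frozenset([1, 2, 3])]:
            assert energy(Labeling(selected=sel), tree, model) == pytest.approx(expected)

    def test_pairwise_closed_forms(self):
        tree = _chain_tree_3()
        scores = {n: 0.5 for n in tree.nodes}
        # V(B=0, L=10, mu=1) = 10 when the labels differ
        model = EnergyModel(scores=scores, pairwise=[(1, 2, 0.0, 10)], mu=1.0)
        base = energy(Labeling(selected=frozenset()), tree, model)
        e_sel = energy(Labeling(selected=frozenset([1])), tree, model)
        du = -math.log(0.5 + 1e-6) - (-math.log(0.5 + 1e-6))
        assert e_sel - base == pytest.approx(10.0 + du)
        # V(B=ln 2, L=3, mu=2) = 2 * (1/2) * 3 = 3
        model2 = EnergyModel(scores=scores, pairwise=[(1, 2, math.log(2), 3)], mu=2.0)
        e2 = energy(Labeling(selected=frozenset([1])), tree, model2)
        base2 = energy(Labeling(selected=frozenset()), tree, model2)
        assert e2 - base2 == pytest.approx(3.0)

    def test_antichain_violation_rejected(self):
        tree = _chain_tree_3()
        model = EnergyModel(scores={n: 0.5 for n in tree.nodes}, pairwise=[])
        with pytest.raises(ValueError, match="antichain"):
            energy(Labeling(selected=frozenset([4, 1])), tree, model)

    def test_background_pairs_do_not_pay(self):
        tree = _chain_tree_3()
        model = EnergyModel(
            scores={n: 0.5 for n in tree.nodes}, pairwise=[(2, 3, 0.0, 100)], mu=1.0
        )
        e_empty = energy(Labeling(selected=frozenset()), tree, model)
        # both leaves background: no pairwise term
        assert e_empty == pytest.approx(5 * (-math.log(0.5 + 1e-6)))


# ---------------------------------------------------------------------------
# inference oracles


def oracle_min_energy(tree, model):
    """Independent brute force: all subsets filtered by the antichain test."""
    node_ids = sorted(tree.nodes)
    eps = model.epsilon
    anc = {n: set(tree.ancestors(n)) for n in node_ids}

    def leaves(n):
        out = []
        stack = [n]
        while stack:
            x = stack.pop()
            nd = tree.nodes[x]
            if nd.is_leaf:
                out.append(x)
            else:
                stack.extend([nd.left, nd.right])
        return out

    best = None
    for r in range(len(node_ids) + 1):
        for sel in itertools.combinations(node_ids, r):
            s = set(sel)
            if any(anc[n] & s for n in s):
                continue
            e = 0.0
            for n in node_ids:
                p = model.scores[n]
                e += -math.log(p + eps) if n in s else -math.log(1 - p + eps)
            owner = {}
            for n in s:
                for leaf in leaves(n):
                    owner[leaf] = n
            for i, j, b, l in model.pairwise:
                if owner.get(i) != owner.get(j):
                    e += model.mu * math.exp(-b) * l
            key = tuple(sorted(s))
            if best is None or e < best[0] - 1e-15 or (
                abs(e - best[0]) <= 1e-15 and key < best[1]
            ):
                best = (e, key)
    return best


class TestInferExact:
    def test_single_leaf_selects_high_score(self):
        tree = RegionTree(nodes={1: Node(id=1, region_label=1)}, root=1)
        model = EnergyModel(scores={1: 0.9}, pairwise=[], mu=0.0)
        lab = infer_exact(tree, model)
        assert lab.selected == frozenset([1])

    def test_three_leaf_matches_bruteforce(self, random_tree_factory):
        rng = np.random.default_rng(0)
        for _ in range(20):
            tree, scores, pairwise = random_tree_factory(rng, 3)
            model = EnergyModel(scores=scores, pairwise=pairwise, mu=0.0)
            lab = infer_exact(tree, model)
            e = energy(lab, tree, model)
            oe, osel = oracle_min_energy(tree, model)
            assert e == pytest.approx(oe, abs=1e-10)
            assert tuple(sorted(lab.selected)) == osel

    def test_sibling_leaves_beat_weak_parent(self):
        nodes = {
            1: Node(id=1, region_label=1),
            2: Node(id=2, region_label=2),
            3: Node(id=3, left=1, right=2),
        }
        tree = RegionTree(nodes=nodes, root=3)
        model = EnergyModel(scores={1: 0.9, 2: 0.9, 3: 0.1}, pairwise=[], mu=0.0)
        lab = infer_exact(tree, model)
        assert lab.selected == frozenset([1, 2])

    def test_leaf_budget_enforced(self, random_tree_factory):
        rng = np.random.default_rng(1)
        tree, scores, pairwise = random_tree_factory(rng, 12)
        model = EnergyModel(scores=scores, pairwise=pairwise)
        with pytest.raises(SubtreeTooLarge):
            infer_exact(tree, model, max_leaves=10)

    def test_monotone_in_single_score(self, random_tree_factory):
        """Raising s_i (mu = 0) never removes node i from the solution."""
        rng = np.random.default_rng(2)
        for _ in range(10):
            tree, scores, _ = random_tree_factory(rng, 5)
            model = EnergyModel(scores=scores, pairwise=[], mu=0.0)
            sel = infer_exact(tree, model).selected
            for nid in sel:
                boosted = dict(scores)
                boosted[nid] = min(1.0, boosted[nid] + 0.3)
                lab2 = infer_exact(tree, EnergyModel(scores=boosted, pairwise=[], mu=0.0))
                assert nid in lab2.selected


class TestInferFast:
    def test_unary_only_matches_exact(self, random_tree_factory):
        rng = np.random.default_rng(3)
        for _ in range(20):
            tree, scores, pairwise = random_tree_factory(rng, 8)
            model = EnergyModel(scores=scores, pairwise=pairwise, mu=0.0)
            e_fast = energy(infer_fast(tree, model), tree, model)
            e_exact = energy(infer_exact(tree, model), tree, model)
            assert e_fast == pytest.approx(e_exact, rel=1e-12)

    def test_antichain_always_satisfied(self, random_tree_factory):
        rng = np.random.default_rng(4)
        for _ in range(20):
            tree, scores, pairwise = random_tree_factory(rng, 15)
            model = EnergyModel(scores=scores, pairwise=pairwise, mu=0.5)
            lab = infer_fast(tree, model)
            assert is_antichain(tree, lab.selected)

    @pytest.mark.timeout(300)
    def test_close_to_exact_with_pairwise(self, random_tree_factory):
        """Local search lands within 5% of the exact energy (100 trials)."""
        rng = np.random.default_rng(5)
        for _ in range(100):
            tree, scores, pairwise = random_tree_factory(rng, 10)
            mu = float(rng.choice([0.05, 0.2, 1.0]))
            model = EnergyModel(scores=scores, pairwise=pairwise, mu=mu)
            e_fast = energy(infer_fast(tree, model), tree, model)
            e_exact = energy(infer_exact(tree, model), tree, model)
            assert e_fast <= 1.05 * e_exact + 1e-9


# ---------------------------------------------------------------------------
# final segment extraction


class TestSelectSegments:
    def test_nothing_selected_all_background(self):
        rm, adj = _strip_map(3, [0.5, 0.5])
        tree = build_tree(rm, adj)
        out, cells = select_segments([tree], [Labeling(selected=frozenset())], rm)
        assert not out.any() and cells == []

    def test_root_only_covers_all_regions(self):
        rm, adj = _strip_map(3, [0.5, 0.5])
        tree = build_tree(rm, adj)
        out, cells = select_segments([tree], [Labeling(selected=frozenset([tree.root]))], rm)
        assert len(cells) == 1
        assert np.all(out[rm.labels > 0] == 1)
        # internal walls between merged strips are filled in
        assert np.all(out[:, 3] == 1) and np.all(out[:, 7] == 1)

    def test_score_threshold_filters(self):
        rm, adj = _strip_map(2, [0.5])
        tree = build_tree(rm, adj)
        scores = {1: 0.9, 2: 0.1, 3: 0.5}
        out, cells = select_segments(
            [tree],
            [Labeling(selected=frozenset([1, 2]))],
            rm,
            scores=scores,
            score_threshold=0.26,
        )
        assert len(cells) == 1 and cells[0]["node"] == 1
        assert set(np.unique(out)) == {0, 1}
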