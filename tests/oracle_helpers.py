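"""Independent oracles shared by the unit and acceptance tests.

These deliberately re-derive quantities with their own (naive) code paths:
recursive antichain enumeration plus from-scratch energy evaluation, and a
contingency-based partition-nesting check.
"""

import math

import numpy as np


def oracle_leaves(tree, nid):
    out = []
    stack = [nid]
    while stack:
        x = stack.pop()
        node = tree.nodes[x]
        if node.is_leaf:
            out.append(x)
        else:
            stack.extend([node.left, node.right])
    return out


def oracle_energy(tree, model, selected):
    """From-scratch energy: unary over all nodes + pairwise over leaf owners."""
    eps = model.epsilon
    e = 0.0
    for n in tree.nodes:
        p = model.scores[n]
        e += -math.log(p + eps) if n in selected else -math.log(1 - p + eps)
    owner = {}
    for n in selected:
        for leaf in oracle_leaves(tree, n):
            owner[leaf] = n
    for i, j, b, l in model.pairwise:
        if owner.get(i) != owner.get(j):
            e += model.mu * math.exp(-b) * l
    return e


def oracle_antichains(tree, nid=None):
    """All antichains of the subtree below ``nid`` by direct recursion."""
    if nid is None:
        nid = tree.root
    node = tree.nodes[nid]
    if node.is_leaf:
        return [frozenset(), frozenset([nid])]
    result = [frozenset([nid])]
    for a in oracle_antichains(tree, node.left):
        for b in oracle_antichains(tree, node.right):
            result.append(a | b)
    return result


def oracle_best_labeling(tree, model):
    """Global minimum by enumeration; ties to the smallest selected tuple."""
    best = None
    for sel in oracle_antichains(tree):
        e = oracle_energy(tree, model, sel)
        key = tuple(sorted(sel))
        if best is None or e < best[0] - 1e-15 or (
            abs(e - best[0]) <= 1e-15 and key < best[1]
        ):
            best = (e, key)
    return best


def partitions_nested(fine, coarse) -> bool:
    """Every fine region's pixels fall inside exactly one coarse region."""
    mask = (fine.labels > 0) & (coarse.labels > 0)
    pairs = np.stack([fine.labels[mask], coarse.labels[mask]])
    uniq = np.unique(pairs, axis=1)
    _, counts = np.unique(uniq[0], return_counts=True)
    return bool(np.all(counts == 1))
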