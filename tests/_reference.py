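"""Independent oracle implementations used only by the test suite.

These deliberately avoid the code paths they check: the neighbour-joining
reference is a naive pure-Python O(N^3) loop, the hypergeometric oracle uses
exact rational arithmetic, and tree comparisons go through leaf bipartitions.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np

from hgca.treecluster import CoexpressionTree, TreeNode


def naive_nj(names, dist) -> CoexpressionTree:
    """Textbook Saitou-Nei neighbour joining with explicit Python loops."""
    nodes = [TreeNode(name=n) for n in names]
    d = [[float(v) for v in row] for row in dist]

    if len(nodes) == 2:
        half = d[0][1] / 2.0
        nodes[0].length = half
        nodes[1].length = half
        return CoexpressionTree(TreeNode(children=nodes))

    while len(nodes) > 3:
        size = len(nodes)
        sums = [sum(d[i]) for i in range(size)]
        best = None
        for i in range(size):
            for j in range(i + 1, size):
                q = (size - 2) * d[i][j] - sums[i] - sums[j]
                if best is None or q < best[0]:
                    best = (q, i, j)
        _, i, j = best
        li = 0.5 * d[i][j] + (sums[i] - sums[j]) / (2.0 * (size - 2))
        lj = d[i][j] - li
        if li < 0.0:
            li, lj = 0.0, d[i][j]
        elif lj < 0.0:
            li, lj = d[i][j], 0.0
        nodes[i].length = li
        nodes[j].length = lj
        joined = TreeNode(children=[nodes[i], nodes[j]])
        keep = [k for k in range(size) if k not in (i, j)]
        new_row = [0.5 * (d[i][k] + d[j][k] - d[i][j]) for k in keep]
        d = [[d[a][b] for b in keep] + [new_row[ai]] for ai, a in enumerate(keep)]
        d.append(new_row + [0.0])
        nodes = [nodes[k] for k in keep] + [joined]

    da, db, dc = d[0][1], d[0][2], d[1][2]
    la = max(0.0, 0.5 * (da + db - dc))
    lb = max(0.0, 0.5 * (da + dc - db))
    lc = max(0.0, 0.5 * (db + dc - da))
    nodes[0].length, nodes[1].length, nodes[2].length = la, lb, lc
    return CoexpressionTree(TreeNode(children=nodes))


def edge_bipartitions(tree: CoexpressionTree) -> dict[frozenset, float]:
    """Map every edge's leaf bipartition to its branch length."""
    all_names = frozenset(tree.leaf_names())
    result: dict[frozenset, float] = {}
    for node in tree.root.walk():
        if node is tree.root:
            continue
        below = frozenset(l.name for l in node.leaves())
        key = frozenset({below, all_names - below})
        result[key] = result.get(key, 0.0) + (node.length or 0.0)
    return result


def unrooted_splits(tree: CoexpressionTree) -> set[frozenset]:
    """Non-trivial leaf bipartitions (the unrooted topology signature)."""
    all_names = frozenset(tree.leaf_names())
    splits = set()
    for node in tree.root.walk():
        if node is tree.root:
            continue
        below = frozenset(l.name for l in node.leaves())
        if 1 < len(below) < len(all_names) - 1:
            splits.add(frozenset({below, all_names - below}))
    return splits


def random_distance_matrix(n: int, rng: np.random.Generator) -> np.ndarray:
    """Random symmetric zero-diagonal matrix with distances in (0.1, 2)."""
    a = rng.uniform(0.1, 2.0, size=(n, n))
    d = (a + a.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return d


def random_additive_tree(names, rng: np.random.Generator) -> CoexpressionTree:
    """Random tree with positive branch lengths; its leaf path-length matrix
    is additive, so NJ must recover the topology exactly."""
    nodes = [TreeNode(name=n, length=float(rng.uniform(0.1, 1.0))) for n in names]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        joined = TreeNode(length=float(rng.uniform(0.1, 1.0)), children=[nodes[i], nodes[j]])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [joined]
    return CoexpressionTree(TreeNode(children=nodes))


def mrca_leaf_set(tree: CoexpressionTree, names) -> frozenset:
    """Leaves under the most recent common ancestor of *names*."""
    targets = set(names)
    leaves = [tree.find_leaf(n) for n in targets]
    node = leaves[0]
    while not targets <= {l.name for l in node.leaves()}:
        node = node.parent
    return frozenset(l.name for l in node.leaves())


def hypergeom_upper_exact(n: int, m: int, c: int, k: int) -> Fraction:
    """P(X >= k) by exact rational enumeration of the hypergeometric pmf."""
    total = comb(n, c)
    tail = sum(comb(m, i) * comb(n - m, c - i) for i in range(k, min(c, m) + 1))
    return Fraction(tail, total)
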