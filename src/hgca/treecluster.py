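"""Correlation-distance conversion, neighbour-joining clustering, and
height-adjustable tree neighborhoods.

The distance between two probe sets is ``D = 1 - r``, so perfectly correlated
profiles sit at distance 0 and perfectly anti-correlated ones at distance 2.
The tree is canonical Saitou-Nei neighbour joining: at each step the pair
minimizing ``Q(i, j) = (N - 2) d(i, j) - S_i - S_j`` is joined (``S_i`` the
row sum over active nodes), branch lengths come from the standard two-point
formulas, and the final three nodes are attached to a trifurcating root.
Negative branch-length estimates are clamped to zero with the deficit moved
to the sister edge so the joined pair's path length is preserved.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

from hgca.errors import ProbeLookupError, ValidationError
from hgca.matrix_io import ProbeSetId

logger = logging.getLogger(__name__)


@dataclass
class DistanceMatrix:
    """Symmetric non-negative distances over probe sets, zero diagonal."""

    probe_ids: list[str]
    D: np.ndarray

    def __post_init__(self) -> None:
        self.probe_ids = [str(p) for p in self.probe_ids]
        self.D = np.asarray(self.D, dtype=float)
        m = len(self.probe_ids)
        if len(set(self.probe_ids)) != m:
            raise ValidationError("duplicate leaf names in distance matrix")
        if self.D.shape != (m, m):
            raise ValidationError("D shape does not match probe_ids")
        if m:
            if not np.allclose(self.D, self.D.T, atol=1e-9):
                raise ValidationError("D is not symmetric")
            if not np.allclose(np.diag(self.D), 0.0, atol=1e-9):
                raise ValidationError("D diagonal is not zero")
            if np.any(self.D < -1e-9):
                raise ValidationError("D has negative entries")


class TreeNode:
    """Node of a rooted tree; leaves carry probe-set names, edges lengths."""

    __slots__ = ("name", "length", "children", "parent")

    def __init__(
        self,
        name: str | None = None,
        length: float | None = None,
        children: list["TreeNode"] | None = None,
    ) -> None:
        self.name = name
        self.length = length
        self.children: list[TreeNode] = children or []
        self.parent: TreeNode | None = None
        for child in self.children:
            child.parent = self

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add_child(self, child: "TreeNode") -> None:
        child.parent = self
        self.children.append(child)

    def leaves(self) -> Iterator["TreeNode"]:
        if self.is_leaf:
            yield self
        else:
            for child in self.children:
                yield from child.leaves()

    def walk(self) -> Iterator["TreeNode"]:
        yield self
        for child in self.children:
            yield from child.walk()

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = f"leaf {self.name!r}" if self.is_leaf else f"{len(self.children)} children"
        return f"<TreeNode {kind} length={self.length}>"


@dataclass
class CoexpressionTree:
    """Rooted tree over probe-set leaves with correlation-distance branch
    lengths; the root may be trifurcating (unrooted NJ core)."""

    root: TreeNode

    def __post_init__(self) -> None:
        names = self.leaf_names()
        if len(set(names)) != len(names):
            raise ValidationError("leaf names are not unique")
        for node in self.root.walk():
            if node is not self.root and node.length is not None and node.length < 0:
                raise ValidationError("negative branch length")

    def leaf_names(self) -> list[str]:
        return [leaf.name for leaf in self.root.leaves()]

    def find_leaf(self, name: str) -> TreeNode:
        for leaf in self.root.leaves():
            if leaf.name == name:
                return leaf
        raise ProbeLookupError(name)

    def leaf_distances(self) -> DistanceMatrix:
        """Pairwise leaf path-length matrix (sums of branch lengths)."""
        leaves = list(self.root.leaves())
        index = {id(leaf): i for i, leaf in enumerate(leaves)}
        n = len(leaves)
        d = np.zeros((n, n))

        def below(node: TreeNode) -> list[tuple[int, float]]:
            if node.is_leaf:
                return [(index[id(node)], 0.0)]
            collected: list[tuple[int, float]] = []
            per_child = []
            for child in node.children:
                sub = [(i, dist + (child.length or 0.0)) for i, dist in below(child)]
                per_child.append(sub)
                collected.extend(sub)
            for a in range(len(per_child)):
                for b in range(a + 1, len(per_child)):
                    for i, di in per_child[a]:
                        for j, dj in per_child[b]:
                            d[i, j] = d[j, i] = di + dj
            return collected

        below(self.root)
        return DistanceMatrix([leaf.name for leaf in leaves], d)


@dataclass(frozen=True)
class Neighborhood:
    """Leaves of the clade reached by ascending at most *height* path length
    from the query leaf."""

    query: ProbeSetId
    height: float
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.query not in self.members:
            raise ValidationError("query must be a member of its neighborhood")


def to_distance(cm) -> DistanceMatrix:
    """Elementwise ``D = 1 - R`` with an exactly zero diagonal."""
    D = 1.0 - np.asarray(cm.R, dtype=float)
    np.clip(D, 0.0, None, out=D)
    np.fill_diagonal(D, 0.0)
    return DistanceMatrix(list(cm.probe_ids), D)


def neighbour_joining(distances: DistanceMatrix) -> CoexpressionTree:
    """Canonical neighbour joining over *distances*.

    Fully deterministic: Q-matrix ties are resolved by the lowest (i, j)
    index pair in the current node order (first occurrence in row-major
    scan).  The last three nodes are joined at a trifurcating root via the
    three-point formulas.
    """
    n = len(distances.probe_ids)
    if n < 2:
        raise ValidationError("neighbour joining needs at least 2 leaves")
    nodes: list[TreeNode] = [TreeNode(name=p) for p in distances.probe_ids]
    d = np.array(distances.D, dtype=float)

    if n == 2:
        half = d[0, 1] / 2.0
        nodes[0].length = half
        nodes[1].length = half
        return CoexpressionTree(TreeNode(children=nodes))

    while len(nodes) > 3:
        m = len(nodes)
        s = d.sum(axis=1)
        q = (m - 2) * d - s[:, None] - s[None, :]
        np.fill_diagonal(q, np.inf)
        i, j = np.unravel_index(int(np.argmin(q)), q.shape)
        if i > j:
            i, j = j, i
        li = 0.5 * d[i, j] + (s[i] - s[j]) / (2.0 * (m - 2))
        lj = d[i, j] - li
        li, lj = _clamp_pair(li, lj, d[i, j])
        left, right = nodes[i], nodes[j]
        left.length, right.length = li, lj
        joined = TreeNode(children=[left, right])
        new_row = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        d_next = np.empty((m - 1, m - 1))
        d_next[:-1, :-1] = d[np.ix_(keep, keep)]
        d_next[:-1, -1] = d_next[-1, :-1] = new_row[keep]
        d_next[-1, -1] = 0.0
        d = d_next
        nodes = [nodes[k] for k in keep] + [joined]

    a, b, c = nodes
    la = 0.5 * (d[0, 1] + d[0, 2] - d[1, 2])
    lb = 0.5 * (d[0, 1] + d[1, 2] - d[0, 2])
    lc = 0.5 * (d[0, 2] + d[1, 2] - d[0, 1])
    lengths = []
    for value in (la, lb, lc):
        if value < 0.0:
            logger.info("clamping negative terminal branch length %.3g to 0", value)
            value = 0.0
        lengths.append(value)
    a.length, b.length, c.length = lengths
    return CoexpressionTree(TreeNode(children=[a, b, c]))


def _clamp_pair(li: float, lj: float, dij: float) -> tuple[float, float]:
    # Negative estimates: zero the offender, give the deficit to the sister
    # edge so li + lj still equals d(i, j).
    if li < 0.0:
        logger.info("clamping negative branch length %.3g to 0", li)
        return 0.0, dij
    if lj < 0.0:
        logger.info("clamping negative branch length %.3g to 0", lj)
        return dij, 0.0
    return li, lj


def neighborhood(tree: CoexpressionTree, query: str, height: float) -> Neighborhood:
    """Clade neighborhood of *query*: ascend through ancestors while the path
    length from the query stays <= *height*, then collect every leaf below
    the deepest such ancestor.  ``height = 0`` yields the query alone (unless
    zero-length branches make other leaves equidistant)."""
    if height < 0:
        raise ValidationError("height must be >= 0")
    leaf = tree.find_leaf(query)
    node = leaf
    climbed = 0.0
    anchor = leaf
    while node.parent is not None:
        climbed += node.length or 0.0
        if climbed > height:
            break
        node = node.parent
        anchor = node
    members = tuple(l.name for l in anchor.leaves())
    return Neighborhood(ProbeSetId(query), float(height), members)


def tree_ranked_list(
    tree: CoexpressionTree, query: str, height: float, cm
) -> list[tuple[str, float]]:
    """Neighborhood members ordered by descending correlation with the query
    (ties by probe ID); the query itself leads with r = 1."""
    hood = neighborhood(tree, query, height)
    pairs = [(member, cm.r(query, member)) for member in hood.members]
    pairs.sort(key=lambda pr: (-pr[1], pr[0]))
    return pairs


def midpoint_root(tree: CoexpressionTree) -> CoexpressionTree:
    """Re-root at the midpoint of the longest leaf-to-leaf path.

    Optional alternative to the trifurcating NJ root; returns a new tree
    with a bifurcating root.
    """
    dm = tree.leaf_distances()
    d = dm.D
    i, j = np.unravel_index(int(np.argmax(d)), d.shape)
    if d[i, j] == 0.0:
        return tree
    target = d[i, j] / 2.0

    # walk from leaf i towards leaf j, find the edge containing the midpoint
    src = tree.find_leaf(dm.probe_ids[i])
    dst = tree.find_leaf(dm.probe_ids[j])
    path = _node_path(src, dst)
    travelled = 0.0
    for a, b in zip(path, path[1:]):
        edge_len, child = _edge_between(a, b)
        if travelled + edge_len >= target - 1e-15:
            offset = target - travelled  # distance from `a` into the edge
            return _reroot_on_edge(tree, child, a, offset)
        travelled += edge_len
    return tree  # pragma: no cover - midpoint always lies on the path


def _node_path(src: TreeNode, dst: TreeNode) -> list[TreeNode]:
    up: list[TreeNode] = [src]
    node = src
    while node.parent is not None:
        node = node.parent
        up.append(node)
    ancestors = {id(n): k for k, n in enumerate(up)}
    down: list[TreeNode] = [dst]
    node = dst
    while id(node) not in ancestors:
        node = node.parent
        down.append(node)
    return up[: ancestors[id(node)]] + list(reversed(down))


def _edge_between(a: TreeNode, b: TreeNode) -> tuple[float, TreeNode]:
    """Length of the edge joining adjacent nodes and its child endpoint."""
    if b.parent is a:
        return (b.length or 0.0), b
    if a.parent is b:
        return (a.length or 0.0), a
    raise ValueError("nodes are not adjacent")


def _reroot_on_edge(
    tree: CoexpressionTree, child: TreeNode, towards: TreeNode, offset: float
) -> CoexpressionTree:
    """Split the parent(child) edge and root there; *offset* is measured from
    the *towards* endpoint of the edge."""
    edge_len = child.length or 0.0
    if towards is child:
        below_part = offset
    else:
        below_part = edge_len - offset
    below_part = min(max(below_part, 0.0), edge_len)
    upper = _flip_to_root(child.parent, exclude=child)
    upper.length = edge_len - below_part
    child.parent = None
    child.length = below_part
    root = TreeNode(children=[child, upper])
    return CoexpressionTree(root)


def _flip_to_root(node: TreeNode, exclude: TreeNode) -> TreeNode:
    """Rebuild the tree hanging off *node* when viewed from the (removed)
    edge towards *exclude*; parent links are reversed iteratively."""
    new_node = TreeNode(name=node.name)
    new_node.children = [c for c in node.children if c is not exclude]
    if node.parent is not None:
        flipped = _flip_to_root(node.parent, exclude=node)
        flipped.length = node.length or 0.0
        new_node.children = new_node.children + [flipped]
    for c in new_node.children:
        c.parent = new_node
    # a former root left with a single child is collapsed into its child
    if len(new_node.children) == 1 and new_node.name is None:
        only = new_node.children[0]
        only.length = (only.length or 0.0) + (new_node.length or 0.0)
        only.parent = None
        return only
    return new_node
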