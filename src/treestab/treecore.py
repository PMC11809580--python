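"""Unrooted binary trees: Newick I/O, splits, pruning, and topological distances.

The whole stability analysis runs on unrooted binary trees with branch
lengths in expected substitutions per site and optional bootstrap-support
labels on internal edges.  Rooted Newick input is unrooted by suppressing
the degree-2 root (its two incident edge lengths are summed).  Supports
follow the IQ-TREE convention: an internal-node label is the support of the
edge above that node.
"""

from __future__ import annotations

import io
from collections import deque
from dataclasses import dataclass
from typing import Iterable, Iterator

import dendropy

__all__ = [
    "NewickParseError",
    "TreeValidationError",
    "Split",
    "UnrootedTree",
    "parse_newick",
    "rf_distance",
]


class NewickParseError(ValueError):
    """Malformed Newick input (message includes the parser's position info)."""


class TreeValidationError(ValueError):
    """Structurally invalid tree (duplicate labels, polytomy, < 3 leaves ...)."""


@dataclass(frozen=True)
class Split:
    """A nontrivial-or-trivial bipartition of a leaf set.

    Stored canonically as the block that does NOT contain the
    lexicographically smallest leaf, so equal bipartitions hash equally.
    """

    block: frozenset
    leaves: frozenset

    @staticmethod
    def from_side(side: Iterable[str], leaves: Iterable[str]) -> "Split":
        leaves = frozenset(leaves)
        block = frozenset(side)
        if min(leaves) in block:
            block = leaves - block
        return Split(block, leaves)

    @property
    def is_trivial(self) -> bool:
        return len(self.block) <= 1 or len(self.leaves - self.block) <= 1

    def remove(self, label: str) -> "Split":
        """The induced bipartition after deleting one leaf from the set."""
        new_leaves = self.leaves - {label}
        return Split.from_side(self.block - {label}, new_leaves)

    def sort_key(self):
        return (len(self.block), tuple(sorted(self.block)))

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        other = sorted(self.leaves - self.block)
        return f"Split({''.join(sorted(self.block))}|{''.join(other)})"


class _Edge:
    __slots__ = ("u", "v", "length", "support")

    def __init__(self, u: int, v: int, length: float, support: float | None):
        self.u = u
        self.v = v
        self.length = float(length)
        self.support = support

    def other(self, node: int) -> int:
        return self.v if node == self.u else self.u


class UnrootedTree:
    """Unrooted binary tree over labelled leaves.

    Internal nodes all have degree 3; an ``n``-leaf tree has ``2n - 3``
    edges, ``n - 3`` of which are internal and carry the nontrivial splits.
    Branch lengths are nonnegative reals; supports, when present, live on
    internal edges and are percentages in [0, 100].
    """

    def __init__(self):
        self._adj: dict[int, dict[int, int]] = {}
        self.edges: dict[int, _Edge] = {}
        self._leaf_label: dict[int, str] = {}
        self._label_node: dict[str, int] = {}
        self._next_node = 0
        self._next_edge = 0

    # ------------------------------------------------------------------ build
    def _new_node(self, label: str | None = None) -> int:
        nid = self._next_node
        self._next_node += 1
        self._adj[nid] = {}
        if label is not None:
            if label in self._label_node:
                raise TreeValidationError(f"duplicate leaf label {label!r}")
            if not label:
                raise TreeValidationError("empty leaf label")
            self._leaf_label[nid] = label
            self._label_node[label] = nid
        return nid

    def _add_edge(self, u: int, v: int, length: float, support: float | None) -> int:
        if length < 0:
            raise TreeValidationError(f"negative branch length {length}")
        eid = self._next_edge
        self._next_edge += 1
        self.edges[eid] = _Edge(u, v, length, support)
        self._adj[u][v] = eid
        self._adj[v][u] = eid
        return eid

    def _remove_edge(self, eid: int) -> None:
        e = self.edges.pop(eid)
        del self._adj[e.u][e.v]
        del self._adj[e.v][e.u]

    @classmethod
    def star(cls, labels: Iterable[str], lengths: Iterable[float] | None = None) -> "UnrootedTree":
        """The unique 3-leaf topology."""
        labels = list(labels)
        if len(labels) != 3:
            raise TreeValidationError("star() needs exactly 3 labels")
        lengths = list(lengths) if lengths is not None else [1.0, 1.0, 1.0]
        t = cls()
        center = t._new_node()
        for lab, ln in zip(labels, lengths):
            leaf = t._new_node(lab)
            t._add_edge(center, leaf, ln, None)
        return t

    def copy(self) -> "UnrootedTree":
        t = UnrootedTree()
        t._adj = {n: dict(nb) for n, nb in self._adj.items()}
        t.edges = {k: _Edge(e.u, e.v, e.length, e.support) for k, e in self.edges.items()}
        t._leaf_label = dict(self._leaf_label)
        t._label_node = dict(self._label_node)
        t._next_node = self._next_node
        t._next_edge = self._next_edge
        return t

    # ------------------------------------------------------------- inspection
    @property
    def leaf_labels(self) -> list[str]:
        return sorted(self._label_node)

    @property
    def n_leaves(self) -> int:
        return len(self._label_node)

    def is_leaf(self, node: int) -> bool:
        return node in self._leaf_label

    def nodes(self) -> Iterator[int]:
        return iter(self._adj)

    def degree(self, node: int) -> int:
        return len(self._adj[node])

    def neighbors(self, node: int) -> list[int]:
        return sorted(self._adj[node])

    def leaf_node(self, label: str) -> int:
        try:
            return self._label_node[label]
        except KeyError:
            raise KeyError(f"no leaf labelled {label!r}") from None

    def pendant_edge(self, label: str) -> int:
        node = self.leaf_node(label)
        (eid,) = self._adj[node].values()
        return eid

    def is_internal_edge(self, eid: int) -> bool:
        e = self.edges[eid]
        return not (self.is_leaf(e.u) or self.is_leaf(e.v))

    def internal_edges(self) -> list[int]:
        return [eid for eid in sorted(self.edges) if self.is_internal_edge(eid)]

    def edge_ids(self) -> list[int]:
        return sorted(self.edges)

    def total_branch_length(self) -> float:
        return sum(e.length for e in self.edges.values())

    def mean_branch_length(self) -> float:
        return self.total_branch_length() / len(self.edges)

    # ------------------------------------------------------------- validation
    def validate(self) -> None:
        n = self.n_leaves
        if n < 3:
            raise TreeValidationError(f"tree has {n} leaves; need at least 3")
        for node, nb in self._adj.items():
            deg = len(nb)
            if self.is_leaf(node):
                if deg != 1:
                    raise TreeValidationError(f"leaf {self._leaf_label[node]!r} has degree {deg}")
            elif deg != 3:
                raise TreeValidationError(
                    f"internal node has degree {deg}; only binary trees are supported"
                )
        if len(self.edges) != 2 * n - 3:
            raise TreeValidationError(
                f"{n}-leaf tree has {len(self.edges)} edges, expected {2 * n - 3}"
            )
        for e in self.edges.values():
            if e.length < 0:
                raise TreeValidationError("negative branch length")

    # ------------------------------------------------------------------ splits
    def side_leaves(self, eid: int, from_node: int | None = None) -> frozenset:
        """Leaf labels on one side of an edge (the side of ``from_node``,
        default the side of ``edges[eid].u``)."""
        e = self.edges[eid]
        start = e.u if from_node is None else from_node
        other = e.other(start)
        seen = {start}
        out = []
        stack = [start]
        while stack:
            node = stack.pop()
            if self.is_leaf(node):
                out.append(self._leaf_label[node])
            for nb in self._adj[node]:
                if nb not in seen and not (node == start and nb == other):
                    seen.add(nb)
                    stack.append(nb)
        return frozenset(out)

    def split_of_edge(self, eid: int) -> Split:
        leaves = frozenset(self._label_node)
        return Split.from_side(self.side_leaves(eid), leaves)

    def splits(self) -> frozenset:
        """The nontrivial splits, one per internal edge (``n - 3`` of them)."""
        return frozenset(self.split_of_edge(eid) for eid in self.internal_edges())

    def edge_splits(self) -> dict:
        """Mapping internal edge id -> its nontrivial Split."""
        return {eid: self.split_of_edge(eid) for eid in self.internal_edges()}

    def edge_for_split(self, split: Split) -> int | None:
        for eid, s in self.edge_splits().items():
            if s == split:
                return eid
        return None

    def topologically_equal(self, other: "UnrootedTree") -> bool:
        return rf_distance(self, other) == 0

    # ------------------------------------------------------------ topological
    def edge_node_distance(self, e1: int, e2: int) -> int:
        """Number of nodes on the path connecting two edges, endpoints
        inclusive: 0 for the same edge, 1 for edges sharing a node."""
        if e1 not in self.edges or e2 not in self.edges:
            raise KeyError("edge not in tree")
        if e1 == e2:
            return 0
        a = self.edges[e1]
        b = self.edges[e2]
        targets = {b.u, b.v}
        # BFS in the node graph from e1's endpoints.
        dist = {a.u: 0, a.v: 0}
        q = deque([a.u, a.v])
        while q:
            node = q.popleft()
            if node in targets:
                return dist[node] + 1
            for nb in self._adj[node]:
                if nb not in dist:
                    dist[nb] = dist[node] + 1
                    q.append(nb)
        raise RuntimeError("disconnected tree")  # pragma: no cover

    def node_distances(self, start: int) -> dict[int, float]:
        """Patristic (branch-length sum) distance from ``start`` to every node."""
        dist = {start: 0.0}
        q = deque([start])
        while q:
            node = q.popleft()
            for nb, eid in self._adj[node].items():
                if nb not in dist:
                    dist[nb] = dist[node] + self.edges[eid].length
                    q.append(nb)
        return dist

    def leaf_distance_matrix(self) -> dict[tuple[str, str], float]:
        """Patristic distances between all leaf pairs, keyed both ways."""
        out = {}
        for lab, node in self._label_node.items():
            dist = self.node_distances(node)
            for lab2, node2 in self._label_node.items():
                out[(lab, lab2)] = dist[node2]
        return out

    # --------------------------------------------------------------- surgery
    def _suppress_degree2(self, node: int) -> None:
        (n1, e1), (n2, e2) = list(self._adj[node].items())
        a, b = self.edges[e1], self.edges[e2]
        length = a.length + b.length
        sups = [s for s in (a.support, b.support) if s is not None]
        support = max(sups) if sups else None
        self._remove_edge(e1)
        self._remove_edge(e2)
        del self._adj[node]
        self._add_edge(n1, n2, length, support)

    def prune_taxon(self, label: str) -> "UnrootedTree":
        """Remove one leaf and its pendant edge; the resulting degree-2 node
        is suppressed with its two incident edge lengths summed."""
        if label not in self._label_node:
            raise KeyError(f"no leaf labelled {label!r}")
        if self.n_leaves < 4:
            raise TreeValidationError("pruning would leave fewer than 3 leaves")
        t = self.copy()
        node = t._label_node.pop(label)
        del t._leaf_label[node]
        (eid,) = list(t._adj[node].values())
        nbr = t.edges[eid].other(node)
        t._remove_edge(eid)
        del t._adj[node]
        if len(t._adj[nbr]) == 2:
            t._suppress_degree2(nbr)
        t.validate()
        return t

    def attach_leaf(
        self,
        eid: int,
        label: str,
        distal_length: float,
        pendant_length: float,
    ) -> "UnrootedTree":
        """Insert a new leaf on edge ``eid`` at ``distal_length`` from the
        edge's ``u`` endpoint, with the given pendant branch length.

        The split edge's two halves inherit its support label.
        """
        if label in self._label_node:
            raise TreeValidationError(f"leaf {label!r} already in tree")
        e = self.edges[eid]
        if not (-1e-12 <= distal_length <= e.length + 1e-12):
            raise ValueError("distal_length outside the edge")
        distal_length = min(max(distal_length, 0.0), e.length)
        t = self.copy()
        eu, ev, sup = e.u, e.v, e.support
        t._remove_edge(eid)
        w = t._new_node()
        leaf = t._new_node(label)
        t._add_edge(eu, w, distal_length, sup)
        t._add_edge(w, ev, e.length - distal_length, sup)
        t._add_edge(w, leaf, pendant_length, None)
        t.validate()
        return t

    def nni_neighbors(self, eid: int) -> list["UnrootedTree"]:
        """The two nearest-neighbor-interchange rearrangements around an
        internal edge, in deterministic order."""
        if not self.is_internal_edge(eid):
            raise ValueError("NNI requires an internal edge")
        e = self.edges[eid]
        u, v = e.u, e.v
        a, b = sorted(n for n in self._adj[u] if n != v)
        c, d = sorted(n for n in self._adj[v] if n != u)
        out = []
        for swap_with in (c, d):
            t = self.copy()
            # swap subtree b (at u) with subtree swap_with (at v)
            eb = t._adj[u].pop(b)
            ec = t._adj[v].pop(swap_with)
            del t._adj[b][u]
            del t._adj[swap_with][v]
            t.edges[eb].u, t.edges[eb].v = v, b
            t.edges[ec].u, t.edges[ec].v = u, swap_with
            t._adj[v][b] = eb
            t._adj[b][v] = eb
            t._adj[u][swap_with] = ec
            t._adj[swap_with][u] = ec
            out.append(t)
        return out

    def scale_branch_lengths(self, factor: float) -> "UnrootedTree":
        t = self.copy()
        for e in t.edges.values():
            e.length *= factor
        return t

    def relabel(self, mapping: dict[str, str]) -> "UnrootedTree":
        t = self.copy()
        t._leaf_label = {n: mapping.get(l, l) for n, l in self._leaf_label.items()}
        if len(set(t._leaf_label.values())) != len(t._leaf_label):
            raise TreeValidationError("relabelling collides")
        t._label_node = {l: n for n, l in t._leaf_label.items()}
        return t

    # ----------------------------------------------------------------- newick
    @classmethod
    def from_newick(cls, text: str) -> "UnrootedTree":
        return parse_newick(text)

    def to_newick(self, include_supports: bool = True) -> str:
        """Deterministic Newick string; supports written as internal-node
        labels, lengths to 10 significant digits."""
        root = self.edges[self.pendant_edge(min(self._label_node))].other(
            self.leaf_node(min(self._label_node))
        )
        if self.is_leaf(root):  # 3-leaf tree edge case cannot occur (center internal)
            root = next(n for n in self._adj if not self.is_leaf(n))

        def fmt_len(x: float) -> str:
            return format(x, ".10g")

        def fmt_sup(s: float | None) -> str:
            if s is None or not include_supports:
                return ""
            return format(s, ".10g")

        def write(node: int, parent: int) -> str:
            if self.is_leaf(node):
                eid = self._adj[node][parent]
                return f"{self._leaf_label[node]}:{fmt_len(self.edges[eid].length)}"
            parts = [write(nb, node) for nb in self.neighbors(node) if nb != parent]
            eid = self._adj[node][parent]
            e = self.edges[eid]
            return f"({','.join(parts)}){fmt_sup(e.support)}:{fmt_len(e.length)}"

        parts = [write(nb, root) for nb in self.neighbors(root)]
        return f"({','.join(parts)});"

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"UnrootedTree(n_leaves={self.n_leaves})"


def parse_newick(text: str) -> UnrootedTree:
    """Parse a Newick string into an :class:`UnrootedTree`.

    Rooted inputs are unrooted by suppressing the degree-2 root; numeric
    internal-node labels are attached as supports of the edge above the node.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            suppress_leaf_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises schema-specific errors
        raise NewickParseError(f"malformed Newick: {exc}") from None

    t = UnrootedTree()
    node_map: dict = {}
    labels_seen = set()
    for dnode in dtree.preorder_node_iter():
        if dnode.is_leaf():
            if not dnode.label:
                raise NewickParseError("leaf without a label")
            label = dnode.label
            if label in labels_seen:
                raise TreeValidationError(f"duplicate leaf label {label!r}")
            labels_seen.add(label)
            node_map[dnode] = t._new_node(label)
        else:
            node_map[dnode] = t._new_node()
        if dnode.parent_node is not None:
            support = None
            if not dnode.is_leaf() and dnode.label is not None:
                try:
                    support = float(dnode.label)
                except ValueError:
                    support = None
            length = dnode.edge.length if dnode.edge.length is not None else 0.0
            if length < 0:
                raise TreeValidationError("negative branch length in Newick input")
            t._add_edge(node_map[dnode.parent_node], node_map[dnode], length, support)

    # suppress any degree-2 artifacts (rooted input, knuckles)
    changed = True
    while changed:
        changed = False
        for node in list(t._adj):
            if not t.is_leaf(node) and len(t._adj[node]) == 2:
                t._suppress_degree2(node)
                changed = True
    # drop an isolated degree-0 root (e.g. "(A);"-style pathologies)
    for node in list(t._adj):
        if not t.is_leaf(node) and len(t._adj[node]) == 0:
            del t._adj[node]
    t.validate()
    return t


def rf_distance(t1: UnrootedTree, t2: UnrootedTree) -> int:
    """Robinson-Foulds distance: size of the symmetric difference of the two
    trees' nontrivial split sets.  At most ``2(n - 3)`` for binary trees."""
    l1, l2 = set(t1.leaf_labels), set(t2.leaf_labels)
    if l1 != l2:
        only1 = sorted(l1 - l2)
        only2 = sorted(l2 - l1)
        raise ValueError(
            f"leaf sets differ: only in first {only1}, only in second {only2}"
        )
    return len(t1.splits() ^ t2.splits())
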