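"""Felsenstein-pruning likelihood engine with directional edge messages.

For every directed edge (u -> v) the engine caches the message
``M(u->v)``: the conditional likelihood of the subtree on u's side,
transported across the edge to v.  With all messages cached, the total
likelihood can be evaluated at any node, the likelihood as a function of a
single branch length needs only that edge's two side-partials, and taxon
placement on an edge is a three-message product — the same bookkeeping the
fast placement tools use.

Two numerical conveniences: alignment columns are compressed to unique
site patterns (per-site values are expanded on output), and per-pattern
scaling factors guard against underflow.  Branch lengths are floored at
1e-9 when exponentiating the rate matrix so zero-length branches stay
evaluable.
"""

from __future__ import annotations

import numpy as np

from .seqmodels import Alignment, SubstModel
from .treecore import UnrootedTree

__all__ = ["LikelihoodEngine"]

_BL_FLOOR = 1e-9


class _Msg:
    """A scaled partial: array (k, P, 4) plus per-pattern log-scale (P,)."""

    __slots__ = ("arr", "logsc")

    def __init__(self, arr: np.ndarray, logsc: np.ndarray):
        self.arr = arr
        self.logsc = logsc

    @staticmethod
    def product(msgs: list["_Msg"]) -> "_Msg":
        arr = msgs[0].arr.copy()
        logsc = msgs[0].logsc.copy()
        for m in msgs[1:]:
            arr = arr * m.arr
            logsc = logsc + m.logsc
        return _Msg(arr, logsc)

    def rescaled(self) -> "_Msg":
        s = np.maximum(self.arr.max(axis=(0, 2)), 1e-300)
        return _Msg(self.arr / s[None, :, None], self.logsc + np.log(s))


class _PlacementEdge:
    """Attachment likelihood on one edge as a function of (distal, pendant).

    Spectral forms of the three side partials are cached so each evaluation
    costs one small einsum per moving parameter."""

    def __init__(self, engine: "LikelihoodEngine", eid: int, query: np.ndarray):
        self.engine = engine
        self.b_len = engine.tree.edges[eid].length
        A, B = engine.side_partials(eid)
        Qc = np.broadcast_to(
            engine.compress_site_values(query)[None, :, :],
            (engine.k, engine.n_patterns, 4),
        )
        Lm = engine.model._left
        self._LA = np.einsum("ab,klb->kla", Lm, A.arr)
        self._LB = np.einsum("ab,klb->kla", Lm, B.arr)
        self._LQ = np.einsum("ab,klb->kla", Lm, Qc)
        self._base = A.logsc + B.logsc

    def _transported(self, Lx: np.ndarray, t: float) -> np.ndarray:
        m = self.engine.model
        e = m.category_exp(t)  # (k, 4)
        return np.einsum("ab,klb->kla", m._right, e[:, None, :] * Lx)

    def _total(self, prod: np.ndarray) -> float:
        eng = self.engine
        lik = np.einsum("kla,a->l", prod, eng.model.pi) / eng.k
        return float(np.dot(eng.weights,
                            np.log(np.maximum(lik, 1e-300)) + self._base))

    def lnl(self, distal: float, pendant: float) -> float:
        distal = min(max(distal, 0.0), self.b_len)
        MA = self._transported(self._LA, distal)
        MB = self._transported(self._LB, self.b_len - distal)
        MQ = self._transported(self._LQ, pendant)
        return self._total(MA * MB * MQ)

    def pendant_objective(self, distal: float):
        distal = min(max(distal, 0.0), self.b_len)
        MA = self._transported(self._LA, distal)
        MB = self._transported(self._LB, self.b_len - distal)
        H = MA * MB

        def f(pendant: float) -> float:
            return self._total(H * self._transported(self._LQ, pendant))

        return f

    def distal_objective(self, pendant: float):
        MQ = self._transported(self._LQ, pendant)

        def f(distal: float) -> float:
            distal = min(max(distal, 0.0), self.b_len)
            MA = self._transported(self._LA, distal)
            MB = self._transported(self._LB, self.b_len - distal)
            return self._total(MA * MB * MQ)

        return f


class LikelihoodEngine:
    """Per-site likelihood machinery for one (tree, alignment, model) triple.

    The tree's leaves must all have sequences in the alignment.  Gaps and
    IUPAC ambiguity codes enter as partial-likelihood vectors (1 for every
    compatible state), so fully missing characters contribute likelihood 1.
    ``extra_taxa`` adds alignment rows to the site-pattern key without
    putting them in the tree (needed when a query sequence will be placed).
    """

    def __init__(
        self,
        tree: UnrootedTree,
        aln: Alignment,
        model: SubstModel,
        extra_taxa: list[str] | None = None,
    ):
        missing = [l for l in tree.leaf_labels if l not in aln]
        if missing:
            raise ValueError(f"leaves without sequences: {missing}")
        self.tree = tree
        self.model = model
        self.k = len(model.category_rates)
        self.n_sites = aln.n_sites
        key_taxa = tree.leaf_labels + sorted(extra_taxa or [])
        cols = np.array(
            [list(aln.sequence(t).upper()) for t in key_taxa], dtype="S1"
        ).T  # (n_sites, n_key_taxa) single bytes
        keys = np.ascontiguousarray(cols).view(f"S{cols.shape[1]}").ravel()
        _, first_idx, inverse = np.unique(keys, return_index=True, return_inverse=True)
        self.pattern_index = inverse  # (n_sites,)
        self._first_idx = first_idx   # (n_patterns,)
        self.n_patterns = len(first_idx)
        counts = np.bincount(inverse, minlength=self.n_patterns)
        self.weights = counts.astype(float)
        self._tips: dict[int, _Msg] = {}
        for label in tree.leaf_labels:
            node = tree.leaf_node(label)
            part = aln.tip_partials(label)[first_idx]  # (P, 4)
            arr = np.broadcast_to(part[None, :, :], (self.k, self.n_patterns, 4)).copy()
            self._tips[node] = _Msg(arr, np.zeros(self.n_patterns))
        self._msgs: dict[tuple[int, int], _Msg] = {}
        self.refresh()

    def compress_site_values(self, per_site: np.ndarray) -> np.ndarray:
        """Restrict a per-site array to the unique-pattern representatives."""
        return np.asarray(per_site)[self._first_idx]

    # --------------------------------------------------------------- passes
    def _transport(self, msg: _Msg, length: float) -> _Msg:
        P = self.model.transition_matrices(max(length, _BL_FLOOR))
        out = np.einsum("kab,klb->kla", P, msg.arr)
        return _Msg(out, msg.logsc).rescaled()

    def _side_partial_from(self, node: int, excl: int) -> _Msg:
        """Partial at ``node`` for the component away from ``excl`` (uses
        cached incoming messages)."""
        if self.tree.is_leaf(node):
            return self._tips[node]
        msgs = [self._msgs[(nb, node)] for nb in self.tree.neighbors(node) if nb != excl]
        return _Msg.product(msgs)

    def refresh(self) -> None:
        """Recompute all directional messages (after any length mutation)."""
        tree = self.tree
        root = next(n for n in tree.nodes() if not tree.is_leaf(n))
        order = []
        stack = [(root, None)]
        while stack:
            node, parent = stack.pop()
            order.append((node, parent))
            for nb in tree.neighbors(node):
                if nb != parent:
                    stack.append((nb, node))
        self._msgs.clear()
        for node, parent in reversed(order):
            if parent is None:
                continue
            eid = tree._adj[node][parent]
            part = self._side_partial_from(node, parent)
            self._msgs[(node, parent)] = self._transport(part, tree.edges[eid].length)
        for node, parent in order:
            if parent is None:
                continue
            eid = tree._adj[node][parent]
            part = self._side_partial_from(parent, node)
            self._msgs[(parent, node)] = self._transport(part, tree.edges[eid].length)

    # ------------------------------------------------------------ evaluation
    def _pattern_lnl(self, full: _Msg) -> np.ndarray:
        lik = np.einsum("kla,a->l", full.arr, self.model.pi) / self.k
        return np.log(np.maximum(lik, 1e-300)) + full.logsc

    def site_log_likelihoods(self) -> np.ndarray:
        tree = self.tree
        root = next(n for n in tree.nodes() if not tree.is_leaf(n))
        full = _Msg.product([self._msgs[(nb, root)] for nb in tree.neighbors(root)])
        return self._pattern_lnl(full)[self.pattern_index]

    def log_likelihood(self) -> float:
        tree = self.tree
        root = next(n for n in tree.nodes() if not tree.is_leaf(n))
        full = _Msg.product([self._msgs[(nb, root)] for nb in tree.neighbors(root)])
        return float(np.dot(self.weights, self._pattern_lnl(full)))

    def side_partials(self, eid: int) -> tuple[_Msg, _Msg]:
        """Partials at the two endpoints of an edge, each for its own side."""
        e = self.tree.edges[eid]
        return (
            self._side_partial_from(e.u, e.v),
            self._side_partial_from(e.v, e.u),
        )

    def edge_lnl_function(self, eid: int):
        """Total lnL as a function of one branch length, all else fixed."""
        A, B = self.side_partials(eid)
        m = self.model
        pi = m.pi
        base = A.logsc + B.logsc
        LB = np.einsum("ab,klb->kla", m._left, B.arr)
        Api = A.arr * pi[None, None, :]

        def f(t: float) -> float:
            e = m.category_exp(t)
            MB = np.einsum("ab,klb->kla", m._right, e[:, None, :] * LB)
            lik = np.einsum("kla,kla->l", Api, MB) / self.k
            return float(np.dot(self.weights, np.log(np.maximum(lik, 1e-300)) + base))

        return f

    def placement_edge(self, eid: int, query_partial: np.ndarray) -> _PlacementEdge:
        """Attachment-likelihood evaluator for one edge; ``query_partial``
        is the query's per-site (n_sites, 4) tip-partial matrix."""
        return _PlacementEdge(self, eid, query_partial)
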