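"""Maximum-likelihood placement of a query taxon on an inferred tree.

Every edge of the tree is tried as an attachment point: the pendant branch
length and the attachment position along the edge are optimized by
coordinate descent while all other branch lengths stay fixed.  Attachment
likelihoods are converted to likelihood weight ratios

    LWR(l_i) = L(D | T, l_i) / sum_j L(D | T, l_j)

over all edges, and candidates are reported sorted by decreasing LWR,
truncated once the cumulative LWR exceeds 0.99 (a single dominant edge with
LWR > 0.99 is reported alone).  A jplace v3 writer is provided.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import logsumexp

from .likelihood import LikelihoodEngine
from .seqmodels import Alignment, SubstModel
from .treecore import UnrootedTree

__all__ = [
    "PlacementCandidate",
    "PlacementSet",
    "placement_candidates",
    "best_placement_tree",
    "jplace_string",
]

_PENDANT_MAX = 10.0
_OPT_TOL = 1e-6


@dataclass(frozen=True)
class PlacementCandidate:
    """One candidate attachment edge for the query taxon."""

    edge_id: int
    lwr: float
    pendant_length: float
    distal_length: float
    log_likelihood: float


@dataclass
class PlacementSet:
    """Ranked placement candidates (sorted by decreasing LWR, truncated at
    cumulative LWR > 0.99).  ``full`` keeps the untruncated per-edge list so
    the LWR normalization can be audited."""

    taxon: str
    candidates: list
    full: list

    def __post_init__(self):
        if not self.candidates:
            raise ValueError("empty placement set")

    @property
    def best(self) -> PlacementCandidate:
        return self.candidates[0]

    def __len__(self) -> int:
        return len(self.candidates)


def _optimize_edge(pe, rounds: int = 2):
    """Coordinate descent over (distal, pendant) for one edge, using the
    engine's cached spectral partials."""
    b_len = pe.b_len
    distal = 0.5 * b_len
    pendant = 0.05
    best = pe.lnl(distal, pendant)
    for _ in range(rounds):
        round_start = best
        fp = pe.pendant_objective(distal)
        res = minimize_scalar(
            lambda p: -fp(p), bounds=(0.0, _PENDANT_MAX),
            method="bounded", options={"xatol": _OPT_TOL},
        )
        if -res.fun >= best:
            pendant, best = float(res.x), -res.fun
        if b_len > 0:
            fd = pe.distal_objective(pendant)
            res = minimize_scalar(
                lambda x: -fd(x), bounds=(0.0, b_len),
                method="bounded", options={"xatol": _OPT_TOL},
            )
            if -res.fun >= best:
                distal, best = float(res.x), -res.fun
        if best - round_start < 1e-3:
            break
    # snap near-zero optima to the boundary (the bounded optimizer cannot
    # reach it exactly)
    if pendant < 1e-5:
        at_zero = pe.lnl(distal, 0.0)
        if at_zero >= best - 1e-9:
            pendant, best = 0.0, at_zero
    return distal, pendant, best


def placement_candidates(
    tree: UnrootedTree,
    aln: Alignment,
    s: str,
    model: SubstModel,
    cumulative_lwr: float = 0.99,
) -> PlacementSet:
    """Place taxon ``s`` (present in the alignment, absent from the tree)
    on every edge and rank the attachments by likelihood weight ratio."""
    if s in tree.leaf_labels:
        raise ValueError(f"taxon {s!r} is already in the tree")
    if s not in aln:
        raise ValueError(f"taxon {s!r} is not in the alignment")
    engine = LikelihoodEngine(tree, aln, model, extra_taxa=[s])
    query = aln.tip_partials(s)
    # cheap screen first: every edge is evaluated at its midpoint with a
    # few pendant lengths; only edges within a wide log-likelihood margin
    # of the screening best get the full two-parameter optimization (the
    # others' LWR is numerically zero either way, and their screened value
    # still enters the LWR denominator)
    screen_pendants = (0.02, 0.2, 1.0)
    margin = 50.0
    edges = {}
    screened = {}
    for eid in tree.edge_ids():
        pe = engine.placement_edge(eid, query)
        edges[eid] = pe
        mid = 0.5 * pe.b_len
        vals = [(pe.lnl(mid, p), p) for p in screen_pendants]
        screened[eid] = (max(vals), mid)
    best_screen = max(v[0][0] for v in screened.values())
    raw = []
    for eid, pe in edges.items():
        (lnl0, p0), mid = screened[eid]
        if lnl0 >= best_screen - margin:
            distal, pendant, lnl = _optimize_edge(pe)
        else:
            distal, pendant, lnl = mid, p0, lnl0
        raw.append((eid, distal, pendant, lnl))
    lnls = np.array([r[3] for r in raw])
    lwr = np.exp(lnls - logsumexp(lnls))
    full = [
        PlacementCandidate(eid, float(w), pendant, distal, lnl)
        for (eid, distal, pendant, lnl), w in zip(raw, lwr)
    ]
    # deterministic order: decreasing LWR, ties broken by canonical split form
    full_sorted = sorted(
        full, key=lambda c: (-c.lwr, tree.split_of_edge(c.edge_id).sort_key())
    )
    kept, cum = [], 0.0
    for cand in full_sorted:
        kept.append(cand)
        cum += cand.lwr
        if cum > cumulative_lwr:
            break
    return PlacementSet(s, kept, full_sorted)


def best_placement_tree(
    tree: UnrootedTree, placement: PlacementSet, s: str | None = None
) -> UnrootedTree:
    """The tree with the query attached at its best candidate edge: the
    insertion branch is split at the optimized distal length and the query
    hangs by its pendant branch."""
    s = s or placement.taxon
    best = placement.best
    return tree.attach_leaf(best.edge_id, s, best.distal_length, best.pendant_length)


def jplace_string(tree: UnrootedTree, placement: PlacementSet) -> str:
    """Serialize a placement as jplace v3 (edge numbering ``{k}``)."""
    edge_num = {eid: k for k, eid in enumerate(tree.edge_ids())}
    root = tree.edges[tree.pendant_edge(min(tree.leaf_labels))].other(
        tree.leaf_node(min(tree.leaf_labels))
    )

    def write(node: int, parent: int) -> str:
        eid = tree._adj[node][parent]
        e = tree.edges[eid]
        tail = f":{format(e.length, '.10g')}{{{edge_num[eid]}}}"
        if tree.is_leaf(node):
            return tree._leaf_label[node] + tail
        parts = [write(nb, node) for nb in tree.neighbors(node) if nb != parent]
        return f"({','.join(parts)}){tail}"

    newick = "(" + ",".join(write(nb, root) for nb in tree.neighbors(root)) + ");"
    doc = {
        "version": 3,
        "tree": newick,
        "placements": [
            {
                "p": [
                    [
                        edge_num[c.edge_id],
                        c.log_likelihood,
                        c.lwr,
                        c.distal_length,
                        c.pendant_length,
                    ]
                    for c in placement.candidates
                ],
                "n": [placement.taxon],
            }
        ],
        "fields": [
            "edge_num",
            "likelihood",
            "like_weight_ratio",
            "distal_length",
            "pendant_length",
        ],
        "metadata": {"invocation": "treestab placement"},
    }
    return json.dumps(doc, indent=1)
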