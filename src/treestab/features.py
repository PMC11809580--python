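"""Summary statistics for predicting taxon-addition stability.

One FeatureVector per taxon addition, computed exclusively from the
inferred tree Ts* (with bootstrap supports), the placement of the taxon on
it, the augmented tree Ts+, and the alignment — never from the full tree,
so the features remain usable as predictors when re-inference is the thing
one wants to avoid.

All standard deviations are population SDs (divide by N).  Branch-length
features are normalized by the mean branch length of Ts+; topological
distances by the relevant tree diameter, as stated per feature.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields as dc_fields

import numpy as np

from .inference import nj_tree
from .placement import PlacementSet
from .seqmodels import Alignment, SubstModel, corrected_distance_matrix
from .stability import LOW_SUPPORT_THRESHOLD, tii
from .treecore import UnrootedTree

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureVector",
    "FEATURE_COLUMNS",
    "insertion_distance_stats",
    "branch_features",
    "support_features",
    "sequence_distance_features",
    "insertion_height",
    "nj_tii_feature",
    "assemble_features",
]


@dataclass
class FeatureVector:
    """The per-taxon summary-statistic battery (one classifier/regressor
    input row).  Missing optional values stay None, never zero-filled."""

    taxon: str
    insertion_dist_mean: float | None = None
    insertion_dist_sd: float | None = None
    lwr: float | None = None
    n_insertion_locations: int | None = None
    insertion_branch_length: float | None = None
    norm_dist_nearest_node: float | None = None
    pendant_length: float | None = None
    dist_low_bootstrap_edge: float | None = None
    bootstrap_mean: float | None = None
    bootstrap_sd: float | None = None
    distance_ratio_mean: float | None = None
    distance_ratio_sd: float | None = None
    ratio_diff_closest_mean: float | None = None
    ratio_diff_closest_sd: float | None = None
    dist_diff_insertion_sibling: float | None = None
    insertion_height: float | None = None
    nj_tii: float | None = None
    pythia_difficulty: float | None = None

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in dc_fields(self)}


FEATURE_COLUMNS = [f.name for f in dc_fields(FeatureVector) if f.name != "taxon"]


def _pop_sd(values) -> float:
    return float(np.std(np.asarray(values, dtype=float)))


# ----------------------------------------------------------- spread features
def _edge_pair_diameter(tree: UnrootedTree) -> int:
    eids = tree.edge_ids()
    return max(
        (tree.edge_node_distance(a, b) for i, a in enumerate(eids) for b in eids[i + 1:]),
        default=0,
    )


def insertion_distance_stats(
    placements: PlacementSet, tree: UnrootedTree
) -> tuple[float, float]:
    """Mean and SD of pairwise topological distances between high-quality
    insertion edges, normalized by the tree's edge-pair diameter.  A single
    dominant location gives (0, 0)."""
    edges = [c.edge_id for c in placements.candidates]
    if len(edges) == 1:
        return 0.0, 0.0
    diam = _edge_pair_diameter(tree)
    if diam == 0:
        return 0.0, 0.0
    dists = [
        tree.edge_node_distance(a, b) / diam
        for i, a in enumerate(edges)
        for b in edges[i + 1:]
    ]
    return float(np.mean(dists)), _pop_sd(dists)


def branch_features(
    tree: UnrootedTree, best, tplus: UnrootedTree
) -> tuple[float, float, float]:
    """(insertion branch length, normalized distance to nearest node,
    pendant length); branch lengths normalized by Ts+'s mean branch length,
    the attachment offset by the insertion branch length itself."""
    mean_bl = tplus.mean_branch_length()
    if mean_bl <= 0:
        logger.warning("degenerate tree: mean branch length 0; using 1.0")
        mean_bl = 1.0
    b = tree.edges[best.edge_id].length
    if b > 0:
        nearest = min(best.distal_length, b - best.distal_length) / b
    else:
        nearest = 0.0  # limit of the ratio as the branch shrinks
    return b / mean_bl, nearest, best.pendant_length / mean_bl


def support_features(
    tree: UnrootedTree, best, threshold: float = LOW_SUPPORT_THRESHOLD
) -> tuple[float, float, float]:
    """(bootstrap mean, bootstrap SD, normalized distance from the best
    insertion edge to the closest low-support edge)."""
    internal = tree.internal_edges()
    sups = [tree.edges[eid].support for eid in internal]
    if any(s is None for s in sups) or not sups:
        raise ValueError("inferred tree lacks bootstrap supports")
    low = [eid for eid in internal if tree.edges[eid].support < threshold]
    best_eid = best.edge_id
    denom = max(
        (tree.edge_node_distance(best_eid, other) for other in tree.edge_ids()
         if other != best_eid),
        default=1,
    )
    denom = max(denom, 1)
    if not low:
        logger.info("no low-support edge; dist_low_bootstrap_edge set to 1.0")
        dist = 1.0
    else:
        dist = min(tree.edge_node_distance(best_eid, l) for l in low) / denom
    return float(np.mean(sups)), _pop_sd(sups), float(dist)


# ----------------------------------------------- sequence-distance features
def _sibling_clades(tree: UnrootedTree, best_eid: int) -> tuple[frozenset, frozenset]:
    """Resolve (C, C') around the best insertion edge of the unrooted tree.

    C is the leaf set on the far side of the edge from the canonical
    reference leaf (the lexicographically smallest); at the near endpoint
    the two remaining subtrees are the sister candidates and C' is the one
    with fewer leaves (ties break on the smallest leaf label)."""
    ref = min(tree.leaf_labels)
    e = tree.edges[best_eid]
    side_u = tree.side_leaves(best_eid, from_node=e.u)
    if ref in side_u:
        near, C = e.u, frozenset(tree.side_leaves(best_eid, from_node=e.v))
    else:
        near, C = e.v, frozenset(side_u)
    if tree.is_leaf(near):
        return C, frozenset({tree._leaf_label[near]})
    cands = []
    for nb in tree.neighbors(near):
        eid = tree._adj[near][nb]
        if eid == best_eid:
            continue
        cands.append(frozenset(tree.side_leaves(eid, from_node=nb)))
    cands.sort(key=lambda s: (len(s), min(s)))
    return C, cands[0]


def sequence_distance_features(
    aln: Alignment,
    s: str,
    tplus: UnrootedTree,
    model: SubstModel,
    inferred_tree: UnrootedTree,
    best_eid: int,
    D=None,
) -> tuple[float, float, float, float, float]:
    """Tree-likeness diagnostics of the added sequence.

    For each other taxon t: ratio_t = (model-corrected sequence distance
    from t to s) / (patristic distance in Ts+) -> mean/SD.  The closest-
    sequence comparison divides s's ratio by the analogous ratio of the
    taxon whose sequence is nearest to s.  The sibling statistic is
    as / aC with as the mean sequence distance from s to the sister clade
    C' of the insertion clade C, and aC the mean C-to-C' sequence distance.
    """
    taxa = [t for t in tplus.leaf_labels if t != s]
    if len(taxa) < 3:
        raise ValueError("need at least 3 non-query taxa")
    if D is None:
        D = corrected_distance_matrix(aln.subset(tplus.leaf_labels), model)
    pat = tplus.leaf_distance_matrix()

    def ratio(t, x):
        p = pat[(t, x)]
        if p <= 0:
            raise ValueError(f"zero patristic distance between {t!r} and {x!r}")
        return D[(t, x)] / p

    ratios = [ratio(t, s) for t in taxa]
    closest = min(taxa, key=lambda t: (D[(t, s)], t))
    rel = []
    for t in taxa:
        if t == closest:
            continue
        rc = ratio(t, closest)
        if rc == 0:
            logger.warning("zero distance ratio for %r vs closest taxon; term skipped", t)
            continue
        rel.append(ratio(t, s) / rc)
    if not rel:
        rel_mean = rel_sd = float("nan")
    else:
        rel_mean, rel_sd = float(np.mean(rel)), _pop_sd(rel)
    C, Cp = _sibling_clades(inferred_tree, best_eid)
    a_s = float(np.mean([D[(s, t)] for t in sorted(Cp)]))
    a_c = float(np.mean([D[(x, y)] for x in sorted(C) for y in sorted(Cp)]))
    sibling = a_s / a_c if a_c > 0 else float("nan")
    return float(np.mean(ratios)), _pop_sd(ratios), rel_mean, rel_sd, sibling


def insertion_height(tplus: UnrootedTree, s: str) -> float:
    """Patristic distance from the attachment point of s to the nearest
    other leaf, normalized by half the leaf-pair patristic diameter."""
    leaf = tplus.leaf_node(s)
    (eid,) = [tplus._adj[leaf][nb] for nb in tplus.neighbors(leaf)]
    attach = tplus.edges[eid].other(leaf)
    dist = tplus.node_distances(attach)
    raw = min(dist[tplus.leaf_node(t)] for t in tplus.leaf_labels if t != s)
    pat = tplus.leaf_distance_matrix()
    diam = max(pat.values())
    if diam <= 0:
        return 0.0
    return raw / (diam / 2.0)


def nj_tii_feature(aln: Alignment, s: str, model: SubstModel, D=None) -> float | None:
    """Normalized taxon influence index of s under Neighbor Joining.

    NJ trees are built on the full alignment and on the alignment without
    s (pairwise-deletion distances are unaffected by dropping a row, so the
    reduced matrix is reused).  Needs >= 5 taxa, else missing."""
    if aln.n_taxa < 5:
        return None
    if D is None:
        D = corrected_distance_matrix(aln, model)
    t_full = nj_tree(D)
    t_reduced = nj_tree(D.drop(s))
    _, norm = tii(t_full.prune_taxon(s), t_reduced)
    return norm


def assemble_features(
    tree: UnrootedTree,
    placement: PlacementSet,
    tplus: UnrootedTree,
    aln: Alignment,
    model: SubstModel,
    full_aln: Alignment | None = None,
    pythia_difficulty: float | None = None,
    distance_matrix=None,
) -> FeatureVector:
    """One complete feature row for one taxon addition.

    ``aln`` must contain the tree's taxa plus the query; ``full_aln`` (for
    the NJ TII) defaults to ``aln``.  A precomputed corrected distance
    matrix over the full taxon set may be supplied to avoid recomputation.
    Sub-feature failures leave explicit missing values and are logged; the
    row is still emitted."""
    s = placement.taxon
    fv = FeatureVector(taxon=s)
    best = placement.best
    try:
        fv.insertion_dist_mean, fv.insertion_dist_sd = insertion_distance_stats(
            placement, tree)
        fv.lwr = best.lwr
        fv.n_insertion_locations = len(placement)
    except Exception:
        logger.exception("insertion spread features failed for %r", s)
    try:
        (fv.insertion_branch_length, fv.norm_dist_nearest_node,
         fv.pendant_length) = branch_features(tree, best, tplus)
    except Exception:
        logger.exception("branch features failed for %r", s)
    try:
        fv.bootstrap_mean, fv.bootstrap_sd, fv.dist_low_bootstrap_edge = (
            support_features(tree, best))
    except Exception:
        logger.exception("support features failed for %r", s)
    try:
        (fv.distance_ratio_mean, fv.distance_ratio_sd,
         fv.ratio_diff_closest_mean, fv.ratio_diff_closest_sd,
         fv.dist_diff_insertion_sibling) = sequence_distance_features(
            aln, s, tplus, model, tree, best.edge_id, D=distance_matrix)
    except Exception:
        logger.exception("sequence-distance features failed for %r", s)
    try:
        fv.insertion_height = insertion_height(tplus, s)
    except Exception:
        logger.exception("insertion height failed for %r", s)
    try:
        fv.nj_tii = nj_tii_feature(full_aln or aln, s, model, D=distance_matrix)
    except Exception:
        logger.exception("NJ TII failed for %r", s)
    fv.pythia_difficulty = pythia_difficulty
    return fv
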