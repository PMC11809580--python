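"""Stability measures for a single taxon addition.

Given the full tree T* (on all taxa), the pruned tree Ts (T* with taxon s
removed) and the inferred tree Ts* (re-inferred without s), this module
computes the taxon influence index (TII), the disruption radius, and the
distance of unstable edges to low-bootstrap-support regions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .treecore import Split, UnrootedTree, rf_distance

logger = logging.getLogger(__name__)

__all__ = [
    "StabilityRecord",
    "tii",
    "edge_present_after_removal",
    "disruption_radius",
    "unstable_to_low_support_distance",
]

LOW_SUPPORT_THRESHOLD = 70.0


@dataclass
class StabilityRecord:
    """Per-taxon leave-one-out outcome.

    ``stable`` means TII = 0; ``significant_instability`` means TII != 0
    and the AU test rejects the pruned tree at the 0.05 level.  The AU/SH
    p-values and the unstable-edge distance are undefined (None) for stable
    taxa.
    """

    taxon: str
    tii: int
    tii_normalized: float
    disruption_radius: float
    mean_unstable_to_low_support: float | None = None
    au_p: float | None = None
    sh_p: float | None = None

    @property
    def stable(self) -> bool:
        return self.tii == 0

    @property
    def significant_instability(self) -> bool:
        return self.tii != 0 and self.au_p is not None and self.au_p < 0.05


def tii(pruned: UnrootedTree, inferred: UnrootedTree) -> tuple[int, float]:
    """Taxon influence index: RF distance between the pruned and inferred
    trees, plus its normalization by the maximum 2(m-3) for the m leaves of
    the compared trees.  (0, 0.0) iff the topologies coincide."""
    raw = rf_distance(pruned, inferred)
    m = pruned.n_leaves
    denom = 2 * (m - 3)
    return raw, (raw / denom if denom > 0 else 0.0)


def edge_present_after_removal(split: Split, inferred: UnrootedTree, s: str) -> bool:
    """Is a full-tree split still represented once taxon s is removed?

    True when deleting s from the split leaves a trivial bipartition (every
    tree induces those, via pendant edges) or a bipartition induced by some
    edge of the inferred tree."""
    reduced = split.remove(s)
    return reduced.is_trivial or reduced in inferred.splits()


def disruption_radius(full: UnrootedTree, inferred: UnrootedTree, s: str) -> float:
    """How far from s's attachment edge the topology changes reach, in
    node-count distance, normalized to [0, 1].

    The raw radius is the maximum distance from the pendant edge of s in
    the full tree to any full-tree internal edge whose split (with s
    removed) is absent from the inferred tree; the denominator is the
    maximum distance from s's pendant edge to any internal edge.  0 when
    nothing differs."""
    expected = set(inferred.leaf_labels) | {s}
    if set(full.leaf_labels) != expected:
        raise ValueError("leaf sets do not match (full must equal inferred plus s)")
    e_s = full.pendant_edge(s)
    internal = full.internal_edges()
    if not internal:
        return 0.0
    inferred_splits = inferred.splits()
    raw = 0
    denom = 0
    for eid in internal:
        d = full.edge_node_distance(e_s, eid)
        denom = max(denom, d)
        split = full.split_of_edge(eid)
        reduced = split.remove(s)
        if not (reduced.is_trivial or reduced in inferred_splits):
            raw = max(raw, d)
    return raw / denom if denom > 0 else 0.0


def unstable_to_low_support_distance(
    inferred: UnrootedTree,
    pruned: UnrootedTree,
    threshold: float = LOW_SUPPORT_THRESHOLD,
) -> float | None:
    """Mean normalized distance from unstable inferred-tree edges to their
    closest low-support edge.

    Unstable edges are internal edges of the inferred tree whose split is
    absent from the pruned tree.  Each distance is normalized by that
    edge's maximum distance to any internal edge.  Returns None when there
    are no unstable edges (stable case); an edge that is itself
    low-support contributes 0."""
    internal = inferred.internal_edges()
    missing = [eid for eid in internal if inferred.edges[eid].support is None]
    if missing:
        raise ValueError("inferred tree lacks support values on internal edges")
    pruned_splits = pruned.splits()
    unstable = [eid for eid in internal
                if inferred.split_of_edge(eid) not in pruned_splits]
    if not unstable:
        return None
    low = [eid for eid in internal if inferred.edges[eid].support < threshold]
    terms = []
    for eid in unstable:
        denom = max(inferred.edge_node_distance(eid, other) for other in internal) \
            if len(internal) > 1 else 1
        denom = max(denom, 1)
        if not low:
            logger.info("no low-support edge in inferred tree; distance term set to 1.0")
            terms.append(1.0)
            continue
        d = min(inferred.edge_node_distance(eid, l) for l in low)
        terms.append(d / denom)
    return sum(terms) / len(terms)
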