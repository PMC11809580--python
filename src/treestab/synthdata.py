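"""Synthetic trees, alignments, and labelled stability scenarios.

The generator produces the regimes the stability analysis cares about with
known ground truth:

* ``clean`` — strong signal: every internal branch at least 0.05 expected
  substitutions/site, so leave-one-out inference is almost always stable;
* ``low_support_region`` — a contiguous set of internal edges shrunk to
  near zero, creating a poorly supported neighbourhood where taxon removal
  can rearrange the topology;
* ``mosaic_taxon`` — the focal taxon's sequence is the concatenation of two
  conditionally simulated donor segments, breaking tree-likeness while
  preserving the marginal substitution process;
* ``long_pendant`` — the focal taxon's pendant branch is stretched by a
  configurable factor (long-branch-attraction risk).

Topologies are sampled uniformly (random sequential addition); branch
lengths are i.i.d. exponential with mean 0.1 substitutions/site unless a
scenario modifies them.  All randomness flows through one seeded generator
per scenario.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .seqmodels import Alignment, SubstModel
from .treecore import UnrootedTree

__all__ = [
    "Scenario",
    "ScenarioTruth",
    "default_scenario_model",
    "sample_tree",
    "simulate_alignment",
    "make_scenario",
    "fixture_suite",
]

_STATES = "ACGT"

SCENARIO_KINDS = ("clean", "low_support_region", "mosaic_taxon", "long_pendant")


def default_scenario_model() -> SubstModel:
    """GTR+Gamma model used by scenarios unless overridden."""
    return SubstModel.gtr(
        (1.0, 2.0, 1.0, 1.0, 2.0, 1.0), (0.3, 0.2, 0.2, 0.3), gamma_alpha=1.0
    )


@dataclass
class Scenario:
    """A fully specified synthetic condition; the seed determines output."""

    kind: str = "clean"
    n_taxa: int = 12
    n_sites: int = 1000
    model: SubstModel = field(default_factory=default_scenario_model)
    seed: int = 0
    branch_mean: float = 0.1
    internal_floor: float = 0.05
    n_shrunk_edges: int = 2
    shrink_length: float = 5e-4
    breakpoint: float = 0.5
    pendant_multiplier: float = 10.0
    donors: tuple | None = None

    def __post_init__(self):
        if self.kind not in SCENARIO_KINDS:
            raise ValueError(f"unknown scenario kind {self.kind!r}")
        if self.n_taxa < 4:
            raise ValueError("need at least 4 taxa")


@dataclass
class ScenarioTruth:
    """Ground truth accompanying a generated alignment."""

    tree: UnrootedTree
    focal_taxon: str
    kind: str
    expect_focal_instability: bool
    shrunk_edges: list = field(default_factory=list)
    donors: tuple | None = None
    breakpoint_site: int | None = None


# ------------------------------------------------------------------ sampling
def sample_tree(
    n: int,
    rng: np.random.Generator,
    branch_mean: float = 0.1,
) -> UnrootedTree:
    """Uniform random binary topology on labels T01..Tnn via sequential
    addition (each new leaf attaches to a uniformly chosen edge), with
    i.i.d. exponential branch lengths."""
    if n < 4:
        raise ValueError("need at least 4 leaves")
    width = len(str(n))
    labels = [f"T{i + 1:0{width}d}" for i in range(n)]
    tree = UnrootedTree.star(labels[:3], [1.0, 1.0, 1.0])
    for label in labels[3:]:
        eids = tree.edge_ids()
        eid = eids[rng.integers(0, len(eids))]
        tree = tree.attach_leaf(eid, label, tree.edges[eid].length / 2.0, 1.0)
    for eid in tree.edge_ids():
        tree.edges[eid].length = float(rng.exponential(branch_mean))
    return tree


def simulate_alignment(
    tree: UnrootedTree,
    model: SubstModel,
    L: int,
    rng: np.random.Generator,
    return_node_states: bool = False,
):
    """Evolve ``L`` independent sites along the tree.

    The root state is drawn from the stationary frequencies and propagated
    edge-wise with the model's transition matrices; when gamma rate
    variation is enabled, each site draws its rate category once and keeps
    it on every branch."""
    if L < 1:
        raise ValueError("need at least one site")
    rates = model.category_rates
    cats = rng.integers(0, len(rates), L)
    root = next(n for n in tree.nodes() if not tree.is_leaf(n))
    states = {root: rng.choice(4, size=L, p=model.pi)}
    order = [(root, None)]
    stack = [(root, None)]
    while stack:
        node, parent = stack.pop()
        for nb in tree.neighbors(node):
            if nb != parent:
                order.append((nb, node))
                stack.append((nb, node))
    for node, parent in order:
        if parent is None:
            continue
        t = tree.edges[tree._adj[node][parent]].length
        P = np.stack([model.transition_matrix(t, r) for r in rates])  # (k,4,4)
        rows = P[cats, states[parent]]  # (L, 4)
        cum = np.cumsum(rows, axis=1)
        cum[:, -1] = 1.0
        u = rng.random(L)
        states[node] = (u[:, None] > cum).sum(axis=1).astype(np.int64)
    seqs = {
        lab: "".join(_STATES[s] for s in states[tree.leaf_node(lab)])
        for lab in tree.leaf_labels
    }
    aln = Alignment(tree.leaf_labels, [seqs[t] for t in tree.leaf_labels])
    if return_node_states:
        return aln, states, cats
    return aln


def _evolve_from(
    state: np.ndarray, cats: np.ndarray, t: float, model: SubstModel,
    rng: np.random.Generator,
) -> np.ndarray:
    rates = model.category_rates
    P = np.stack([model.transition_matrix(t, r) for r in rates])
    rows = P[cats, state]
    cum = np.cumsum(rows, axis=1)
    cum[:, -1] = 1.0
    u = rng.random(len(state))
    return (u[:, None] > cum).sum(axis=1).astype(np.int64)


# ------------------------------------------------------------------ scenarios
def _clean_tree(sc: Scenario, rng: np.random.Generator) -> UnrootedTree:
    tree = sample_tree(sc.n_taxa, rng, sc.branch_mean)
    for eid in tree.internal_edges():
        tree.edges[eid].length = max(tree.edges[eid].length, sc.internal_floor)
    return tree


def _contiguous_internal_edges(tree, start_eid, count):
    chosen = [start_eid]
    internal = set(tree.internal_edges())
    frontier = [start_eid]
    while len(chosen) < count and frontier:
        base = frontier.pop(0)
        nbrs = sorted(
            e for e in internal
            if e not in chosen and tree.edge_node_distance(base, e) == 1
        )
        for e in nbrs:
            if len(chosen) >= count:
                break
            chosen.append(e)
            frontier.append(e)
    return chosen


def make_scenario(sc: Scenario):
    """Generate (alignment, truth) for one scenario."""
    rng = np.random.default_rng(np.random.SeedSequence([sc.seed, 0x5CE0]))
    tree = _clean_tree(sc, rng)
    labels = tree.leaf_labels
    focal = labels[rng.integers(0, len(labels))]
    shrunk: list = []
    truth_kwargs: dict = {}

    if sc.kind == "low_support_region":
        internal = tree.internal_edges()
        start = internal[rng.integers(0, len(internal))]
        shrunk = _contiguous_internal_edges(tree, start, sc.n_shrunk_edges)
        for eid in shrunk:
            tree.edges[eid].length = sc.shrink_length
        # focal taxon: the leaf whose pendant edge is closest to the region
        focal = min(
            labels,
            key=lambda l: (tree.edge_node_distance(tree.pendant_edge(l), start), l),
        )
    elif sc.kind == "long_pendant":
        eid = tree.pendant_edge(focal)
        tree.edges[eid].length *= sc.pendant_multiplier

    aln, states, cats = simulate_alignment(tree, sc.model, sc.n_sites, rng,
                                           return_node_states=True)

    if sc.kind == "mosaic_taxon":
        if sc.donors is not None:
            d1, d2 = sc.donors
            if d1 == d2 or focal in (d1, d2):
                raise ValueError("mosaic donor clades must be disjoint from each "
                                 "other and from the focal taxon")
        else:
            # two donors far apart in the tree, neither the focal taxon
            cands = [l for l in labels if l != focal]
            pat = tree.leaf_distance_matrix()
            d1, d2 = max(
                ((a, b) for i, a in enumerate(cands) for b in cands[i + 1:]),
                key=lambda p: pat[p],
            )
        bp = int(round(sc.breakpoint * sc.n_sites))
        pend = max(tree.edges[tree.pendant_edge(focal)].length, 0.02)
        seq = np.empty(sc.n_sites, dtype=np.int64)
        for donor, sl in ((d1, slice(0, bp)), (d2, slice(bp, sc.n_sites))):
            anchor = tree.edges[tree.pendant_edge(donor)].other(tree.leaf_node(donor))
            seg = _evolve_from(states[anchor][sl], cats[sl], pend, sc.model, rng)
            seq[sl] = seg
        new_seq = "".join(_STATES[s] for s in seq)
        seqs = [new_seq if t == focal else aln.sequence(t) for t in aln.taxa]
        aln = Alignment(aln.taxa, seqs)
        truth_kwargs.update(donors=(d1, d2), breakpoint_site=bp)

    truth = ScenarioTruth(
        tree=tree,
        focal_taxon=focal,
        kind=sc.kind,
        expect_focal_instability=sc.kind != "clean",
        shrunk_edges=shrunk,
        **truth_kwargs,
    )
    return aln, truth


def write_scenario(directory, sc: Scenario) -> None:
    """Materialize one scenario as FASTA + true tree + manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    aln, truth = make_scenario(sc)
    aln.to_fasta(directory / "alignment.fasta")
    truth.tree.write(directory / "true_tree.nw")
    manifest = {
        "kind": sc.kind, "n_taxa": sc.n_taxa, "n_sites": sc.n_sites,
        "seed": sc.seed, "model": sc.model.spec_string(),
        "focal_taxon": truth.focal_taxon,
        "expect_focal_instability": truth.expect_focal_instability,
    }
    with open(directory / "scenario.txt", "w") as fh:
        for k, v in manifest.items():
            fh.write(f"{k}\t{v}\n")


# -------------------------------------------------------------- fixture suite
def fixture_suite(
    seed: int = 0,
    n_alignments: int = 40,
    n_taxa_range: tuple = (8, 16),
    n_sites_range: tuple = (500, 2000),
    bootstrap: int = 100,
    significance_B: int = 1000,
    model: SubstModel | None = None,
    backend: str = "nj",
) -> pd.DataFrame:
    """A labelled feature table from a mixture of scenarios pushed through
    the full leave-one-out pipeline.

    Half the alignments are clean (mostly stable taxa), the rest cycle
    through the engineered-instability kinds, so both stability classes are
    populated with the stable class in the majority.  One row per analyzed
    taxon; deterministic given the seed."""
    from .pipeline import RunConfig, run_leave_one_out

    model = model or default_scenario_model()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xF1D7]))
    unstable_kinds = ("low_support_region", "mosaic_taxon", "long_pendant")
    frames = []
    for i in range(n_alignments):
        kind = "clean" if i % 2 == 0 else unstable_kinds[(i // 2) % 3]
        sc = Scenario(
            kind=kind,
            n_taxa=int(rng.integers(n_taxa_range[0], n_taxa_range[1] + 1)),
            n_sites=int(rng.integers(n_sites_range[0], n_sites_range[1] + 1)),
            model=model,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        aln, truth = make_scenario(sc)
        cfg = RunConfig(
            model=model,
            backend=backend,
            bootstrap=bootstrap,
            significance_B=significance_B,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        stab, feats = run_leave_one_out(aln, cfg)
        merged = feats.merge(stab, on="taxon")
        merged.insert(0, "alignment", f"aln{i:03d}")
        merged["scenario_kind"] = kind
        merged["is_focal"] = merged["taxon"] == truth.focal_taxon
        frames.append(merged)
    table = pd.concat(frames, ignore_index=True)
    table["unstable"] = (table["tii"] != 0).astype(int)
    table["significant"] = table["significant_instability"].astype(int)
    return table
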