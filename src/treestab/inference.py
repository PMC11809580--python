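"""Tree inference backends for the leave-one-out loop.

Three backends: Neighbor Joining on model-corrected distances, an NNI
hill-climbing maximum-likelihood search (a desk-scale search in the spirit
of the large ML packages), and an adapter that reads externally inferred
trees from a directory.  Nonparametric (Felsenstein) bootstrap supports are
computed by re-inferring on site-resampled alignments with the same
backend.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np
from scipy.optimize import minimize_scalar

from .likelihood import LikelihoodEngine
from .seqmodels import (
    Alignment,
    DistanceMatrix,
    SubstModel,
    corrected_distance_matrix,
    counts_from_patterns,
    distances_from_counts,
    pair_pattern_table,
)
from .treecore import UnrootedTree

__all__ = [
    "InferenceConfig",
    "MLResult",
    "nj_tree",
    "ml_search",
    "optimize_branch_lengths",
    "bootstrap_supports",
    "infer_tree",
    "sanitize_label",
]

_BL_BOUNDS = (1e-8, 10.0)
_BL_TOL = 1e-6


@dataclass
class InferenceConfig:
    """How trees are inferred: backend, model, bootstrap replicates, seed.

    ``bootstrap = 0`` disables support computation.  For the ``external``
    backend, ``external_dir`` must contain ``full.nw`` plus one reduced tree
    per taxon named ``<sanitized taxon label>.nw``.
    """

    backend: str = "nj"
    model: SubstModel = field(default_factory=SubstModel.jc69)
    bootstrap: int = 0
    seed: int = 0
    external_dir: str | None = None

    def __post_init__(self):
        if self.backend not in ("nj", "ml", "external"):
            raise ValueError(f"unknown backend {self.backend!r}")
        if self.backend == "external" and self.external_dir is None:
            raise ValueError("external backend needs external_dir")


class MLResult(NamedTuple):
    tree: UnrootedTree
    log_likelihood: float


# ------------------------------------------------------------------------ NJ
def nj_tree(D: DistanceMatrix) -> UnrootedTree:
    """Saitou-Nei Neighbor Joining.

    Exact on additive matrices; negative intermediate branch lengths are
    clamped to 0.  Ties in the Q criterion break on the smallest index pair,
    so the result is deterministic.
    """
    n = len(D.taxa)
    if n < 3:
        raise ValueError("need at least 3 taxa")
    tree = UnrootedTree()
    nodes = [tree._new_node(t) for t in D.taxa]
    d = D.values.copy()
    active = list(range(n))
    while len(active) > 3:
        N = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (N - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        ai, aj = np.unravel_index(np.argmin(Q), Q.shape)  # row-major: smallest pair on ties
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]
        dij = sub[ai, aj]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2.0 * (N - 2))
        lj = dij - li
        u = tree._new_node()
        tree._add_edge(u, nodes[i], max(li, 0.0), None)
        tree._add_edge(u, nodes[j], max(lj, 0.0), None)
        rest = [k for k in active if k not in (i, j)]
        new_row = 0.5 * (d[i, rest] + d[j, rest] - dij)
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, rest] = new_row
        d[rest, -1] = new_row
        nodes.append(u)
        active = rest + [len(nodes) - 1]
    # final 3-way join by the three-point formulas
    i, j, k = active
    dij, dik, djk = d[i, j], d[i, k], d[j, k]
    c = tree._new_node()
    tree._add_edge(c, nodes[i], max(0.5 * (dij + dik - djk), 0.0), None)
    tree._add_edge(c, nodes[j], max(0.5 * (dij + djk - dik), 0.0), None)
    tree._add_edge(c, nodes[k], max(0.5 * (dik + djk - dij), 0.0), None)
    tree.validate()
    return tree


# -------------------------------------------------------- branch-length opt
def optimize_branch_lengths(
    tree: UnrootedTree,
    aln: Alignment,
    model: SubstModel,
    tol: float = 1e-3,
    max_sweeps: int = 20,
    engine: LikelihoodEngine | None = None,
) -> float:
    """Round-robin single-branch optimization (in place); returns final lnL.

    Each sweep caches directional partials once, then maximizes each branch
    with a bounded derivative-free optimizer on [1e-8, 10] to 1e-6;
    sweeping stops once a whole sweep gains less than ``tol`` log units.
    """
    engine = engine or LikelihoodEngine(tree, aln, model)
    last = engine.log_likelihood()
    if not np.isfinite(last):
        raise ValueError("non-finite starting log-likelihood")
    for _ in range(max_sweeps):
        for eid in tree.edge_ids():
            f = engine.edge_lnl_function(eid)
            res = minimize_scalar(
                lambda t: -f(t), bounds=_BL_BOUNDS, method="bounded",
                options={"xatol": _BL_TOL},
            )
            if -res.fun > f(tree.edges[eid].length):
                tree.edges[eid].length = float(res.x)
        engine.refresh()
        lnl = engine.log_likelihood()
        if not np.isfinite(lnl):
            raise ValueError("non-finite log-likelihood during branch optimization")
        if lnl - last < tol:
            last = max(lnl, last)
            break
        last = lnl
    return last


# ------------------------------------------------------------------ ML + NNI
def _best_nni_move(tree, engine, current_lnl):
    """Scan all internal edges for the best strictly improving NNI move.

    Candidate topologies are scored with cached subtree messages and the
    central branch length re-optimized, all other lengths fixed — a valid
    lower bound on the candidate's optimized likelihood.
    """
    pi = engine.model.pi
    k = engine.k
    best = (None, current_lnl)
    for eid in tree.internal_edges():
        e = tree.edges[eid]
        u, v = e.u, e.v
        a, b = sorted(n for n in tree._adj[u] if n != v)
        c, d = sorted(n for n in tree._adj[v] if n != u)
        M = {n: engine._msgs[(n, u)] for n in (a, b)}
        M.update({n: engine._msgs[(n, v)] for n in (c, d)})
        # which=0 swaps b<->c giving sides {a,c}|{b,d}; which=1 swaps b<->d
        for which, (side_u, side_v) in enumerate((((a, c), (b, d)), ((a, d), (c, b)))):
            A = M[side_u[0]].arr * M[side_u[1]].arr
            B = M[side_v[0]].arr * M[side_v[1]].arr
            logsc = sum(M[n].logsc for n in side_u + side_v)

            def f(t):
                P = engine.model.transition_matrices(max(t, 1e-9))
                MB = np.einsum("kab,klb->kla", P, B)
                lik = np.einsum("kla,a,kla->l", A, pi, MB) / k
                return float(np.dot(engine.weights,
                                    np.log(np.maximum(lik, 1e-300)) + logsc))

            res = minimize_scalar(lambda t: -f(t), bounds=_BL_BOUNDS,
                                  method="bounded", options={"xatol": _BL_TOL})
            cand = -res.fun
            if cand > best[1] + 1e-9:
                best = ((eid, which, float(res.x)), cand)
    return best


def ml_search(
    aln: Alignment,
    model: SubstModel,
    start: UnrootedTree | None = None,
    seed: int = 0,
    tol: float = 1e-6,
    max_rounds: int = 50,
) -> MLResult:
    """Hill-climbing ML tree search: branch-length optimization alternating
    with NNI sweeps, accepting only strictly improving moves.

    The default start tree is Neighbor Joining on model-corrected distances.
    The search is deterministic (the seed is accepted for interface
    uniformity; no stochastic choices are made).
    """
    if start is None:
        start = nj_tree(corrected_distance_matrix(aln, model))
    tree = start.copy()
    engine = LikelihoodEngine(tree, aln, model)
    lnl = optimize_branch_lengths(tree, aln, model, tol=tol, engine=engine)
    for _ in range(max_rounds):
        move, cand_lnl = _best_nni_move(tree, engine, lnl)
        if move is None:
            break
        eid, which, t_opt = move
        tree = tree.nni_neighbors(eid)[which]
        tree.edges[eid].length = t_opt
        engine = LikelihoodEngine(tree, aln, model)
        lnl = optimize_branch_lengths(tree, aln, model, tol=tol, engine=engine)
        if lnl < cand_lnl - 1e-6:  # pragma: no cover - safety net
            lnl = max(lnl, cand_lnl)
    return MLResult(tree, lnl)


# -------------------------------------------------------------- bootstrapping
def _infer_backend(aln: Alignment, cfg: InferenceConfig) -> UnrootedTree:
    if cfg.backend == "nj":
        return nj_tree(corrected_distance_matrix(aln, cfg.model))
    if cfg.backend == "ml":
        return ml_search(aln, cfg.model, seed=cfg.seed).tree
    raise ValueError("bootstrap/inference with external backend is not defined")


def bootstrap_supports(
    aln: Alignment, tree: UnrootedTree, cfg: InferenceConfig
) -> UnrootedTree:
    """Annotate internal edges with standard nonparametric bootstrap support.

    ``cfg.bootstrap`` site-resampled alignments are each re-inferred with
    the configured backend; each internal edge of ``tree`` receives the
    percentage of replicates whose inferred tree contains its split.
    """
    B = cfg.bootstrap
    if B < 1:
        raise ValueError("bootstrap replicates must be >= 1")
    counts = {eid: 0 for eid in tree.internal_edges()}
    splits = tree.edge_splits()
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0xB007]))
    L = aln.n_sites
    if cfg.backend == "nj":
        # fast path: a replicate is a multinomial site-weight vector applied
        # to precomputed per-pair site patterns; distances for all replicates
        # are corrected in one vectorized batch
        pairs, patterns = pair_pattern_table(aln.code_matrix())
        W = rng.multinomial(L, np.full(L, 1.0 / L), size=B)
        rep_counts = np.stack([counts_from_patterns(patterns, W[b]) for b in range(B)])
        flat = rep_counts.reshape(-1, 4, 4)
        dvec = distances_from_counts(flat, cfg.model, on_empty="cap")
        dvec = dvec.reshape(B, len(pairs))
        n = aln.n_taxa
        for b in range(B):
            D = np.zeros((n, n))
            for (i, j), val in zip(pairs, dvec[b]):
                D[i, j] = D[j, i] = val
            rep_splits = nj_tree(DistanceMatrix(aln.taxa, D)).splits()
            for eid, s in splits.items():
                if s in rep_splits:
                    counts[eid] += 1
    else:
        for _ in range(B):
            idx = rng.integers(0, L, L)
            rep = aln.resample_sites(idx)
            rep_splits = _infer_backend(rep, cfg).splits()
            for eid, s in splits.items():
                if s in rep_splits:
                    counts[eid] += 1
    out = tree.copy()
    for eid, c in counts.items():
        out.edges[eid].support = 100.0 * c / B
    return out


# ------------------------------------------------------------------ external
def sanitize_label(label: str) -> str:
    """File-name-safe form of a taxon label."""
    return re.sub(r"[^A-Za-z0-9_.-]", "_", label)


def _external_tree(cfg: InferenceConfig, exclude_taxon: str | None) -> UnrootedTree:
    base = Path(cfg.external_dir)
    name = "full.nw" if exclude_taxon is None else f"{sanitize_label(exclude_taxon)}.nw"
    path = base / name
    if not path.exists():
        raise FileNotFoundError(f"external tree {path} not found")
    return UnrootedTree.from_newick(path.read_text())


def infer_tree(
    aln: Alignment, cfg: InferenceConfig, exclude_taxon: str | None = None
) -> UnrootedTree:
    """Infer a tree for the alignment (which must already exclude the taxon
    when ``exclude_taxon`` is set; the argument only routes the external
    backend to the right file)."""
    if cfg.backend == "external":
        return _external_tree(cfg, exclude_taxon)
    return _infer_backend(aln, cfg)
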