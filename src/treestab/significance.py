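"""Topology tests on per-site log-likelihoods.

Implements RELL resampling (bootstrap of site log-likelihoods without
re-optimization), the Shimodaira-Hasegawa (SH) test, and the approximately
unbiased (AU) test via multiscale bootstrap with a weighted probit fit.
The pipeline applies the two-tree case — pruned tree versus inferred tree —
whenever their topologies differ; "equally good or better" ties in
replicate maxima are awarded to the tree under test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .inference import optimize_branch_lengths
from .seqmodels import Alignment, SubstModel
from .likelihood import LikelihoodEngine
from .treecore import UnrootedTree, rf_distance

logger = logging.getLogger(__name__)

__all__ = [
    "SiteLnLTable",
    "rell_totals",
    "sh_test",
    "au_test",
    "assess_significance",
    "DEFAULT_AU_SCALES",
]

DEFAULT_AU_SCALES = tuple(round(0.5 + 0.1 * i, 1) for i in range(10))  # 0.5 .. 1.4


@dataclass
class SiteLnLTable:
    """Per-site log-likelihoods for a set of trees (trees x sites)."""

    tree_ids: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != len(self.tree_ids):
            raise ValueError("values must be trees x sites")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite site log-likelihoods")

    @property
    def n_sites(self) -> int:
        return self.values.shape[1]

    def export_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for tid, row in zip(self.tree_ids, self.values):
                fh.write(tid + "\t" + "\t".join(format(v, ".10g") for v in row) + "\n")


def rell_totals(
    table: SiteLnLTable, B: int, scale: float = 1.0, seed: int = 0
) -> np.ndarray:
    """RELL replicate totals: (trees x B) weighted sums of site lnLs under
    multinomial site weights of resample size round(scale * sites)."""
    if scale <= 0:
        raise ValueError("scale must be positive")
    if B < 1:
        raise ValueError("need at least one replicate")
    L = table.n_sites
    m = max(int(round(scale * L)), 1)
    rng = np.random.default_rng(np.random.SeedSequence([seed, int(round(scale * 1000))]))
    # multinomial site weights via index resampling + bincount (fast for
    # large site counts)
    idx = rng.integers(0, L, size=(B, m))
    flat = idx + (np.arange(B, dtype=np.int64)[:, None] * L)
    W = np.bincount(flat.ravel(), minlength=B * L).reshape(B, L)
    return table.values @ W.T.astype(float)  # (trees, B)


def sh_test(table: SiteLnLTable, B: int = 1000, seed: int = 0) -> np.ndarray:
    """Shimodaira-Hasegawa test p-value for each tree.

    Centered RELL totals form the null distribution of the difference to
    the best tree; ties count in favour of the tested tree (p = 1 for
    identical rows)."""
    if len(table.tree_ids) < 2:
        raise ValueError("need at least 2 trees")
    if B < 100:
        logger.warning("SH test with B=%d replicates; p-values will be unstable", B)
    obs = table.values.sum(axis=1)
    delta = obs.max() - obs  # observed lnL difference to the best tree
    totals = rell_totals(table, B, 1.0, seed)
    centered = totals - totals.mean(axis=1, keepdims=True)
    null_max = centered.max(axis=0)  # (B,)
    null_delta = null_max[None, :] - centered  # (trees, B)
    return (null_delta >= delta[:, None] - 1e-12).mean(axis=1)


def au_test(
    table: SiteLnLTable,
    scales=DEFAULT_AU_SCALES,
    B: int = 1000,
    seed: int = 0,
) -> np.ndarray:
    """Approximately unbiased test p-value for each tree.

    Multiscale bootstrap: at each resample scale r the bootstrap proportion
    of replicates in which the tree attains the maximum total is probit-
    transformed and fit as z(r) = d*sqrt(r) + c/sqrt(r) by weighted least
    squares (binomial-variance weights); p = 1 - Phi(d - c).  Proportions
    degenerate at every scale map to p = 0 or 1; trees with fewer than two
    informative scales fall back to their SH p-value with a warning."""
    scales = list(scales)
    if len(scales) < 2:
        raise ValueError("need at least 2 scales")
    T = len(table.tree_ids)
    bp = np.empty((T, len(scales)))
    for si, r in enumerate(scales):
        totals = rell_totals(table, B, r, seed)
        best_other = np.empty_like(totals)
        overall = totals.max(axis=0)
        for i in range(T):
            others = np.delete(totals, i, axis=0)
            best_other[i] = others.max(axis=0) if len(others) else -np.inf
        # tie goes to the tree under test ("equally good or better")
        bp[:, si] = (totals >= best_other - 1e-12).mean(axis=1)
    pvals = np.empty(T)
    sh_fallback = None
    for i in range(T):
        row = bp[i]
        if np.all(row >= 1.0):
            pvals[i] = 1.0
            continue
        if np.all(row <= 0.0):
            pvals[i] = 0.0
            continue
        ok = (row > 0.0) & (row < 1.0)
        if ok.sum() < 2:
            if sh_fallback is None:
                sh_fallback = sh_test(table, B, seed)
            logger.warning(
                "AU fit degenerate for tree %s; falling back to SH p-value",
                table.tree_ids[i],
            )
            pvals[i] = sh_fallback[i]
            continue
        r = np.asarray(scales)[ok]
        p = row[ok]
        z = norm.ppf(1.0 - p)
        X = np.column_stack([np.sqrt(r), 1.0 / np.sqrt(r)])
        w = B * norm.pdf(z) ** 2 / (p * (1.0 - p))
        WX = X * w[:, None]
        beta = np.linalg.solve(X.T @ WX, WX.T @ z)
        d_hat, c_hat = beta
        pvals[i] = float(norm.sf(d_hat - c_hat))
    return pvals


def site_lnl_table(
    trees: dict[str, UnrootedTree],
    aln: Alignment,
    model: SubstModel,
    optimize: bool = True,
    opt_tol: float = 1e-2,
) -> SiteLnLTable:
    """Build a SiteLnLTable, optionally optimizing each tree's branch
    lengths under the model first (the trees are copied)."""
    ids, rows = [], []
    for tid, tree in trees.items():
        t = tree.copy()
        engine = LikelihoodEngine(t, aln, model)
        if optimize:
            optimize_branch_lengths(t, aln, model, tol=opt_tol, engine=engine)
        rows.append(engine.site_log_likelihoods())
        ids.append(tid)
    return SiteLnLTable(ids, np.vstack(rows))


def assess_significance(
    pruned: UnrootedTree,
    inferred: UnrootedTree,
    aln: Alignment,
    model: SubstModel,
    B: int = 1000,
    scales=DEFAULT_AU_SCALES,
    seed: int = 0,
) -> tuple[float, float]:
    """AU and SH p-values for the pruned tree against the inferred tree.

    Branch lengths of both trees are re-optimized under the model before
    the per-site log-likelihoods are tabulated.  Raises for topologically
    identical trees: the pipeline only tests unstable cases (TII != 0)."""
    if rf_distance(pruned, inferred) == 0:
        raise ValueError("trees have identical topologies; significance test undefined")
    table = site_lnl_table({"pruned": pruned, "inferred": inferred}, aln, model)
    au = au_test(table, scales=scales, B=B, seed=seed)
    sh = sh_test(table, B=B, seed=seed)
    return float(au[0]), float(sh[0])
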