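"""Alignments, substitution models, and model-corrected pairwise distances.

DNA alignments are read and written as FASTA (via Biopython).  Substitution
models are time-reversible (JC69 / K2P / HKY / GTR) with optional discrete-
gamma rate heterogeneity; the model provides the transition matrices used by
the pruning likelihood, the simulator, and the corrected distances.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

logger = logging.getLogger(__name__)

__all__ = [
    "Alignment",
    "SubstModel",
    "DistanceMatrix",
    "corrected_distance_matrix",
    "distances_from_counts",
    "pair_pattern_table",
    "counts_from_patterns",
    "parse_model_string",
    "site_log_likelihoods",
]

# IUPAC nucleotide codes -> compatible states (A, C, G, T); gaps and N are
# treated as fully missing (all states compatible).
_STATES = "ACGT"
_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT", "-": "ACGT", "?": "ACGT", ".": "ACGT", "X": "ACGT",
}
# char -> partial-likelihood row (4,)
_PARTIAL = {c: np.array([1.0 if s in comp else 0.0 for s in _STATES])
            for c, comp in _IUPAC.items()}
# char -> pure state index or -1 (used for pairwise-deletion distances)
_PURE = {c: (_STATES.index(comp) if len(comp) == 1 else -1)
         for c, comp in _IUPAC.items()}


class Alignment:
    """Taxa-by-sites DNA character matrix.

    Sequences keep their original byte content (case included); character
    interpretation for likelihoods and distances is case-insensitive.
    """

    def __init__(self, taxa: list[str], sequences: list[str]):
        if len(taxa) != len(sequences):
            raise ValueError("taxa and sequences differ in length")
        if len(set(taxa)) != len(taxa):
            raise ValueError("duplicate taxon names")
        if not sequences or not sequences[0]:
            raise ValueError("alignment needs at least one site")
        L = len(sequences[0])
        for t, s in zip(taxa, sequences):
            if len(s) != L:
                raise ValueError(f"sequence {t!r} has length {len(s)}, expected {L}")
            bad = set(s.upper()) - set(_IUPAC)
            if bad:
                raise ValueError(f"sequence {t!r} contains invalid characters {sorted(bad)}")
        self.taxa = list(taxa)
        self.sequences = list(sequences)
        self._index = {t: i for i, t in enumerate(taxa)}

    # ---------------------------------------------------------------- basics
    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_sites(self) -> int:
        return len(self.sequences[0])

    def sequence(self, taxon: str) -> str:
        return self.sequences[self._index[taxon]]

    def __contains__(self, taxon: str) -> bool:
        return taxon in self._index

    def drop_taxon(self, taxon: str) -> "Alignment":
        """The alignment with one sequence removed (site count unchanged)."""
        if taxon not in self._index:
            raise KeyError(f"no taxon {taxon!r}")
        keep = [i for i, t in enumerate(self.taxa) if t != taxon]
        return Alignment([self.taxa[i] for i in keep], [self.sequences[i] for i in keep])

    def subset(self, taxa: list[str]) -> "Alignment":
        return Alignment(list(taxa), [self.sequence(t) for t in taxa])

    def resample_sites(self, site_indices: np.ndarray) -> "Alignment":
        """Column-resampled alignment (bootstrap replicate)."""
        chars = np.array([list(s) for s in self.sequences])
        sub = chars[:, site_indices]
        return Alignment(self.taxa, ["".join(row) for row in sub])

    # --------------------------------------------------------------- numeric
    def code_matrix(self) -> np.ndarray:
        """(n_taxa, n_sites) int8 of pure state indices; -1 = gap/ambiguous."""
        out = np.empty((self.n_taxa, self.n_sites), dtype=np.int8)
        for i, s in enumerate(self.sequences):
            out[i] = [_PURE[c] for c in s.upper()]
        return out

    def tip_partials(self, taxon: str) -> np.ndarray:
        """(n_sites, 4) partial-likelihood rows for one sequence."""
        return np.array([_PARTIAL[c] for c in self.sequence(taxon).upper()])

    # ------------------------------------------------------------------- I/O
    @classmethod
    def from_fasta(cls, path) -> "Alignment":
        records = list(SeqIO.parse(str(path), "fasta"))
        if not records:
            raise ValueError(f"no sequences in {path}")
        return cls([r.id for r in records], [str(r.seq) for r in records])

    def to_fasta(self, path) -> None:
        records = [SeqRecord(Seq(s), id=t, description="")
                   for t, s in zip(self.taxa, self.sequences)]
        SeqIO.write(records, str(path), "fasta")

    @classmethod
    def from_phylip(cls, path) -> "Alignment":
        """Relaxed sequential PHYLIP reader (name whitespace sequence)."""
        with open(path) as fh:
            header = fh.readline().split()
            n, L = int(header[0]), int(header[1])
            taxa, seqs = [], []
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                name, seq = line.split(None, 1)
                taxa.append(name)
                seqs.append(seq.replace(" ", ""))
        if len(taxa) != n or any(len(s) != L for s in seqs):
            raise ValueError("PHYLIP header does not match content")
        return cls(taxa, seqs)


# --------------------------------------------------------------------- model
@dataclass
class SubstModel:
    """Time-reversible nucleotide substitution model.

    ``rates`` are the six exchangeabilities in order (AC, AG, AT, CG, CT,
    GT); ``freqs`` the stationary base frequencies (A, C, G, T).  The rate
    matrix is scaled so the expected substitution rate at stationarity is 1,
    making branch lengths expected substitutions per site.  Discrete-gamma
    rate variation uses ``gamma_k`` equal-probability categories whose rates
    are the category means (mean 1 overall).
    """

    family: str = "JC69"
    rates: tuple = (1.0, 1.0, 1.0, 1.0, 1.0, 1.0)
    freqs: tuple = (0.25, 0.25, 0.25, 0.25)
    gamma_alpha: float | None = None
    gamma_k: int = 4

    def __post_init__(self):
        f = np.asarray(self.freqs, dtype=float)
        if np.any(f <= 0) or abs(f.sum() - 1.0) > 1e-12:
            raise ValueError("frequencies must be positive and sum to 1")
        if len(self.rates) != 6 or any(r <= 0 for r in self.rates):
            raise ValueError("need 6 positive exchangeability rates")
        if self.gamma_alpha is not None and self.gamma_alpha <= 0:
            raise ValueError("gamma shape must be positive")
        self._build()

    # constructors ----------------------------------------------------------
    @classmethod
    def jc69(cls, gamma_alpha=None, gamma_k=4):
        return cls("JC69", gamma_alpha=gamma_alpha, gamma_k=gamma_k)

    @classmethod
    def k2p(cls, kappa: float = 2.0, gamma_alpha=None, gamma_k=4):
        return cls("K2P", (1.0, kappa, 1.0, 1.0, kappa, 1.0),
                   gamma_alpha=gamma_alpha, gamma_k=gamma_k)

    @classmethod
    def hky(cls, kappa: float, freqs, gamma_alpha=None, gamma_k=4):
        return cls("HKY", (1.0, kappa, 1.0, 1.0, kappa, 1.0), tuple(freqs),
                   gamma_alpha=gamma_alpha, gamma_k=gamma_k)

    @classmethod
    def gtr(cls, rates, freqs, gamma_alpha=None, gamma_k=4):
        return cls("GTR", tuple(rates), tuple(freqs),
                   gamma_alpha=gamma_alpha, gamma_k=gamma_k)

    # internals -------------------------------------------------------------
    def _build(self):
        pi = np.asarray(self.freqs, dtype=float)
        ac, ag, at, cg, ct, gt = self.rates
        # state order (A, C, G, T)
        S = np.array([
            [0.0, ac, ag, at],
            [ac, 0.0, cg, ct],
            [ag, cg, 0.0, gt],
            [at, ct, gt, 0.0],
        ])
        Q = S * pi[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mu = -np.sum(pi * np.diag(Q))
        Q /= mu
        self._Q = Q
        d = np.sqrt(pi)
        B = (Q * d[:, None]) / d[None, :]
        B = (B + B.T) / 2.0  # symmetric up to rounding
        lam, U = np.linalg.eigh(B)
        self._lam = lam
        self._left = U.T * d[None, :]          # U^T D^{1/2}
        self._right = U / d[:, None]           # D^{-1/2} U
        self._pi = pi
        self._cat_rates = self._compute_category_rates()

    @property
    def pi(self) -> np.ndarray:
        return self._pi

    @property
    def category_rates(self) -> np.ndarray:
        """Discrete-gamma category rates (mean method, equal-probability
        bins); ``[1.0]`` when rate variation is disabled."""
        return self._cat_rates

    def _compute_category_rates(self) -> np.ndarray:
        if self.gamma_alpha is None:
            return np.array([1.0])
        a, k = self.gamma_alpha, self.gamma_k
        # boundaries of equal-probability bins of Gamma(a, scale=1/a)
        qs = gamma_dist.ppf(np.arange(1, k) / k, a, scale=1.0 / a)
        bounds = np.concatenate([[0.0], qs, [np.inf]])
        # mean within each bin: k * [I(a+1, b*a) - I(a+1, lo*a)]
        upper = gammainc(a + 1.0, bounds[1:] * a)
        lower = gammainc(a + 1.0, bounds[:-1] * a)
        rates = k * (upper - lower)
        return rates / rates.mean()

    def transition_matrix(self, t: float, rate: float = 1.0) -> np.ndarray:
        e = np.exp(self._lam * (t * rate))
        P = (self._right * e[None, :]) @ self._left
        return np.clip(P, 0.0, None)

    def transition_matrices(self, t: float) -> np.ndarray:
        """(k, 4, 4) transition matrices, one per rate category."""
        e = self.category_exp(t)  # (k, 4)
        P = np.einsum("ab,kb,bc->kac", self._right, e, self._left)
        return np.clip(P, 0.0, None)

    def category_exp(self, t: float) -> np.ndarray:
        """exp(lambda * t * r) per rate category: the (k, 4) spectral core
        of the transition matrices (see the likelihood engine's hot paths)."""
        return np.exp(self._lam[None, :] * (t * self.category_rates[:, None]))

    def spec_string(self) -> str:
        s = self.family
        if self.family in ("K2P", "HKY"):
            s += "{%g}" % self.rates[1]
        elif self.family == "GTR":
            s += "{%s}" % ",".join("%g" % r for r in self.rates)
        if self.family in ("HKY", "GTR"):
            s += "+F{%s}" % ",".join("%g" % f for f in self.freqs)
        if self.gamma_alpha is not None:
            s += "+G{%g}" % self.gamma_alpha
        return s


def parse_model_string(spec: str) -> SubstModel:
    """Parse a model spec like ``GTR{1,2,1,1,2,1}+F{.3,.2,.2,.3}+G{0.5}``.

    Families JC/JC69, K2P{kappa}, HKY{kappa}+F{...}, GTR{6 rates}+F{...};
    optional ``+G{alpha}`` discrete-gamma term.  Case-insensitive.
    """
    parts = spec.strip().split("+")
    head = parts[0].strip()
    m = re.fullmatch(r"([A-Za-z0-9]+)(?:\{([^}]*)\})?", head)
    if not m:
        raise ValueError(f"cannot parse model spec {spec!r}")
    fam = m.group(1).upper()
    nums = [float(x) for x in m.group(2).split(",")] if m.group(2) else []
    freqs = (0.25, 0.25, 0.25, 0.25)
    alpha = None
    for part in parts[1:]:
        part = part.strip()
        pm = re.fullmatch(r"([FfGg])\{([^}]*)\}", part)
        if not pm:
            raise ValueError(f"cannot parse model term {part!r}")
        vals = [float(x) for x in pm.group(2).split(",")]
        if pm.group(1).upper() == "F":
            if len(vals) != 4:
                raise ValueError("+F needs 4 frequencies")
            freqs = tuple(vals)
        else:
            alpha = vals[0]
    if fam in ("JC", "JC69"):
        return SubstModel.jc69(gamma_alpha=alpha)
    if fam == "K2P":
        return SubstModel.k2p(nums[0] if nums else 2.0, gamma_alpha=alpha)
    if fam == "HKY":
        return SubstModel.hky(nums[0] if nums else 2.0, freqs, gamma_alpha=alpha)
    if fam == "GTR":
        if len(nums) != 6:
            raise ValueError("GTR needs 6 exchangeability rates")
        return SubstModel.gtr(nums, freqs, gamma_alpha=alpha)
    raise ValueError(f"unknown model family {fam!r}")


# ----------------------------------------------------------------- distances
class DistanceMatrix:
    """Symmetric nonnegative taxon-by-taxon distance matrix."""

    def __init__(self, taxa: list[str], values: np.ndarray):
        values = np.asarray(values, dtype=float)
        if values.shape != (len(taxa), len(taxa)):
            raise ValueError("shape mismatch")
        if not np.all(np.isfinite(values)):
            raise ValueError("non-finite distances")
        if np.max(np.abs(values - values.T)) > 1e-12:
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.abs(np.diag(values)) > 1e-12):
            raise ValueError("nonzero diagonal")
        self.taxa = list(taxa)
        self.values = (values + values.T) / 2.0
        self._index = {t: i for i, t in enumerate(taxa)}

    def __getitem__(self, pair) -> float:
        a, b = pair
        return self.values[self._index[a], self._index[b]]

    def drop(self, taxon: str) -> "DistanceMatrix":
        keep = [i for i, t in enumerate(self.taxa) if t != taxon]
        return DistanceMatrix([self.taxa[i] for i in keep],
                              self.values[np.ix_(keep, keep)])


def pair_pattern_table(codes: np.ndarray):
    """For every taxon pair (i < j): per-site pattern ids a*4+b, or -1 where
    either character is a gap/ambiguity (pairwise deletion).

    Returns (pair index list, (n_pairs, n_sites) int32 array).  This is the
    substrate for fast repeated distance computation (bootstrap)."""
    n = codes.shape[0]
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    pat = np.empty((len(pairs), codes.shape[1]), dtype=np.int32)
    for p, (i, j) in enumerate(pairs):
        a, b = codes[i].astype(np.int32), codes[j].astype(np.int32)
        row = a * 4 + b
        row[(a < 0) | (b < 0)] = -1
        pat[p] = row
    return pairs, pat


def counts_from_patterns(patterns: np.ndarray, weights: np.ndarray | None = None) -> np.ndarray:
    """(n_pairs, 4, 4) pattern counts, optionally under per-site weights
    (a bootstrap replicate is a multinomial weight vector)."""
    n_pairs, L = patterns.shape
    offset = (np.arange(n_pairs, dtype=np.int64)[:, None] * 16)
    flat = (patterns.astype(np.int64) + offset).ravel()
    valid = patterns.ravel() >= 0
    if weights is None:
        w = None
    else:
        w = np.broadcast_to(np.asarray(weights, dtype=float)[None, :], patterns.shape).ravel()[valid]
    counts = np.bincount(flat[valid], weights=w, minlength=n_pairs * 16)
    return counts.reshape(n_pairs, 4, 4)


def _vectorized_ml_distances(counts: np.ndarray, model: SubstModel, cap: float) -> np.ndarray:
    """Pairwise ML distances under the model for a batch of count matrices,
    by golden-section search on [1e-9, cap] (vectorized over pairs)."""
    lam, R, Lm = model._lam, model._right, model._left
    rates = model.category_rates
    pi = model.pi

    def negll(t):
        e = np.exp(lam[None, None, :] * (t[:, None, None] * rates[None, :, None]))
        P = np.einsum("ab,pkb,bc->pkac", R, e, Lm)
        M = (pi[None, None, :, None] * P).mean(axis=1)
        return -(counts * np.log(np.maximum(M, 1e-300))).sum(axis=(1, 2))

    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    a = np.full(counts.shape[0], 1e-9)
    b = np.full(counts.shape[0], cap)
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc, fd = negll(c), negll(d)
    for _ in range(38):  # interval shrinks to ~cap * 0.618^38 ~ 1e-7
        left = fc < fd  # minimum bracketed in [a, d]
        b = np.where(left, d, b)
        a = np.where(left, a, c)
        c = b - invphi * (b - a)
        d = a + invphi * (b - a)
        # one retained interior point per pair (new d = old c on the left
        # branch, new c = old d on the right branch); evaluate the other
        f_eval = negll(np.where(left, c, d))
        fc, fd = np.where(left, f_eval, fd), np.where(left, fc, f_eval)
    return (a + b) / 2.0


def distances_from_counts(
    counts: np.ndarray,
    model: SubstModel,
    cap: float = 10.0,
    names: list | None = None,
    on_empty: str = "error",
) -> np.ndarray:
    """Model-corrected distances for a batch of 4x4 pair count matrices.

    JC69 and K2P (without gamma) use their closed forms; JC69+G the gamma-
    corrected closed form; other families the pairwise ML distance under
    the model.  Saturated pairs cap at ``cap`` with a logged warning; pairs
    with no comparable sites raise, or cap when ``on_empty='cap'``."""
    counts = np.asarray(counts, dtype=float)
    totals = counts.sum(axis=(1, 2))
    empty = totals == 0
    if empty.any():
        if on_empty == "error":
            which = names[int(np.argmax(empty))] if names else int(np.argmax(empty))
            raise ValueError(f"pair {which} shares no comparable sites")
        logger.warning("%d pairs share no comparable sites; capped", int(empty.sum()))
        totals = np.where(empty, 1.0, totals)

    def _warn_saturated(bad, label):
        if bad.any():
            logger.warning("%s correction undefined for %d pairs; capped at %g",
                           label, int(bad.sum()), cap)

    if model.family == "JC69":
        diag = counts[:, [0, 1, 2, 3], [0, 1, 2, 3]].sum(axis=1)
        p = (totals - diag) / totals
        arg = 1.0 - 4.0 * p / 3.0
        bad = arg <= 0
        _warn_saturated(bad, "JC69")
        arg = np.where(bad, 1.0, arg)
        if model.gamma_alpha is None:
            d = -0.75 * np.log(arg)
        else:
            a = model.gamma_alpha
            d = 0.75 * a * (arg ** (-1.0 / a) - 1.0)
        d = np.where(bad, cap, d)
    elif model.family == "K2P" and model.gamma_alpha is None:
        ts = (counts[:, 0, 2] + counts[:, 2, 0] + counts[:, 1, 3] + counts[:, 3, 1]) / totals
        diag = counts[:, [0, 1, 2, 3], [0, 1, 2, 3]].sum(axis=1)
        tv = (totals - diag) / totals - ts
        a1 = 1.0 - 2.0 * ts - tv
        a2 = 1.0 - 2.0 * tv
        bad = (a1 <= 0) | (a2 <= 0)
        _warn_saturated(bad, "K2P")
        a1 = np.where(bad, 1.0, a1)
        a2 = np.where(bad, 1.0, a2)
        d = np.where(bad, cap, -0.5 * np.log(a1) - 0.25 * np.log(a2))
    else:
        d = _vectorized_ml_distances(counts, model, cap)
    d = np.where(empty, cap, d)
    return np.minimum(d, cap)


def corrected_distance_matrix(
    aln: Alignment, model: SubstModel, cap: float = 10.0
) -> DistanceMatrix:
    """Model-corrected pairwise distances with pairwise deletion.

    See :func:`distances_from_counts` for the per-family corrections."""
    if aln.n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    pairs, patterns = pair_pattern_table(aln.code_matrix())
    counts = counts_from_patterns(patterns)
    names = [(aln.taxa[i], aln.taxa[j]) for i, j in pairs]
    d = distances_from_counts(counts, model, cap, names=names)
    n = aln.n_taxa
    D = np.zeros((n, n))
    for (i, j), val in zip(pairs, d):
        D[i, j] = D[j, i] = val
    return DistanceMatrix(aln.taxa, D)


def site_log_likelihoods(tree, aln: Alignment, model: SubstModel) -> np.ndarray:
    """Per-site log-likelihoods of a tree by the pruning algorithm."""
    from .likelihood import LikelihoodEngine

    return LikelihoodEngine(tree, aln, model).site_log_likelihoods()
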