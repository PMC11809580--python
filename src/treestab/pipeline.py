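"""Leave-one-out stability analysis: orchestration and outputs.

For an alignment A, infer the full tree T*; then for each taxon s build
A-s, re-infer Ts* (with bootstrap supports), prune s from T* to get Ts, and
record the stability measures (TII, disruption radius, unstable-edge
distance to low support, AU/SH p-values for unstable cases) plus the
feature row computed only from Ts*, the placement of s on it, Ts+ and the
alignment.  Results go to ``stability.csv`` / ``features.csv`` and, when an
output directory is given, per-taxon trees and jplace placements.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .features import FEATURE_COLUMNS, assemble_features
from .inference import InferenceConfig, bootstrap_supports, infer_tree, sanitize_label
from .placement import best_placement_tree, jplace_string, placement_candidates
from .inference import nj_tree
from .seqmodels import Alignment, SubstModel, corrected_distance_matrix, parse_model_string
from .significance import DEFAULT_AU_SCALES, assess_significance
from .stability import StabilityRecord, disruption_radius, tii, unstable_to_low_support_distance

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "dedupe_alignment", "run_leave_one_out"]

STABILITY_COLUMNS = [
    "taxon", "tii", "tii_norm", "disruption_radius",
    "mean_unstable_low_support_dist", "au_p", "sh_p",
    "stable", "significant_instability", "failed",
]


@dataclass
class RunConfig:
    """Everything a leave-one-out run depends on.

    ``model`` may be a SubstModel or a spec string such as
    ``"GTR{1,2,1,1,2,1}+F{.3,.2,.2,.3}+G{0.5}"``; it is fixed once and
    reused for every reduced inference.  The seed propagates to every
    stochastic stage (bootstrap and RELL resampling)."""

    model: SubstModel | str = field(default_factory=SubstModel.jc69)
    backend: str = "nj"
    bootstrap: int = 100
    seed: int = 0
    compute_significance: bool = True
    significance_B: int = 1000
    au_scales: tuple = DEFAULT_AU_SCALES
    external_dir: str | None = None
    pythia_difficulty: float | None = None
    outdir: str | None = None

    def resolved_model(self) -> SubstModel:
        if isinstance(self.model, str):
            return parse_model_string(self.model)
        return self.model

    def content_hash(self, aln: Alignment) -> str:
        h = hashlib.sha256()
        payload = {
            "model": self.resolved_model().spec_string(),
            "backend": self.backend,
            "bootstrap": self.bootstrap,
            "seed": self.seed,
            "compute_significance": self.compute_significance,
            "significance_B": self.significance_B,
            "au_scales": list(self.au_scales),
            "pythia_difficulty": self.pythia_difficulty,
        }
        h.update(json.dumps(payload, sort_keys=True).encode())
        for t, s in zip(aln.taxa, aln.sequences):
            h.update(t.encode())
            h.update(s.encode())
        return h.hexdigest()


def dedupe_alignment(aln: Alignment) -> Alignment:
    """Drop exact duplicate sequences, keeping the first occurrence.

    Exactness is byte-level (no case folding).  Removals are logged with
    the kept representative.  Errors if fewer than 5 unique sequences
    remain (leave-one-out needs 4-leaf reduced trees)."""
    seen: dict[str, str] = {}
    keep_taxa, keep_seqs = [], []
    for t, s in zip(aln.taxa, aln.sequences):
        if s in seen:
            logger.info("dropping duplicate sequence %r (identical to %r)", t, seen[s])
            continue
        seen[s] = t
        keep_taxa.append(t)
        keep_seqs.append(s)
    if len(keep_taxa) < 5:
        raise ValueError(
            f"only {len(keep_taxa)} unique sequences; leave-one-out needs at least 5"
        )
    return Alignment(keep_taxa, keep_seqs)


def _derived_seed(seed: int, *key: int) -> int:
    return int(np.random.SeedSequence([seed, *key]).generate_state(1)[0] % (2**31))


def _analyze_taxon(
    s: str,
    idx: int,
    aln: Alignment,
    full_tree,
    cfg: RunConfig,
    model: SubstModel,
    outdir: Path | None,
    D_full=None,
):
    aln_minus = aln.drop_taxon(s)
    sub_seed = _derived_seed(cfg.seed, idx)
    icfg = InferenceConfig(
        backend=cfg.backend, model=model, bootstrap=cfg.bootstrap,
        seed=sub_seed, external_dir=cfg.external_dir,
    )
    if cfg.backend == "nj" and D_full is not None:
        # pairwise-deletion distances are row-drop consistent
        inferred = nj_tree(D_full.drop(s))
    else:
        inferred = infer_tree(aln_minus, icfg, exclude_taxon=s)
    if cfg.bootstrap >= 1 and cfg.backend != "external":
        inferred = bootstrap_supports(aln_minus, inferred, icfg)
    pruned = full_tree.prune_taxon(s)

    raw_tii, norm_tii = tii(pruned, inferred)
    radius = disruption_radius(full_tree, inferred, s)
    low_dist = None
    if all(inferred.edges[e].support is not None for e in inferred.internal_edges()):
        low_dist = unstable_to_low_support_distance(inferred, pruned)
    au_p = sh_p = None
    if raw_tii != 0 and cfg.compute_significance:
        au_p, sh_p = assess_significance(
            pruned, inferred, aln_minus, model,
            B=cfg.significance_B, scales=cfg.au_scales, seed=sub_seed,
        )
    record = StabilityRecord(
        taxon=s, tii=raw_tii, tii_normalized=norm_tii, disruption_radius=radius,
        mean_unstable_to_low_support=low_dist, au_p=au_p, sh_p=sh_p,
    )

    placement = placement_candidates(inferred, aln, s, model)
    tplus = best_placement_tree(inferred, placement)
    fv = assemble_features(
        inferred, placement, tplus, aln, model,
        full_aln=aln, pythia_difficulty=cfg.pythia_difficulty,
        distance_matrix=D_full,
    )
    if outdir is not None:
        safe = sanitize_label(s)
        inferred.write(outdir / f"inferred_{safe}.nw")
        pruned.write(outdir / f"pruned_{safe}.nw")
        (outdir / f"placement_{safe}.jplace").write_text(
            jplace_string(inferred, placement)
        )
    return record, fv


def run_leave_one_out(aln: Alignment, cfg: RunConfig):
    """Run the full leave-one-out analysis; returns (stability, features)
    DataFrames.

    Duplicate sequences are removed first.  Per-taxon failures are flagged
    in the output and the run continues; a failure to infer the full tree
    aborts.  With ``cfg.outdir`` set, results are written there and an
    identical rerun (same config hash) reloads them instead of recomputing.
    """
    aln = dedupe_alignment(aln)
    model = cfg.resolved_model()
    outdir = Path(cfg.outdir) if cfg.outdir else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
        stamp = outdir / "run.json"
        digest = cfg.content_hash(aln)
        stab_csv, feat_csv = outdir / "stability.csv", outdir / "features.csv"
        if stamp.exists() and stab_csv.exists() and feat_csv.exists():
            meta = json.loads(stamp.read_text())
            if meta.get("config_hash") == digest:
                logger.info("outputs up to date for config hash %s; reloading", digest[:12])
                return pd.read_csv(stab_csv), pd.read_csv(feat_csv)

    icfg = InferenceConfig(
        backend=cfg.backend, model=model, bootstrap=cfg.bootstrap,
        seed=_derived_seed(cfg.seed, 0xF011), external_dir=cfg.external_dir,
    )
    D_full = corrected_distance_matrix(aln, model)
    full_tree = nj_tree(D_full) if cfg.backend == "nj" else infer_tree(aln, icfg)
    if cfg.bootstrap >= 1 and cfg.backend != "external":
        full_tree = bootstrap_supports(aln, full_tree, icfg)
    if outdir is not None:
        full_tree.write(outdir / "full.nw")

    stab_rows, feat_rows = [], []
    for idx, s in enumerate(aln.taxa):
        try:
            record, fv = _analyze_taxon(s, idx, aln, full_tree, cfg, model, outdir, D_full)
            stab_rows.append({
                "taxon": s, "tii": record.tii, "tii_norm": record.tii_normalized,
                "disruption_radius": record.disruption_radius,
                "mean_unstable_low_support_dist": record.mean_unstable_to_low_support,
                "au_p": record.au_p, "sh_p": record.sh_p,
                "stable": record.stable,
                "significant_instability": record.significant_instability,
                "failed": False,
            })
            feat_rows.append(fv.as_dict())
        except Exception:
            logger.exception("taxon %r failed; row flagged", s)
            stab_rows.append({
                "taxon": s, "tii": None, "tii_norm": None, "disruption_radius": None,
                "mean_unstable_low_support_dist": None, "au_p": None, "sh_p": None,
                "stable": None, "significant_instability": None, "failed": True,
            })
            feat_rows.append({"taxon": s, **{c: None for c in FEATURE_COLUMNS}})
    stability = pd.DataFrame(stab_rows, columns=STABILITY_COLUMNS)
    features = pd.DataFrame(feat_rows, columns=["taxon"] + FEATURE_COLUMNS)
    for col in STABILITY_COLUMNS[1:7]:
        stability[col] = pd.to_numeric(stability[col])
    for col in ("stable", "significant_instability", "failed"):
        stability[col] = stability[col].astype("boolean")
    for col in FEATURE_COLUMNS:
        features[col] = pd.to_numeric(features[col])
    if outdir is not None:
        stability.to_csv(outdir / "stability.csv", index=False)
        features.to_csv(outdir / "features.csv", index=False)
        (outdir / "run.json").write_text(
            json.dumps({"config_hash": cfg.content_hash(aln)}, indent=1)
        )
    return stability, features
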