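"""Random-forest prediction of taxon-addition stability.

Four tasks: classification of TII zero vs non-zero (``classify_tii``,
class-balanced batched ensemble: every batch holds all minority-class rows
plus an equal-size, disjoint draw from the majority class), classification
of significant instability (``classify_significant``, single forest —
those classes are roughly balanced by construction), and regression of the
normalized TII and disruption radius.  Hyperparameters are tuned by a
seeded 200-trial random search over the declared space, scored on a
validation split (AUROC / R^2); the held-out test split is only used for
final evaluation.  Classification predictions are majority votes across
batch forests (ties to the positive, unstable class), probabilities are
averaged for ROC curves, and permutation importances are averaged across
forests and normalized to sum to one.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.inspection import permutation_importance
from sklearn.metrics import r2_score, roc_auc_score, roc_curve

from .features import FEATURE_COLUMNS

logger = logging.getLogger(__name__)

__all__ = [
    "TASKS",
    "HyperparamSpace",
    "BalancedEnsemble",
    "split_data",
    "balanced_batches",
    "tune_and_train",
    "ensemble_predict",
    "evaluate",
    "feature_importances",
    "FEATURE_CONFIGS",
]

# task -> (target column, is_classification, batched)
TASKS = {
    "classify_tii": ("unstable", True, True),
    "classify_significant": ("significant", True, False),
    "regress_tii": ("tii_norm", False, False),
    "regress_radius": ("disruption_radius", False, False),
}

FEATURE_CONFIGS = {
    "full": FEATURE_COLUMNS,
    "no_difficulty": [c for c in FEATURE_COLUMNS if c != "pythia_difficulty"],
    "no_difficulty_no_bootstrap": [
        c for c in FEATURE_COLUMNS
        if c not in ("pythia_difficulty", "bootstrap_mean", "bootstrap_sd")
    ],
}


@dataclass
class HyperparamSpace:
    """Random-forest hyperparameter search space.

    Tree count and depth are sampled uniformly on [10, 1000] (depth in the
    log domain), the minimum split/leaf fractions log-uniformly on
    [1e-5, 1]; fractions are converted to sample counts at fit time.
    """

    n_trees: tuple = (10, 1000)
    max_depth: tuple = (10, 1000)
    min_split_fraction: tuple = (1e-5, 1.0)
    min_leaf_fraction: tuple = (1e-5, 1.0)
    max_features: tuple = ("all", "log2")
    classification_criteria: tuple = ("gini", "log_loss", "entropy")
    regression_criteria: tuple = ("squared_error", "absolute_error", "friedman_mse", "poisson")
    trials: int = 200

    def _log_uniform(self, rng, lo, hi):
        return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))

    def sample(self, rng: np.random.Generator, classification: bool) -> dict:
        crit = self.classification_criteria if classification else self.regression_criteria
        return {
            "n_trees": int(rng.integers(self.n_trees[0], self.n_trees[1] + 1)),
            "max_depth": int(round(self._log_uniform(rng, *self.max_depth))),
            "min_split_fraction": self._log_uniform(rng, *self.min_split_fraction),
            "min_leaf_fraction": self._log_uniform(rng, *self.min_leaf_fraction),
            "max_features": self.max_features[rng.integers(0, len(self.max_features))],
            "criterion": crit[rng.integers(0, len(crit))],
        }


@dataclass
class BalancedEnsemble:
    """A fitted ensemble of forests (one per balanced batch) plus the split
    bookkeeping needed for honest evaluation."""

    task: str
    feature_names: list
    forests: list
    batches: list
    params: dict
    splits: dict
    validation_score: float

    @property
    def classification(self) -> bool:
        return TASKS[self.task][1]

    def save(self, path) -> None:
        joblib.dump({"format_version": 1, "ensemble": self}, path)

    @staticmethod
    def load(path) -> "BalancedEnsemble":
        payload = joblib.load(path)
        if payload.get("format_version") != 1:
            raise ValueError("unrecognized model archive version")
        return payload["ensemble"]


# ------------------------------------------------------------------ splitting
def split_data(
    table: pd.DataFrame,
    seed: int = 0,
    balance_test_target: str | None = None,
    group_col: str | None = None,
    stratify_target: str | None = None,
) -> dict:
    """Disjoint 60/20/20 train/validation/test row-index split.

    With ``group_col`` set, whole groups (source alignments) are assigned
    to one side only, so rows from an alignment never straddle splits.
    ``balance_test_target`` subsamples the larger class within the test
    split so test classes have equal size (the convention for evaluating
    the TII classifier).  Deterministic given the seed."""
    if len(table) < 10:
        raise ValueError("need at least 10 rows to split")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5B11]))
    idx = np.arange(len(table))
    if group_col is not None:
        groups = table[group_col].to_numpy()
        uniq = np.array(sorted(set(groups)))
        rng.shuffle(uniq)
        targets = {"train": 0.6, "validation": 0.2, "test": 0.2}
        splits = {k: [] for k in targets}
        total = len(table)
        counts = {k: 0 for k in targets}
        for g in uniq:
            rows = idx[groups == g]
            # most-underfilled split relative to its target fraction
            key = min(targets, key=lambda k: counts[k] / total - targets[k])
            splits[key].extend(rows.tolist())
            counts[key] += len(rows)
        out = {k: np.array(sorted(v), dtype=int) for k, v in splits.items()}
    else:
        rng.shuffle(idx)
        n = len(idx)
        n_train = int(round(0.6 * n))
        n_val = int(round(0.2 * n))
        out = {
            "train": np.sort(idx[:n_train]),
            "validation": np.sort(idx[n_train:n_train + n_val]),
            "test": np.sort(idx[n_train + n_val:]),
        }
    check = stratify_target or balance_test_target
    if check is not None:
        y = table[check].to_numpy()
        for name, rows in out.items():
            if len(np.unique(y[rows])) < 2:
                raise ValueError(
                    f"class missing from the {name} split; try another seed "
                    "or provide more data"
                )
    if balance_test_target is not None:
        y = table[balance_test_target].to_numpy()
        rows = out["test"]
        classes, counts = np.unique(y[rows], return_counts=True)
        m = counts.min()
        kept = []
        for c in classes:
            members = rows[y[rows] == c]
            kept.extend(rng.choice(members, size=m, replace=False).tolist())
        out["test"] = np.array(sorted(kept), dtype=int)
    return out


def balanced_batches(labels: np.ndarray, seed: int = 0) -> list:
    """Index batches for the class-balanced ensemble.

    floor(majority/minority) batches; each contains every minority-class
    index plus an equal number of majority-class indices drawn without
    replacement across batches (leftover majority rows are unused)."""
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("both classes must be nonempty")
    minority = classes[np.argmin(counts)]
    majority = classes[np.argmax(counts)]
    min_idx = np.flatnonzero(labels == minority)
    maj_idx = np.flatnonzero(labels == majority)
    n_batches = len(maj_idx) // len(min_idx)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xBA7C]))
    perm = rng.permutation(maj_idx)
    batches = []
    for b in range(n_batches):
        chunk = perm[b * len(min_idx):(b + 1) * len(min_idx)]
        batches.append(np.sort(np.concatenate([min_idx, chunk])))
    return batches


# ------------------------------------------------------------------- training
def _make_forest(params: dict, classification: bool, n_samples: int, random_state: int):
    kwargs = dict(
        n_estimators=params["n_trees"],
        max_depth=params["max_depth"],
        min_samples_split=max(2, int(np.ceil(params["min_split_fraction"] * n_samples))),
        min_samples_leaf=max(1, int(np.ceil(params["min_leaf_fraction"] * n_samples))),
        max_features=None if params["max_features"] == "all" else "log2",
        criterion=params["criterion"],
        random_state=random_state,
        n_jobs=1,
    )
    cls = RandomForestClassifier if classification else RandomForestRegressor
    with warnings.catch_warnings():
        # friedman_mse stays in the declared criterion set; newer sklearn
        # aliases it to squared_error with a FutureWarning at construction
        warnings.simplefilter("ignore", FutureWarning)
        return cls(**kwargs)


def _fit_ensemble(X, y, batches, params, classification, seed):
    forests = []
    for b, batch in enumerate(batches):
        rs = int(np.random.SeedSequence([seed, b]).generate_state(1)[0] % (2**31))
        forest = _make_forest(params, classification, len(batch), rs)
        forest.fit(X[batch], y[batch])
        forests.append(forest)
    return forests


def _score(forests, X, y, classification) -> float:
    if classification:
        probs = np.mean([f.predict_proba(X)[:, list(f.classes_).index(1)]
                         for f in forests], axis=0)
        return float(roc_auc_score(y, probs))
    preds = np.mean([f.predict(X) for f in forests], axis=0)
    return float(r2_score(y, preds))


def prepare_table(table: pd.DataFrame, task: str, feature_config: str = "full"):
    """Select usable feature columns and complete rows for a task.

    Columns that are entirely missing (e.g. no difficulty sidecar) are
    dropped with a log note; rows with missing values in the remaining
    features or the target are excluded."""
    target = TASKS[task][0]
    cols = [c for c in FEATURE_CONFIGS[feature_config] if c in table.columns]
    dropped = [c for c in cols if table[c].isna().all()]
    if dropped:
        logger.info("dropping all-missing feature columns: %s", dropped)
    cols = [c for c in cols if c not in dropped]
    mask = table[cols + [target]].notna().all(axis=1)
    if (~mask).any():
        logger.info("excluding %d rows with missing values", int((~mask).sum()))
    return table.loc[mask].reset_index(drop=True), cols, target


def tune_and_train(
    table: pd.DataFrame,
    task: str,
    space: HyperparamSpace | None = None,
    feature_config: str = "full",
    seed: int = 0,
    group_col: str | None = None,
) -> BalancedEnsemble:
    """Random-search hyperparameter optimization and final ensemble fit.

    The search maximizes validation AUROC (classification) or R^2
    (regression); the best configuration's ensemble, trained on the
    training batches, is returned together with the split bookkeeping."""
    if task not in TASKS:
        raise ValueError(f"unknown task {task!r}")
    space = space or HyperparamSpace()
    target, classification, batched = TASKS[task]
    data, cols, target = prepare_table(table, task, feature_config)
    splits = split_data(
        data, seed=seed,
        balance_test_target=target if task == "classify_tii" else None,
        stratify_target=target if classification else None,
        group_col=group_col,
    )
    X = data[cols].to_numpy(dtype=float)
    y = data[target].to_numpy()
    train, val = splits["train"], splits["validation"]
    if batched:
        rel_batches = balanced_batches(y[train], seed=seed)
        batches = [train[b] for b in rel_batches]
    else:
        batches = [train]
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x7071]))
    best = None
    failures = []
    for trial in range(space.trials):
        params = space.sample(rng, classification)
        try:
            forests = _fit_ensemble(X, y, batches, params, classification, seed)
            score = _score(forests, X[val], y[val], classification)
        except Exception as exc:
            failures.append((trial, params, str(exc)))
            continue
        if best is None or score > best[0] + 1e-12:
            best = (score, params, forests)
    if best is None:
        raise RuntimeError(f"all {space.trials} trials failed; log: {failures[:5]}")
    score, params, forests = best
    return BalancedEnsemble(
        task=task, feature_names=cols, forests=forests,
        batches=[b.tolist() for b in batches], params=params,
        splits={k: v.tolist() for k, v in splits.items()},
        validation_score=score,
    )


# ----------------------------------------------------------------- prediction
def ensemble_predict(model: BalancedEnsemble, rows: pd.DataFrame):
    """Predict for a feature table.

    Classification returns (index, labels, averaged probabilities): labels
    are majority votes across forests with ties to the positive class;
    regression returns (index, mean predictions).  Rows with missing
    mandatory features are skipped with a log entry."""
    missing_cols = [c for c in model.feature_names if c not in rows.columns]
    if missing_cols:
        raise ValueError(f"rows lack feature columns {missing_cols}")
    mask = rows[model.feature_names].notna().all(axis=1)
    if (~mask).any():
        logger.info("skipping %d rows with missing features", int((~mask).sum()))
    kept = rows.loc[mask]
    X = kept[model.feature_names].to_numpy(dtype=float)
    if model.classification:
        votes = np.stack([f.predict(X) for f in model.forests])
        frac_pos = (votes == 1).mean(axis=0)
        labels = (frac_pos >= 0.5).astype(int)  # tie -> positive (unstable)
        if np.any(np.isclose(frac_pos, 0.5)):
            logger.info("majority-vote tie(s) resolved to the positive class")
        probs = np.mean(
            [f.predict_proba(X)[:, list(f.classes_).index(1)] for f in model.forests],
            axis=0,
        )
        return kept.index, labels, probs
    preds = np.mean([f.predict(X) for f in model.forests], axis=0)
    return kept.index, preds


def evaluate(model: BalancedEnsemble, table: pd.DataFrame, split: str = "test"):
    """Score the ensemble on one of its own splits (default: held-out test).

    Returns a dict with the metric (auroc or r2) and, for classification,
    the averaged-probability ROC curve points."""
    data, cols, target = prepare_table(table, model.task)
    rows = data.iloc[model.splits[split]]
    y = rows[target].to_numpy()
    if model.classification:
        _, labels, probs = ensemble_predict(model, rows)
        fpr, tpr, _ = roc_curve(y, probs)
        return {
            "auroc": float(roc_auc_score(y, probs)),
            "accuracy": float((labels == y).mean()),
            "roc": pd.DataFrame({"fpr": fpr, "tpr": tpr}),
        }
    _, preds = ensemble_predict(model, rows)
    return {"r2": float(r2_score(y, preds))}


def feature_importances(
    model: BalancedEnsemble,
    table: pd.DataFrame,
    seed: int = 0,
    n_repeats: int = 10,
    split: str = "test",
) -> pd.Series:
    """Permutation importances on held-out rows, averaged across the batch
    forests, floored at zero, and normalized to sum to one."""
    data, cols, target = prepare_table(table, model.task)
    rows = data.iloc[model.splits[split]]
    X = rows[model.feature_names].to_numpy(dtype=float)
    y = rows[target].to_numpy()
    scoring = "roc_auc" if model.classification else "r2"
    per_forest = []
    for f in model.forests:
        imp = permutation_importance(
            f, X, y, scoring=scoring, n_repeats=n_repeats, random_state=seed,
            n_jobs=1,
        )
        per_forest.append(imp.importances_mean)
    mean_imp = np.mean(per_forest, axis=0)
    if np.any(mean_imp < 0):
        logger.info("negative permutation importances floored at 0")
        mean_imp = np.maximum(mean_imp, 0.0)
    total = mean_imp.sum()
    if total <= 0:
        logger.warning("all permutation importances are zero; returning uniform")
        mean_imp = np.ones_like(mean_imp)
        total = mean_imp.sum()
    return pd.Series(mean_imp / total, index=model.feature_names)
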