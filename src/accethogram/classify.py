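"""Random-forest behaviour classification with the study protocol:
rare-behaviour filtering, stratified 70/30 split, within-fold up-sampling,
individual-blocked cross-validated tuning by AUC, and confusion-matrix
evaluation.

Individuals are the cross-validation blocks: each fold holds out every
window of one animal, so tuning scores generalisation to an unseen
individual rather than interpolation within one.  A provenance assertion
(:func:`check_fold_provenance`) guards against the classic leakage fault in
which up-sampled copies of held-out windows slip into a training fold.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import roc_auc_score

from .features import FEATURE_NAMES

__all__ = [
    "SplitSpec",
    "TrainedClassifier",
    "EvalReport",
    "LeakageError",
    "filter_rare_behaviours",
    "split_train_test",
    "upsample",
    "blocked_cv_tune",
    "check_fold_provenance",
    "evaluate",
]


class LeakageError(AssertionError):
    """Raised when a training fold contains rows (or up-sampled copies of
    rows) from the held-out individual."""


@dataclass(frozen=True)
class SplitSpec:
    """Stratified train/test split settings."""

    train_fraction: float = 0.7
    stratify_on: str = "behaviour"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")


@dataclass
class TrainedClassifier:
    """A tuned, refitted random forest with its tuning summary."""

    model: RandomForestClassifier
    classes: list[str]
    mtry: int
    n_trees: int
    cv_auc: float
    cv_auc_by_mtry: dict[int, float]
    importance: dict[str, float]
    feature_names: list[str]
    seed: int
    fold_notes: list[str] = field(default_factory=list)

    def save(self, path: str | Path) -> None:
        """Persist the model (joblib binary) plus a JSON sidecar with the
        tuning metadata."""
        import joblib

        path = Path(path)
        joblib.dump(self.model, path)
        sidecar = {
            "classes": self.classes,
            "mtry": self.mtry,
            "n_trees": self.n_trees,
            "cv_auc": self.cv_auc,
            "importance": self.importance,
            "seed": self.seed,
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


@dataclass
class EvalReport:
    """Held-out evaluation: confusion matrix (rows = truth), overall
    accuracy, per-class balanced accuracy and macro one-vs-rest AUC."""

    classes: list[str]
    confusion: np.ndarray
    overall_accuracy: float
    balanced_accuracy: dict[str, float]
    auc: float
    n_test: int

    def to_json(self) -> str:
        return json.dumps(
            {
                "classes": self.classes,
                "confusion": self.confusion.tolist(),
                "overall_accuracy": self.overall_accuracy,
                "balanced_accuracy": self.balanced_accuracy,
                "auc": self.auc,
                "n_test": self.n_test,
            },
            indent=2,
        )

    def confusion_text(self) -> str:
        df = pd.DataFrame(self.confusion, index=self.classes, columns=self.classes)
        return df.to_string()


def filter_rare_behaviours(
    table: pd.DataFrame, max_individuals: int = 3, return_report: bool = False
):
    """Drop behaviours observed in ``max_individuals`` or fewer distinct
    individuals — too few animals to support individual-blocked
    cross-validation.  The removal is recorded in ``attrs`` (and returned
    when ``return_report``)."""
    counts = table.groupby("behaviour")["individual_id"].nunique()
    removed = sorted(counts[counts <= max_individuals].index)
    out = table[~table["behaviour"].isin(removed)].reset_index(drop=True)
    out.attrs["removed_behaviours"] = removed
    if return_report:
        return out, removed
    return out


def split_train_test(table: pd.DataFrame, spec: SplitSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stratified random partition: per class, round(train_fraction * n)
    rows go to training.  Rows from one individual may land in both halves
    (the study's default); use individual-disjoint folds for the stricter
    design."""
    rng = np.random.default_rng(spec.seed)
    train_idx: list[np.ndarray] = []
    test_idx: list[np.ndarray] = []
    for _, grp in table.groupby(spec.stratify_on, sort=True):
        if len(grp) < 2:
            raise ValueError(
                f"class '{grp[spec.stratify_on].iloc[0]}' has a single row; "
                "cannot stratify"
            )
        idx = grp.index.to_numpy()
        rng.shuffle(idx)
        n_train = int(round(spec.train_fraction * len(idx)))
        n_train = min(max(n_train, 1), len(idx) - 1)
        train_idx.append(idx[:n_train])
        test_idx.append(idx[n_train:])
    train = table.loc[np.concatenate(train_idx)].reset_index(drop=True)
    test = table.loc[np.concatenate(test_idx)].reset_index(drop=True)
    return train, test


def upsample(train: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Random resampling with replacement of minority behaviours up to the
    majority-class count; all original rows are retained.  Provenance
    columns (individual_id) travel with the copies, so the leakage guard
    still sees them."""
    if len(train) == 0:
        return train.copy()
    rng = np.random.default_rng(seed)
    counts = train["behaviour"].value_counts()
    n_max = int(counts.max())
    parts = [train]
    for cls, n in counts.items():
        if n < n_max:
            rows = train[train["behaviour"] == cls]
            extra = rows.iloc[rng.integers(0, len(rows), size=n_max - n)]
            parts.append(extra)
    return pd.concat(parts, ignore_index=True)


def check_fold_provenance(fold_train: pd.DataFrame, holdout_individual: str) -> None:
    """Assert that no row of a training fold — original or up-sampled copy —
    originates from the held-out individual."""
    leaked = int((fold_train["individual_id"] == holdout_individual).sum())
    if leaked:
        raise LeakageError(
            f"{leaked} training rows originate from held-out individual "
            f"'{holdout_individual}'"
        )


def _macro_ovr_auc(
    y_true: np.ndarray, proba: np.ndarray, model_classes: np.ndarray
) -> tuple[float, list[str]]:
    """Macro one-vs-rest AUC over the classes present in y_true; classes the
    held-out individual lacks are skipped and reported."""
    present = [c for c in model_classes if c in set(y_true)]
    skipped = [str(c) for c in model_classes if c not in set(y_true)]
    aucs = []
    for c in present:
        pos = (y_true == c).astype(int)
        if pos.all():  # single-class holdout: AUC undefined for it too
            continue
        col = int(np.where(model_classes == c)[0][0])
        aucs.append(roc_auc_score(pos, proba[:, col]))
    return (float(np.mean(aucs)) if aucs else float("nan")), skipped


def _fit_forest(
    X: np.ndarray, y: np.ndarray, mtry: int, n_trees: int, seed: int
) -> RandomForestClassifier:
    rf = RandomForestClassifier(
        n_estimators=n_trees,
        max_features=mtry,
        random_state=seed,
        n_jobs=1,
    )
    rf.fit(X, y)
    return rf


def blocked_cv_tune(
    train: pd.DataFrame,
    mtry_grid: list[int] | None = None,
    n_trees: int = 1000,
    seed: int = 0,
    feature_names: list[str] | None = None,
) -> TrainedClassifier:
    """Tune the number of predictors per split (mtry) by individual-blocked
    cross-validation, then refit on the full (up-sampled) training set.

    For each candidate mtry and each fold (one individual held out), a
    forest is fitted on the up-sampled rows of all *other* individuals —
    up-sampling happens strictly inside the fold, after the hold-out, and
    the provenance guard verifies it — and scored by macro one-vs-rest AUC
    on the held-out animal.  The mtry with the highest mean AUC wins; ties
    break to the smallest (parsimony).  Impurity-based importance comes
    from the refitted forest.
    """
    feature_names = list(feature_names or FEATURE_NAMES)
    mtry_grid = sorted(set(mtry_grid or [2, 4, 6]))
    if n_trees > 1000:
        raise ValueError("n_trees capped at 1000")
    individuals = sorted(train["individual_id"].unique())
    if len(individuals) < 2:
        raise ValueError("blocked CV needs >= 2 individuals in training data")
    bad = [m for m in mtry_grid if not 1 <= m <= len(feature_names)]
    if bad:
        raise ValueError(f"mtry values out of range: {bad}")

    notes: list[str] = []
    mean_auc: dict[int, float] = {}
    for mtry in mtry_grid:
        fold_aucs = []
        for holdout in individuals:
            fold_train = train[train["individual_id"] != holdout]
            holdout_rows = train[train["individual_id"] == holdout]
            fold_train = upsample(fold_train, seed=seed)
            check_fold_provenance(fold_train, holdout)
            rf = _fit_forest(
                fold_train[feature_names].to_numpy(),
                fold_train["behaviour"].to_numpy(),
                mtry,
                n_trees,
                seed,
            )
            proba = rf.predict_proba(holdout_rows[feature_names].to_numpy())
            auc, skipped = _macro_ovr_auc(
                holdout_rows["behaviour"].to_numpy(), proba, rf.classes_
            )
            if skipped:
                notes.append(
                    f"fold {holdout}: classes absent from holdout, AUC scored "
                    f"over present classes only (missing: {skipped})"
                )
            if np.isfinite(auc):
                fold_aucs.append(auc)
        mean_auc[mtry] = float(np.mean(fold_aucs)) if fold_aucs else float("nan")

    best = max(mtry_grid, key=lambda m: (round(mean_auc[m], 12), -m))
    full = upsample(train, seed=seed)
    rf = _fit_forest(
        full[feature_names].to_numpy(), full["behaviour"].to_numpy(), best, n_trees, seed
    )
    importance = dict(zip(feature_names, map(float, rf.feature_importances_)))
    return TrainedClassifier(
        model=rf,
        classes=[str(c) for c in rf.classes_],
        mtry=best,
        n_trees=n_trees,
        cv_auc=mean_auc[best],
        cv_auc_by_mtry=mean_auc,
        importance=importance,
        feature_names=feature_names,
        seed=seed,
        fold_notes=notes,
    )


def evaluate(model: TrainedClassifier, test: pd.DataFrame) -> EvalReport:
    """Apply a trained classifier to a held-out table.

    Overall accuracy is the confusion-matrix trace over n_test; balanced
    accuracy per class is (sensitivity + specificity) / 2 in one-vs-rest
    form; AUC is macro one-vs-rest.
    """
    if len(test) == 0:
        raise ValueError("empty test set")
    unknown = set(test["behaviour"]) - set(model.classes)
    if unknown:
        raise ValueError(f"test classes not seen in training: {sorted(unknown)}")
    X = test[model.feature_names].to_numpy()
    y = test["behaviour"].to_numpy()
    pred = model.model.predict(X)
    classes = model.classes
    cm = _sk_confusion(y, pred, labels=classes)
    n = len(y)
    overall = float(np.trace(cm) / n)
    balanced: dict[str, float] = {}
    for i, c in enumerate(classes):
        tp = cm[i, i]
        fn = cm[i].sum() - tp
        fp = cm[:, i].sum() - tp
        tn = n - tp - fn - fp
        sens = tp / (tp + fn) if tp + fn else np.nan
        spec = tn / (tn + fp) if tn + fp else np.nan
        balanced[c] = float((sens + spec) / 2)
    proba = model.model.predict_proba(X)
    auc, _ = _macro_ovr_auc(y, proba, np.array(classes, dtype=object))
    return EvalReport(
        classes=classes,
        confusion=cm,
        overall_accuracy=overall,
        balanced_accuracy=balanced,
        auc=auc,
        n_test=n,
    )
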