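"""The stacked ensemble classifier and its evaluation machinery.

Six heterogeneous base learners (KNN, logistic regression, RBF-SVM,
gradient-boosted trees, random forest, MLP) are each tuned by grid search
with stratified cross-validation; a logistic-regression meta-classifier is
then trained on their out-of-fold probabilities, which keeps the stacking
free of information leakage.  Reported metrics are cross-validation means.
"""

from __future__ import annotations

import json
import logging
import pickle
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from lightgbm import LGBMClassifier
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .dataset import FEATURE_COLUMNS, FEATURE_GROUPS, LABEL_COLUMN, SEQUENCE_GROUPS, STRUCTURE_GROUPS

logger = logging.getLogger(__name__)

BASE_LEARNER_NAMES = ("KNN", "LR", "SVM", "LGBM", "RF", "MLP")
STACK_NAME = "stacked"
DEFAULT_SEED = 42


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class Metrics:
    acc: float
    f1: float
    recall: float
    roc_auc: float

    def as_dict(self) -> dict[str, float]:
        return {"ACC": self.acc, "F1": self.f1, "RECALL": self.recall,
                "ROC AUC": self.roc_auc}


def confusion(y_true: Sequence[int], y_pred: Sequence[int]) -> ConfusionCounts:
    """Confusion counts with the covalent class (1) as positive."""
    yt = np.asarray(y_true)
    yp = np.asarray(y_pred)
    if yt.shape != yp.shape or yt.size == 0:
        raise ValueError("label vectors must be equal-length and non-empty")
    for v in (yt, yp):
        if not np.isin(v, (0, 1)).all():
            raise ValueError("labels must be 0/1")
    return ConfusionCounts(
        tp=int(np.sum((yt == 1) & (yp == 1))),
        fp=int(np.sum((yt == 0) & (yp == 1))),
        tn=int(np.sum((yt == 0) & (yp == 0))),
        fn=int(np.sum((yt == 1) & (yp == 0))),
    )


def evaluate(
    y_true: Sequence[int], scores: Sequence[float], threshold: float = 0.5
) -> Metrics:
    """Accuracy, F1, recall, and ROC AUC from class-1 probabilities.

    ROC AUC is the Mann-Whitney rank statistic (ties get half credit);
    F1 is the harmonic mean of precision and recall, defined as 0 when the
    denominator vanishes.
    """
    yt = np.asarray(y_true)
    s = np.asarray(scores, dtype=float)
    if np.any((s < 0) | (s > 1)):
        raise ValueError("scores must lie in [0, 1]")
    if len(np.unique(yt)) < 2:
        raise ValueError("ROC AUC undefined for single-class labels")
    yp = (s >= threshold).astype(int)
    c = confusion(yt, yp)
    acc = (c.tp + c.tn) / c.n
    recall = c.tp / (c.tp + c.fn) if (c.tp + c.fn) else 0.0
    precision = c.tp / (c.tp + c.fp) if (c.tp + c.fp) else 0.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if (precision + recall) > 0 else 0.0
    )
    auc = float(roc_auc_score(yt, s))
    return Metrics(acc=float(acc), f1=float(f1), recall=float(recall), roc_auc=auc)


# ---------------------------------------------------------------------------
# Base learners
# ---------------------------------------------------------------------------

def make_base_learners(
    seed: int = DEFAULT_SEED,
    grids: Mapping[str, Mapping[str, list]] | None = None,
) -> dict[str, tuple[Pipeline, dict[str, list]]]:
    """Specs for the six base learners: (pipeline, hyperparameter grid).

    Every pipeline standardizes features from training-fold statistics
    before the classifier, so cross-validation never leaks test-fold scale.
    """
    default_grids: dict[str, dict[str, list]] = {
        "KNN": {"clf__n_neighbors": [3, 5, 7, 9, 11]},
        "LR": {"clf__C": [0.1, 1, 10]},
        "SVM": {
            "clf__estimator__C": [0.1, 1, 10],
            "clf__estimator__gamma": ["scale", 0.01, 0.1],
        },
        "LGBM": {
            "clf__num_leaves": [15, 31],
            "clf__n_estimators": [100, 300],
            "clf__learning_rate": [0.05, 0.1],
        },
        "RF": {"clf__n_estimators": [200, 500], "clf__max_depth": [None, 8]},
        "MLP": {
            "clf__hidden_layer_sizes": [(64,), (128, 64)],
            "clf__alpha": [1e-4, 1e-3],
        },
    }
    if grids:
        for name, g in grids.items():
            default_grids[name] = dict(g)

    estimators: dict[str, object] = {
        "KNN": KNeighborsClassifier(),
        "LR": LogisticRegression(max_iter=2000, random_state=seed),
        # Platt-style probabilities via cross-fitted sigmoid calibration;
        # SVC's built-in probability estimates can invert on small samples.
        "SVM": CalibratedClassifierCV(
            SVC(kernel="rbf", random_state=seed), ensemble=False
        ),
        "LGBM": LGBMClassifier(
            random_state=seed, n_jobs=1, verbose=-1, deterministic=True,
            force_row_wise=True,
        ),
        "RF": RandomForestClassifier(random_state=seed, n_jobs=1),
        "MLP": MLPClassifier(max_iter=800, random_state=seed),
    }
    specs: dict[str, tuple[Pipeline, dict[str, list]]] = {}
    for name in BASE_LEARNER_NAMES:
        pipe = Pipeline([("scale", StandardScaler()), ("clf", estimators[name])])
        specs[name] = (pipe, default_grids[name])
    return specs


# ---------------------------------------------------------------------------
# Stacking
# ---------------------------------------------------------------------------

@dataclass
class ModelBundle:
    """A fitted stack: six base learners plus the meta logistic regression."""

    base_learners: dict[str, Pipeline]
    meta: LogisticRegression
    window_size: int
    feature_names: list[str]
    seed: int
    best_params: dict[str, dict] = field(default_factory=dict)

    def manifest(self) -> dict:
        return {
            "base_learners": list(self.base_learners),
            "best_params": {
                k: {p: repr(v) for p, v in params.items()}
                for k, params in self.best_params.items()
            },
            "window_size": self.window_size,
            "feature_names": self.feature_names,
            "seed": self.seed,
            "meta_coefficients": self.meta.coef_.ravel().tolist(),
            "meta_intercept": float(self.meta.intercept_[0]),
        }

    def save(self, path: str | Path) -> None:
        path = Path(path)
        with open(path, "wb") as fh:
            pickle.dump(self, fh)
        path.with_suffix(".json").write_text(
            json.dumps(self.manifest(), indent=2, sort_keys=True)
        )

    @staticmethod
    def load(path: str | Path) -> "ModelBundle":
        with open(path, "rb") as fh:
            return pickle.load(fh)


def _split_xy(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, list[str]]:
    if LABEL_COLUMN not in table.columns:
        raise ValueError("feature table has no label column")
    feats = [c for c in table.columns if c != LABEL_COLUMN]
    X = table[feats].to_numpy(dtype=float)
    y = table[LABEL_COLUMN].to_numpy(dtype=int)
    return X, y, feats


def train_stacked(
    table: pd.DataFrame,
    k: int = 10,
    seed: int = DEFAULT_SEED,
    window_size: int = 21,
    grids: Mapping[str, Mapping[str, list]] | None = None,
) -> tuple[ModelBundle, dict[str, Metrics]]:
    """Fit the six-learner stack and report cross-validated metrics.

    Per base learner: grid search maximizing CV accuracy on the full table
    (stratified k-fold).  The tuned learners then produce out-of-fold
    probabilities over the same folds; the meta logistic regression is
    trained on those, and the stacked metrics are computed fold-wise with
    the meta refit on the remaining folds each time.  Finally every base
    learner is refit on all data for deployment.
    """
    X, y, feats = _split_xy(table)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("both classes must be present")
    if len(y) < k:
        raise ValueError(f"n={len(y)} smaller than k={k}")

    cv = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = list(cv.split(X, y))
    specs = make_base_learners(seed=seed, grids=grids)

    tuned: dict[str, Pipeline] = {}
    best_params: dict[str, dict] = {}
    for name, (pipe, grid) in specs.items():
        gs = GridSearchCV(pipe, grid, scoring="accuracy", cv=folds, n_jobs=1)
        gs.fit(X, y)
        tuned[name] = gs.best_estimator_
        best_params[name] = gs.best_params_
        logger.info("%s best params: %s (CV acc %.3f)", name, gs.best_params_,
                    gs.best_score_)

    # Out-of-fold base probabilities over the same folds.
    oof = np.zeros((len(y), len(BASE_LEARNER_NAMES)))
    fold_metrics: dict[str, list[Metrics]] = {n: [] for n in BASE_LEARNER_NAMES}
    from sklearn.base import clone

    for train_idx, test_idx in folds:
        for col, name in enumerate(BASE_LEARNER_NAMES):
            est = clone(tuned[name])
            est.fit(X[train_idx], y[train_idx])
            proba = est.predict_proba(X[test_idx])[:, 1]
            oof[test_idx, col] = proba
            fold_metrics[name].append(evaluate(y[test_idx], proba))

    # Stacked fold metrics: meta trained on the other folds' OOF rows.
    stack_folds: list[Metrics] = []
    for train_idx, test_idx in folds:
        meta_f = LogisticRegression(max_iter=2000, random_state=seed)
        meta_f.fit(oof[train_idx], y[train_idx])
        proba = meta_f.predict_proba(oof[test_idx])[:, 1]
        stack_folds.append(evaluate(y[test_idx], proba))

    meta = LogisticRegression(max_iter=2000, random_state=seed)
    meta.fit(oof, y)

    # Deployment refit on all data.
    final: dict[str, Pipeline] = {}
    for name in BASE_LEARNER_NAMES:
        est = clone(tuned[name])
        est.fit(X, y)
        final[name] = est

    def _mean(ms: list[Metrics]) -> Metrics:
        return Metrics(
            acc=float(np.mean([m.acc for m in ms])),
            f1=float(np.mean([m.f1 for m in ms])),
            recall=float(np.mean([m.recall for m in ms])),
            roc_auc=float(np.mean([m.roc_auc for m in ms])),
        )

    report = {name: _mean(ms) for name, ms in fold_metrics.items()}
    report[STACK_NAME] = _mean(stack_folds)

    bundle = ModelBundle(
        base_learners=final,
        meta=meta,
        window_size=window_size,
        feature_names=feats,
        seed=seed,
        best_params=best_params,
    )
    return bundle, report


def predict(
    bundle: ModelBundle, rows: pd.DataFrame, threshold: float = 0.5
) -> pd.DataFrame:
    """Stacked probabilities and labels for new feature rows."""
    cols = [c for c in rows.columns if c != LABEL_COLUMN]
    missing = [c for c in bundle.feature_names if c not in cols]
    extra = [c for c in cols if c not in bundle.feature_names]
    if missing or extra:
        raise ValueError(
            f"feature columns mismatch; missing={missing}, extra={extra}"
        )
    X = rows[bundle.feature_names].to_numpy(dtype=float)
    base = np.column_stack([
        bundle.base_learners[n].predict_proba(X)[:, 1] for n in BASE_LEARNER_NAMES
    ])
    proba = bundle.meta.predict_proba(base)[:, 1]
    return pd.DataFrame(
        {
            "probability": proba,
            "label": (proba >= threshold).astype(int),
        },
        index=rows.index,
    )


# ---------------------------------------------------------------------------
# Grouped feature importance
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupImportance:
    groups: dict[str, float]          # six feature groups, sums to 1
    aggregate: dict[str, float]       # structure-based vs sequence-based


def grouped_importance(
    table: pd.DataFrame,
    groups: Mapping[str, str] | None = None,
    seed: int = DEFAULT_SEED,
    n_estimators: int = 500,
) -> GroupImportance:
    """Random-forest impurity importance summed per feature group.

    ``groups`` maps each feature column to its group name; by default the
    canonical schema assignment is used.  Group shares are normalized to
    sum to 1, with structure/sequence two-way aggregates.
    """
    X, y, feats = _split_xy(table)
    if groups is None:
        groups = {}
        for g, cols in FEATURE_GROUPS.items():
            for c in cols:
                groups[c] = g
    unassigned = [f for f in feats if f not in groups]
    if unassigned:
        raise ValueError(f"feature columns without a group: {unassigned}")

    rf = RandomForestClassifier(n_estimators=n_estimators, random_state=seed, n_jobs=1)
    rf.fit(X, y)
    importances = rf.feature_importances_
    shares: dict[str, float] = {}
    for f, imp in zip(feats, importances):
        shares[groups[f]] = shares.get(groups[f], 0.0) + float(imp)
    total = sum(shares.values())
    if total > 0:
        shares = {g: v / total for g, v in shares.items()}
    aggregate = {
        "structure-based": sum(shares.get(g, 0.0) for g in STRUCTURE_GROUPS),
        "sequence-based": sum(shares.get(g, 0.0) for g in SEQUENCE_GROUPS),
    }
    return GroupImportance(groups=shares, aggregate=aggregate)


# ---------------------------------------------------------------------------
# Window-size sweep
# ---------------------------------------------------------------------------

def window_sweep(
    builder: Callable[[int], pd.DataFrame],
    ws_list: Sequence[int] = tuple(range(1, 24, 2)),
    k: int = 10,
    seed: int = DEFAULT_SEED,
    grids: Mapping[str, Mapping[str, list]] | None = None,
) -> tuple[pd.DataFrame, int]:
    """Train the full stack at each window size; pick the best by CV accuracy.

    Ties go to the smaller window.  Returns the per-window report (rows in
    ws order with the stacked metrics) and the chosen window size.
    """
    if not ws_list:
        raise ValueError("ws_list must be non-empty")
    if any(ws % 2 == 0 for ws in ws_list):
        raise ValueError("window sizes must be odd")
    records = []
    for ws in ws_list:
        table = builder(ws)
        _, report = train_stacked(table, k=k, seed=seed, window_size=ws, grids=grids)
        m = report[STACK_NAME]
        records.append({"ws": ws, **m.as_dict()})
    df = pd.DataFrame.from_records(records)
    best_idx = int(df.sort_values(["ACC", "ws"], ascending=[False, True]).index[0])
    best_ws = int(df.loc[best_idx, "ws"])
    return df, best_ws


def report_to_frame(report: Mapping[str, Metrics]) -> pd.DataFrame:
    """Rows = models, columns = ACC / F1 / RECALL / ROC AUC."""
    order = [n for n in (*BASE_LEARNER_NAMES, STACK_NAME) if n in report]
    return pd.DataFrame(
        {name: report[name].as_dict() for name in order}
    ).T[["ACC", "F1", "RECALL", "ROC AUC"]]
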