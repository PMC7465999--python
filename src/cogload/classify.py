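"""Dataset construction, classifier training and the evaluation suite.

Three label schemes over the task column:

* ``MSet`` — keep all three classes (baseline / 1-back / 2-back),
* ``BSet1`` — {baseline, 1-back} → baseline group vs {2-back} → task
  group (the mild task is grouped with normal driving),
* ``BSet2`` — {baseline} vs {1-back, 2-back}.

Rows are split 70/30 stratified by the mapped label, classifiers are
tuned with 5-fold cross-validation on the training rows and finally
evaluated on the held-out 30%. Features are median-imputed and
z-scored with statistics fitted on the training rows only; k-NN uses
Euclidean distance with squared-inverse vote weights and K = 5, the
SVM a Gaussian kernel (one-vs-rest for multiclass), and the random
forest 500 bagged trees. No imbalance correction is applied — the
balanced-accuracy/MCC members of the metric suite carry that burden.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.impute import SimpleImputer
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.multiclass import OneVsRestClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .metrics import (
    ConfusionCounts,
    MetricsReport,
    compute_metrics,
    confusion_from_predictions,
    evaluate_multiclass_ovr,
)

log = logging.getLogger(__name__)

__all__ = [
    "SCHEMES",
    "MODEL_KINDS",
    "DataSplit",
    "map_labels",
    "build_datasets",
    "add_scenario_feature",
    "train_classifier",
    "evaluate_on_test",
    "scenario_wise_eval",
    "run_experiment",
]

SCHEMES = ("MSet", "BSet1", "BSet2")
MODEL_KINDS = ("knn", "svm", "rf")

_SCENARIO_CODES = {"CR": 0, "HE": 1, "SW": 2}


def map_labels(tasks: pd.Series, scheme: str) -> pd.Series:
    """Map raw task labels to the scheme's classes."""
    if scheme == "MSet":
        return tasks.astype(str)
    if scheme == "BSet1":
        return tasks.map(
            lambda t: "task_group" if t == "2-back" else "baseline_group"
        )
    if scheme == "BSet2":
        return tasks.map(
            lambda t: "baseline_group" if t == "baseline" else "task_group"
        )
    raise ValueError(f"unknown label scheme {scheme!r}; expected one of {SCHEMES}")


@dataclass
class DataSplit:
    """70/30 split with 5-fold CV fold assignment on the training rows."""

    scheme: str
    feature_columns: list[str]
    x_train: pd.DataFrame
    y_train: np.ndarray
    x_test: pd.DataFrame
    y_test: np.ndarray
    folds: list[tuple[np.ndarray, np.ndarray]]
    seed: int
    meta: dict = field(default_factory=dict)


def build_datasets(
    table: pd.DataFrame,
    scheme: str,
    seed: int = 0,
    feature_columns: list[str] | None = None,
    test_fraction: float = 0.30,
    n_folds: int = 5,
) -> DataSplit:
    """Stratified 70/30 split plus seeded 5-fold CV assignment."""
    if "task" not in table.columns:
        raise ValueError("table must carry a 'task' column")
    y = map_labels(table["task"], scheme).to_numpy()
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2 or counts.min() == 0:
        raise ValueError(f"scheme {scheme}: a mapped class is empty")
    if feature_columns is None:
        feature_columns = [
            c for c in table.columns if c not in ("task", "scenario", "participant")
        ]
    x = table[feature_columns]
    xtr, xte, ytr, yte = train_test_split(
        x, y, test_size=test_fraction, stratify=y, random_state=seed
    )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = list(skf.split(xtr, ytr))
    return DataSplit(
        scheme=scheme,
        feature_columns=list(feature_columns),
        x_train=xtr.reset_index(drop=True),
        y_train=ytr,
        x_test=xte.reset_index(drop=True),
        y_test=yte,
        folds=folds,
        seed=seed,
        meta={"n_rows": len(table)},
    )


def add_scenario_feature(table: pd.DataFrame) -> pd.DataFrame:
    """Append the driving scenario as an integer-coded categorical column.

    CR → 0, HE → 1, SW → 2 in a ``scenario_code`` column; idempotent.
    """
    if "scenario" not in table.columns:
        raise ValueError("table must carry a 'scenario' column")
    bad = table.index[~table["scenario"].isin(_SCENARIO_CODES)].tolist()
    if bad:
        raise ValueError(f"rows with missing/unknown scenario label: {bad[:10]}")
    out = table.copy()
    out["scenario_code"] = out["scenario"].map(_SCENARIO_CODES).astype(float)
    return out


def _inverse_square_weights(distances: np.ndarray) -> np.ndarray:
    """k-NN vote weight 1/d²; exact matches dominate their neighbourhood."""
    w = np.zeros_like(distances, dtype=float)
    for i, row in enumerate(np.atleast_2d(distances)):
        zero = row == 0
        if zero.any():
            w[i, zero] = 1.0
        else:
            w[i] = 1.0 / row**2
    return w


def _make_model(model_kind: str, hyperparams: dict | None, seed: int, n_classes: int):
    hp = dict(hyperparams or {})
    if model_kind == "knn":
        return KNeighborsClassifier(
            n_neighbors=hp.pop("n_neighbors", 5),
            metric="euclidean",
            weights=_inverse_square_weights,
            **hp,
        )
    if model_kind == "svm":
        svc = SVC(kernel="rbf", C=hp.pop("C", 1.0), gamma=hp.pop("gamma", "scale"), **hp)
        return OneVsRestClassifier(svc) if n_classes > 2 else svc
    if model_kind == "rf":
        return RandomForestClassifier(
            n_estimators=hp.pop("n_estimators", 500),
            bootstrap=True,
            random_state=seed,
            **hp,
        )
    raise ValueError(f"unknown model kind {model_kind!r}; expected one of {MODEL_KINDS}")


def _make_pipeline(model) -> Pipeline:
    return Pipeline(
        [
            ("impute", SimpleImputer(strategy="median")),
            ("scale", StandardScaler()),
            ("model", model),
        ]
    )


def train_classifier(
    split: DataSplit,
    model_kind: str,
    hyperparams: dict | None = None,
    seed: int = 0,
) -> tuple[Pipeline, float]:
    """Fit the model on the training rows; report mean 5-fold CV accuracy.

    Imputation and standardization are fitted inside each fold (and on
    the full training set for the final model), so no test information
    leaks into the scaler. A degenerate fold (single class) triggers a
    re-draw of the folds with the next seed, logged.
    """
    xtr = split.x_train.to_numpy(dtype=float)
    ytr = split.y_train
    n_classes = len(set(ytr))
    folds = split.folds
    for attempt in range(5):
        if all(len(set(ytr[tr])) > 1 for tr, _ in folds):
            break
        log.warning("degenerate CV fold; re-drawing folds with seed %d", seed + attempt + 1)
        skf = StratifiedKFold(n_splits=len(folds), shuffle=True,
                              random_state=seed + attempt + 1)
        folds = list(skf.split(xtr, ytr))
    accs = []
    for tr, va in folds:
        pipe = _make_pipeline(_make_model(model_kind, hyperparams, seed, n_classes))
        pipe.fit(xtr[tr], ytr[tr])
        accs.append(float(np.mean(pipe.predict(xtr[va]) == ytr[va])))
    final = _make_pipeline(_make_model(model_kind, hyperparams, seed, n_classes))
    final.fit(xtr, ytr)
    return final, float(np.mean(accs))


def evaluate_on_test(split: DataSplit, model: Pipeline) -> dict:
    """Confusion counts and the metric suite on the held-out 30%.

    Binary schemes report one MetricsReport with the task group as the
    positive class; MSet reports the K×K matrix (rows predicted,
    columns actual) plus per-class one-vs-rest reports.
    """
    y_pred = model.predict(split.x_test.to_numpy(dtype=float))
    y_true = split.y_test
    classes = sorted(set(y_true) | set(y_pred))
    matrix, labels = confusion_from_predictions(y_true, y_pred, class_order=classes)
    out: dict = {"classes": labels, "matrix": matrix}
    if len(labels) == 2:
        pos = labels.index("task_group") if "task_group" in labels else 1
        neg = 1 - pos
        counts = ConfusionCounts(
            tp=int(matrix[pos, pos]),
            fp=int(matrix[pos, neg]),
            fn=int(matrix[neg, pos]),
            tn=int(matrix[neg, neg]),
        )
        out["report"] = compute_metrics(counts)
    else:
        out["per_class"] = evaluate_multiclass_ovr(matrix, labels)
    return out


def scenario_wise_eval(
    table: pd.DataFrame,
    scheme: str,
    model_kind: str,
    seed: int = 0,
    feature_columns: list[str] | None = None,
    hyperparams: dict | None = None,
) -> dict[str, dict]:
    """Run the split→train→test pipeline independently per scenario.

    Scenarios whose subset collapses to one class are skipped with a
    warning. Returns {scenario: evaluation dict}.
    """
    out = {}
    for scenario, sub in table.groupby("scenario"):
        mapped = map_labels(sub["task"], scheme)
        if mapped.nunique() < 2 or mapped.value_counts().min() < 10:
            warnings.warn(f"scenario {scenario}: too few labelled rows, skipped")
            continue
        split = build_datasets(sub.reset_index(drop=True), scheme, seed=seed,
                               feature_columns=feature_columns)
        model, cv_acc = train_classifier(split, model_kind, hyperparams, seed=seed)
        ev = evaluate_on_test(split, model)
        ev["cv_accuracy"] = cv_acc
        out[scenario] = ev
    return out


def run_experiment(
    table: pd.DataFrame,
    scheme: str,
    model_kind: str,
    seed: int = 0,
    feature_columns: list[str] | None = None,
    hyperparams: dict | None = None,
) -> dict:
    """split → train (5-fold CV) → held-out evaluation, one call."""
    split = build_datasets(table, scheme, seed=seed, feature_columns=feature_columns)
    model, cv_acc = train_classifier(split, model_kind, hyperparams, seed=seed)
    ev = evaluate_on_test(split, model)
    ev["cv_accuracy"] = cv_acc
    ev["scheme"] = scheme
    ev["model_kind"] = model_kind
    ev["n_train"] = len(split.x_train)
    ev["n_test"] = len(split.x_test)
    return ev
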