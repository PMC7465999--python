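"""Feature selection: SFFS over the EEG block, permutation MDA elsewhere.

The 270 EEG band-power/ratio columns come from neighbouring electrodes
and are heavily redundant, so they get a wrapper search: sequential
forward floating selection (SFFS) wrapped around a Gaussian-kernel SVM,
scored by cross-validated ``scr = 2·sin(π·sen/2)·sin(π·spe/2)`` — a
bounded score in [0, 2] that is zero when either sensitivity or
specificity collapses, so the wrapper cannot buy accuracy on the
majority class alone. For multiclass labels the score is macro-averaged
over one-vs-rest reductions.

The remaining (EOG/ECG/GSR/respiration/vehicular) columns are ranked by
random-forest permutation importance (mean decrease accuracy, MDA) on a
held-out validation split, and columns with strictly positive mean
importance are kept.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .metrics import confusion_from_predictions, ovr_counts

log = logging.getLogger(__name__)

__all__ = [
    "selection_score",
    "SelectionResult",
    "sffs_select",
    "mda_importance",
    "select_features",
    "make_scr_evaluator",
]


def selection_score(sen: float, spe: float) -> float:
    """scr = 2·sin(π·sen/2)·sin(π·spe/2), in [0, 2].

    Monotone in both arguments, 0 whenever either is 0, and 2 only at
    sen = spe = 1, so it rewards balanced class-wise performance.
    """
    if not (0.0 <= sen <= 1.0 and 0.0 <= spe <= 1.0):
        raise ValueError(f"sen and spe must lie in [0, 1], got {sen}, {spe}")
    return 2.0 * math.sin(math.pi * sen / 2.0) * math.sin(math.pi * spe / 2.0)


def _scr_from_predictions(y_true, y_pred) -> float:
    """scr for binary labels; macro-averaged one-vs-rest scr otherwise."""
    m, labels = confusion_from_predictions(y_true, y_pred)
    scores = []
    for i in range(len(labels)):
        c = ovr_counts(m, i)
        sen = c.tp / (c.tp + c.fn) if c.tp + c.fn else 0.0
        spe = c.tn / (c.tn + c.fp) if c.tn + c.fp else 0.0
        scores.append(selection_score(sen, spe))
    if len(labels) == 2:
        # binary: the two OVR reductions are mirror images; report one scr
        return scores[-1]
    return float(np.mean(scores))


def make_scr_evaluator(n_splits: int = 5, seed: int = 0, C: float = 1.0):
    """Cross-validated SVM evaluator returning mean scr over folds."""

    def evaluate(x: np.ndarray, y: np.ndarray) -> float:
        skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
        scores = []
        for tr, va in skf.split(x, y):
            clf = make_pipeline(StandardScaler(), SVC(kernel="rbf", C=C, gamma="scale"))
            clf.fit(x[tr], y[tr])
            scores.append(_scr_from_predictions(y[va], clf.predict(x[va])))
        return float(np.mean(scores))

    return evaluate


@dataclass
class SelectionResult:
    """Outcome of one SFFS run."""

    selected: list[str]
    trajectory: list[tuple[int, float]]  # (subset size, best score at that size)
    best_per_size: dict = field(default_factory=dict)  # size -> (score, names)
    settings: dict = field(default_factory=dict)
    seed: int = 0

    @property
    def best_score(self) -> float:
        return max((s for _, s in self.trajectory), default=float("nan"))


def sffs_select(
    table: pd.DataFrame,
    candidate_columns: list[str],
    target: str = "task",
    evaluator=None,
    max_size: int = 15,
    seed: int = 0,
) -> SelectionResult:
    """Sequential forward floating selection over the candidate columns.

    Classic SFFS semantics: each forward step adds the single best
    candidate; after every inclusion, backward steps remove a member
    while doing so *strictly improves* the best score known at the
    smaller size. Stops at ``max_size`` or when a forward step no longer
    improves on the best score seen at the target size. Ties between
    candidates break by column order. An evaluator failure on a subset
    scores that subset 0 and is logged.
    """
    missing = [c for c in candidate_columns if c not in table.columns]
    if missing:
        raise ValueError(f"candidate columns not in table: {missing[:5]}")
    y = table[target].to_numpy()
    if len(set(y)) < 2:
        raise ValueError("need at least 2 classes for selection")
    if evaluator is None:
        evaluator = make_scr_evaluator(seed=seed)
    xall = table[candidate_columns].to_numpy(dtype=float)
    col_idx = {c: i for i, c in enumerate(candidate_columns)}

    def score(subset: tuple[str, ...]) -> float:
        cols = [col_idx[c] for c in subset]
        try:
            return evaluator(xall[:, cols], y)
        except Exception as exc:  # evaluator failure -> subset scored 0
            log.warning("evaluator failed on %s: %s", subset, exc)
            return 0.0

    cache: dict[tuple[str, ...], float] = {}

    def cached_score(subset: frozenset) -> float:
        key = tuple(sorted(subset))
        if key not in cache:
            cache[key] = score(key)
        return cache[key]

    current: frozenset = frozenset()
    best_at_size: dict[int, float] = {0: -np.inf}
    best_set_at_size: dict[int, frozenset] = {}
    trajectory: list[tuple[int, float]] = []

    while len(current) < max_size:
        remaining = [c for c in candidate_columns if c not in current]
        if not remaining:
            break
        # forward: best single addition (ties break by column order)
        scored = [(cached_score(current | {c}), c) for c in remaining]
        best_gain = max(s for s, _ in scored)
        add = next(c for s, c in scored if s == best_gain)
        current = current | {add}
        k = len(current)
        if best_gain > best_at_size.get(k, -np.inf):
            best_at_size[k] = best_gain
            best_set_at_size[k] = current
        else:
            # no improvement at this size: keep the known best and stop
            current = best_set_at_size.get(k, current)
            trajectory.append((k, best_at_size[k]))
            break
        trajectory.append((k, best_at_size[k]))

        # floating backward: drop members while that strictly improves
        # the best-known score at the smaller size
        while len(current) > 2:
            drops = [(cached_score(current - {c}), c) for c in sorted(current)]
            drop_score = max(s for s, _ in drops)
            kk = len(current) - 1
            if drop_score > best_at_size.get(kk, -np.inf):
                drop = next(c for s, c in drops if s == drop_score)
                current = current - {drop}
                best_at_size[kk] = drop_score
                best_set_at_size[kk] = current
                trajectory.append((kk, drop_score))
            else:
                break

    best_k = max(best_at_size, key=lambda k: (best_at_size[k], -k))
    selected_set = best_set_at_size.get(best_k, current)
    selected = [c for c in candidate_columns if c in selected_set]
    per_size = {
        k: (best_at_size[k], [c for c in candidate_columns if c in best_set_at_size[k]])
        for k in best_set_at_size
    }
    return SelectionResult(
        selected=selected,
        trajectory=trajectory,
        best_per_size=per_size,
        settings={"max_size": max_size, "target": target},
        seed=seed,
    )


def mda_importance(
    table: pd.DataFrame,
    columns: list[str],
    target: str = "task",
    model: RandomForestClassifier | None = None,
    n_repeats: int = 10,
    seed: int = 0,
    validation_fraction: float = 0.2,
) -> pd.Series:
    """Mean-decrease-accuracy importance per feature.

    Fits (or reuses) a random forest on a training portion, then on the
    held-out validation portion measures the mean drop in accuracy over
    ``n_repeats`` permutations of each column. Irrelevant columns score
    ~0; informative columns score positive.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    x = table[columns].to_numpy(dtype=float)
    y = table[target].to_numpy()
    xtr, xva, ytr, yva = train_test_split(
        x, y, test_size=validation_fraction, stratify=y, random_state=seed
    )
    if model is None:
        model = RandomForestClassifier(n_estimators=200, random_state=seed)
        model.fit(xtr, ytr)
    result = permutation_importance(
        model, xva, yva, scoring="accuracy", n_repeats=n_repeats, random_state=seed
    )
    return pd.Series(result.importances_mean, index=columns)


def select_features(
    table: pd.DataFrame,
    target: str = "task",
    max_eeg: int = 15,
    mda_repeats: int = 10,
    seed: int = 0,
    sffs_subsample: int | None = None,
) -> dict:
    """The full selection stage: SFFS on EEG columns, MDA on the rest.

    The table is split 80/20 (stratified); the 80% drives the SFFS
    wrapper and the forest fit, the 20% is the MDA validation set.
    Non-EEG columns with strictly positive mean decrease accuracy are
    kept. ``sffs_subsample`` optionally caps the rows used by the SFFS
    wrapper (the search cost is linear in rows × candidates).
    Returns a dict with ``eeg`` (SelectionResult), ``other``
    (importance Series) and ``selected`` (final column list).
    """
    from .features import eeg_feature_names, feature_names

    eeg_cols = [c for c in eeg_feature_names() if c in table.columns]
    other_cols = [
        c for c in feature_names() if c in table.columns and c not in eeg_cols
    ]
    sffs_table = table
    if sffs_subsample is not None and len(table) > sffs_subsample:
        sffs_table, _ = train_test_split(
            table,
            train_size=sffs_subsample,
            stratify=table[target],
            random_state=seed,
        )
    eeg_result = sffs_select(
        sffs_table, eeg_cols, target=target, max_size=max_eeg, seed=seed
    )
    importances = mda_importance(
        table, other_cols, target=target, n_repeats=mda_repeats, seed=seed
    )
    kept_other = [c for c in other_cols if importances[c] > 0]
    return {
        "eeg": eeg_result,
        "other": importances,
        "selected": eeg_result.selected + kept_other,
    }
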