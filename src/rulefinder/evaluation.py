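"""Small-sample ML validation harness for rule and descriptor matrices.

Implements the cross-validation protocol used to vet candidate features on
a ~36-sample dataset: stratified 5-fold CV with a tree ensemble, exhaustive
leave-one-out (LOO) evaluation repeated over several random seeds, balanced
leave-P-out splits (P = 4 with exactly 2 high + 2 low test samples), greedy
LOO-driven forward feature selection, recursive feature elimination with CV
(RFECV), per-feature attribution, and standard classification metrics with
``high`` as the positive class.

All randomness is seed-controlled; repeated runs with the same seed(s) are
bit-identical. Prediction ties in ensemble votes resolve to class 0 (low),
the sklearn argmax convention.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, clone
from sklearn.ensemble import ExtraTreesClassifier, RandomForestClassifier
from sklearn.feature_selection import RFECV, SelectorMixin
from sklearn.inspection import permutation_importance
from sklearn.metrics import (
    accuracy_score,
    f1_score,
    precision_score,
    recall_score,
    roc_auc_score,
)
from sklearn.model_selection import LeaveOneOut, StratifiedKFold

from .dataset import labels_to_int

__all__ = [
    "ModelSpec",
    "EvalReport",
    "make_model",
    "kfold_cv",
    "loo_eval",
    "lpo_balanced_splits",
    "forward_select",
    "ForwardSelector",
    "top_feature_frequency",
    "rfecv_select",
    "feature_importance",
    "ImportanceReport",
    "classification_report",
]

DEFAULT_SEEDS = tuple(range(9))


@dataclass(frozen=True)
class ModelSpec:
    """Tree-ensemble configuration; hyperparameters are deliberately plain.

    kind is ``extra_trees`` (the in-loop validator) or ``random_forest``
    (the benchmark model); 100 trees, unlimited depth by default.
    """

    kind: str = "extra_trees"
    n_estimators: int = 100
    max_depth: int | None = None

    def to_dict(self) -> dict:
        return {"kind": self.kind, "n_estimators": self.n_estimators, "max_depth": self.max_depth}


def make_model(spec: ModelSpec, seed: int) -> BaseEstimator:
    cls = {"extra_trees": ExtraTreesClassifier, "random_forest": RandomForestClassifier}.get(spec.kind)
    if cls is None:
        raise ValueError(f"unknown model kind: {spec.kind!r}")
    return cls(n_estimators=spec.n_estimators, max_depth=spec.max_depth, random_state=seed)


@dataclass
class EvalReport:
    """Cross-validation outcome: accuracies plus classification metrics.

    ``per_split`` holds one accuracy per (seed, split); ``accuracy_sd`` is
    the spread across seeds of the per-seed mean accuracy, and
    ``accuracy_sd_splits`` the spread across individual splits (both are
    reported because a "mean +/- sd" can be read either way).
    """

    design: str
    accuracy_mean: float
    accuracy_sd: float
    per_split: list[float]
    seeds: list[int]
    per_seed_accuracy: dict[int, float]
    accuracy_sd_splits: float = 0.0
    recall: float | None = None
    precision: float | None = None
    f1: float | None = None
    roc_auc: float | None = None
    importances: dict[str, float] = field(default_factory=dict)
    importance_backend: str | None = None
    model: dict = field(default_factory=dict)
    n_samples: int = 0
    flags: list[str] = field(default_factory=list)

    @property
    def n_splits_total(self) -> int:
        return len(self.per_split)


def _as_frame(features) -> pd.DataFrame:
    if isinstance(features, pd.DataFrame):
        return features.copy()
    arr = np.asarray(features)
    if arr.ndim == 1:
        arr = arr.reshape(-1, 1)
    return pd.DataFrame(arr, columns=[f"f{j}" for j in range(arr.shape[1])])


def _as_labels(labels) -> np.ndarray:
    y = np.asarray(labels)
    if y.dtype.kind in ("U", "S", "O"):
        return labels_to_int(list(y))
    return y.astype(int)


def _require_two_classes(y: np.ndarray) -> None:
    if len(np.unique(y)) < 2:
        raise ValueError("labels contain a single class; evaluation is undefined")


def _sd(values: np.ndarray) -> float:
    return float(np.std(values, ddof=1)) if values.size > 1 else 0.0


def kfold_cv(features, labels, model_spec: ModelSpec = ModelSpec(), seed: int = 0, k: int = 5) -> EvalReport:
    """Stratified k-fold (default 5) CV accuracy with a tree ensemble."""
    X = _as_frame(features)
    y = _as_labels(labels)
    _require_two_classes(y)
    if len(y) < k:
        raise ValueError(f"need at least k={k} samples, got {len(y)}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    per_split, y_pred, y_score = [], np.empty_like(y), np.empty(len(y), dtype=float)
    for train, test in skf.split(X, y):
        model = make_model(model_spec, seed).fit(X.iloc[train], y[train])
        pred = model.predict(X.iloc[test])
        y_pred[test] = pred
        y_score[test] = model.predict_proba(X.iloc[test])[:, 1]
        per_split.append(float(accuracy_score(y[test], pred)))
    cls = classification_report(y, y_pred, y_score)
    cls.pop("accuracy")
    return EvalReport(
        design=f"{k}-fold",
        accuracy_mean=float(np.mean(per_split)),
        accuracy_sd=_sd(np.asarray(per_split)),
        accuracy_sd_splits=_sd(np.asarray(per_split)),
        per_split=per_split,
        seeds=[seed],
        per_seed_accuracy={seed: float(np.mean(per_split))},
        model=model_spec.to_dict(),
        n_samples=len(y),
        **cls,
    )


def loo_eval(features, labels, model_spec: ModelSpec = ModelSpec(), seeds: Sequence[int] = DEFAULT_SEEDS) -> EvalReport:
    """Leave-one-out evaluation repeated across random seeds.

    Each seed produces n single-sample test splits; the per-seed accuracy is
    the fraction of left-out samples predicted correctly, and the headline
    accuracy is the mean +/- sd of the per-seed accuracies.
    """
    X = _as_frame(features)
    y = _as_labels(labels)
    _require_two_classes(y)
    if len(y) < 3:
        raise ValueError("leave-one-out needs at least 3 samples")
    seeds = list(seeds)
    per_split: list[float] = []
    per_seed: dict[int, float] = {}
    pooled_pred = np.empty((len(seeds), len(y)), dtype=int)
    pooled_score = np.empty((len(seeds), len(y)), dtype=float)
    for si, seed in enumerate(seeds):
        hits = []
        for train, test in LeaveOneOut().split(X):
            model = make_model(model_spec, seed).fit(X.iloc[train], y[train])
            pred = int(model.predict(X.iloc[test])[0])
            pooled_pred[si, test[0]] = pred
            pooled_score[si, test[0]] = float(model.predict_proba(X.iloc[test])[0, 1])
            hits.append(float(pred == y[test[0]]))
        per_split.extend(hits)
        per_seed[seed] = float(np.mean(hits))
    maj_pred = (pooled_pred.mean(axis=0) > 0.5).astype(int)
    cls = classification_report(y, maj_pred, pooled_score.mean(axis=0))
    cls.pop("accuracy")
    seed_acc = np.asarray(list(per_seed.values()))
    return EvalReport(
        design="loo",
        accuracy_mean=float(seed_acc.mean()),
        accuracy_sd=_sd(seed_acc),
        accuracy_sd_splits=_sd(np.asarray(per_split)),
        per_split=per_split,
        seeds=seeds,
        per_seed_accuracy=per_seed,
        model=model_spec.to_dict(),
        n_samples=len(y),
        **cls,
    )


def lpo_balanced_splits(
    labels, p: int = 4, n_splits: int = 50, seed: int = 0
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Balanced leave-P-out: test sets of p/2 high + p/2 low samples.

    Draws ``n_splits`` *distinct* test sets uniformly without replacement
    from all class-balanced p-subsets; returns (train_indices,
    test_indices) pairs. Raises when a class has fewer than p/2 members or
    when fewer than ``n_splits`` balanced subsets exist (stating the
    maximum).
    """
    if p % 2 != 0:
        raise ValueError("p must be even (test sets are class-balanced)")
    y = _as_labels(labels)
    half = p // 2
    highs = np.flatnonzero(y == 1)
    lows = np.flatnonzero(y == 0)
    if len(highs) < half or len(lows) < half:
        raise ValueError(f"need at least {half} samples per class, have {len(highs)} high / {len(lows)} low")
    total = math.comb(len(highs), half) * math.comb(len(lows), half)
    if n_splits > total:
        raise ValueError(f"requested {n_splits} splits but only {total} balanced test sets exist")
    high_combos = list(itertools.combinations(highs, half))
    low_combos = list(itertools.combinations(lows, half))
    rng = np.random.default_rng(seed)
    chosen = rng.choice(total, size=n_splits, replace=False)
    all_idx = np.arange(len(y))
    splits = []
    for flat in sorted(chosen.tolist()):
        hi = high_combos[flat // len(low_combos)]
        lo = low_combos[flat % len(low_combos)]
        test = np.asarray(sorted(hi + lo))
        train = np.setdiff1d(all_idx, test)
        splits.append((train, test))
    return splits


def _loo_accuracy(X: pd.DataFrame, y: np.ndarray, model_spec: ModelSpec, seed: int) -> float:
    hits = []
    for train, test in LeaveOneOut().split(X):
        model = make_model(model_spec, seed).fit(X.iloc[train], y[train])
        hits.append(float(model.predict(X.iloc[test])[0] == y[test[0]]))
    return float(np.mean(hits))


def forward_select(
    train_features,
    train_labels,
    model_spec: ModelSpec = ModelSpec(),
    max_features: int = 5,
    seed: int = 0,
    return_trace: bool = False,
):
    """Greedy forward feature selection scored by LOO accuracy.

    Starts empty and repeatedly adds the candidate feature that maximizes
    LOO accuracy on the training set, breaking ties by column order; stops
    when no candidate strictly improves the score or ``max_features`` is
    reached. Returns the ordered list of selected feature names (and, with
    ``return_trace``, the non-decreasing accuracy after each addition).
    """
    X = _as_frame(train_features)
    y = _as_labels(train_labels)
    if X.shape[1] < 1:
        raise ValueError("need at least one candidate feature")
    selected: list[str] = []
    trace: list[float] = []
    best_acc = -np.inf
    remaining = list(X.columns)
    while remaining and len(selected) < max_features:
        scores = [
            _loo_accuracy(X[selected + [cand]], y, model_spec, seed) for cand in remaining
        ]
        j = int(np.argmax(scores))  # argmax keeps the earliest column on ties
        if scores[j] <= best_acc:
            break
        best_acc = scores[j]
        selected.append(remaining.pop(j))
        trace.append(best_acc)
    return (selected, trace) if return_trace else selected


class ForwardSelector(SelectorMixin, BaseEstimator):
    """sklearn selector wrapping LOO-scored greedy forward selection."""

    def __init__(self, model_spec: ModelSpec = ModelSpec(), max_features: int = 5, seed: int = 0):
        self.model_spec = model_spec
        self.max_features = max_features
        self.seed = seed

    def fit(self, X, y):
        frame = _as_frame(X)
        self.feature_names_in_ = np.asarray(frame.columns, dtype=object)
        self.n_features_in_ = frame.shape[1]
        self.selected_, self.trace_ = forward_select(
            frame, y, self.model_spec, self.max_features, self.seed, return_trace=True
        )
        return self

    def _get_support_mask(self) -> np.ndarray:
        return np.isin(self.feature_names_in_, self.selected_)


def top_feature_frequency(selections: Sequence[Sequence[str]], top_k: int = 3) -> dict[str, int]:
    """Count how often each feature appears in the first top_k positions."""
    counts: dict[str, int] = {}
    for sel in selections:
        for name in list(sel)[:top_k]:
            counts[name] = counts.get(name, 0) + 1
    return counts


def rfecv_select(features, labels, model_spec: ModelSpec = ModelSpec(), seed: int = 0) -> list[str]:
    """Recursive feature elimination (step 1) scored by 5-fold CV accuracy."""
    X = _as_frame(features)
    y = _as_labels(labels)
    _require_two_classes(y)
    if X.shape[1] < 2:
        raise ValueError("RFECV needs at least 2 features")
    cv = StratifiedKFold(n_splits=5, shuffle=True, random_state=seed)
    rfecv = RFECV(make_model(model_spec, seed), step=1, cv=cv, scoring="accuracy", min_features_to_select=1)
    rfecv.fit(X, y)
    return [c for c, keep in zip(X.columns, rfecv.support_) if keep]


@dataclass(frozen=True)
class ImportanceReport:
    """Per-feature attribution with the backend that produced it."""

    values: dict[str, float]
    backend: str


def feature_importance(
    model_spec: ModelSpec,
    features,
    labels,
    seed: int = 0,
    backend: str = "auto",
    n_repeats: int = 20,
) -> ImportanceReport:
    """Per-feature attribution of a fitted ensemble.

    ``backend="shap"`` uses tree Shapley values on the positive-class
    probability (mean absolute value per feature) and requires the optional
    ``shap`` package; ``"permutation"`` uses seeded permutation importance
    of accuracy; ``"auto"`` prefers shap when importable.
    """
    X = _as_frame(features)
    y = _as_labels(labels)
    model = make_model(model_spec, seed).fit(X, y)
    if backend == "auto":
        try:
            import shap  # noqa: F401

            backend = "shap"
        except ImportError:
            backend = "permutation"
    if backend == "shap":
        import shap

        explainer = shap.TreeExplainer(model)
        sv = explainer.shap_values(X)
        if isinstance(sv, list):  # one array per class
            sv = sv[1]
        elif np.ndim(sv) == 3:
            sv = sv[:, :, 1]
        vals = np.abs(np.asarray(sv)).mean(axis=0)
    elif backend == "permutation":
        res = permutation_importance(model, X, y, n_repeats=n_repeats, random_state=seed, scoring="accuracy")
        vals = res.importances_mean
    else:
        raise ValueError(f"unknown importance backend: {backend!r}")
    return ImportanceReport(values={c: float(v) for c, v in zip(X.columns, vals)}, backend=backend)


def classification_report(y_true, y_pred, y_score=None) -> dict:
    """Accuracy, recall, precision, F1 and ROC-AUC with high (1) positive.

    ROC-AUC is None (flagged upstream) when the truth is single-class or no
    scores are given.
    """
    y_true = _as_labels(y_true)
    y_pred = _as_labels(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    out = {
        "accuracy": float(accuracy_score(y_true, y_pred)),
        "recall": float(recall_score(y_true, y_pred, pos_label=1, zero_division=0)),
        "precision": float(precision_score(y_true, y_pred, pos_label=1, zero_division=0)),
        "f1": float(f1_score(y_true, y_pred, pos_label=1, zero_division=0)),
        "roc_auc": None,
    }
    if y_score is not None and len(np.unique(y_true)) == 2:
        out["roc_auc"] = float(roc_auc_score(y_true, np.asarray(y_score, dtype=float)))
    return out
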