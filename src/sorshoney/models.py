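"""Classifier and regressor families for adulteration prediction.

Four classifier families — PLS-DA, random forest, ordinal random forest and
XGBoost — plus a random-forest regressor for the adulteration level as a
continuous % w/w.  All fits are deterministic functions of (data, config,
seed); predictions are always members of the declared class set, with ties
broken by the first class in declared order.

The ordinal forest is the Frank-Hall cumulative decomposition: K-1 binary
forests model P(y > c_k) for the ordered classes c_1 < ... < c_K, the
cumulative probabilities are made monotone (non-increasing in k) by a
running maximum from the top class downwards, and the prediction is
1 + #{k : P(y > c_k) > 0.5}.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.cross_decomposition import PLSRegression
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.model_selection import StratifiedKFold, train_test_split
from xgboost import XGBClassifier


class TaskError(ValueError):
    """Task/label structure unusable for the requested model."""


class UnsupportedModelError(NotImplementedError):
    """Requested quantity not provided by this algorithm."""


# ---------------------------------------------------------------------------
# tasks

@dataclass(frozen=True)
class ClassTask:
    """A classification scheme: ordered classes + label assignment rule.

    ``level_map`` sends the metadata pair (adulterant kind, level % w/w) to a
    class label; class order is the declared order used for tie-breaking and
    for the ordinal decomposition.
    """

    scheme: str
    classes: tuple[str, ...]
    adulterants: tuple[str, ...]
    level_map: Mapping[tuple[str, float], str] = field(hash=False)

    def label(self, adulterant: str, level_pct: float) -> str:
        key = (adulterant, float(level_pct))
        if key not in self.level_map:
            raise TaskError(f"({adulterant}, {level_pct}%) not part of task {self.scheme!r}")
        return self.level_map[key]


@dataclass(frozen=True)
class RegressionTask:
    """Continuous adulteration-level prediction for the given syrup kinds."""

    adulterants: tuple[str, ...]
    scheme: str = "level_regression"


def five_level_task(kind: str, levels: Sequence[float] = (10.0, 20.0, 30.0, 50.0)) -> ClassTask:
    """Pure honey vs the four spiking levels of one syrup, ordered by level."""
    levels = tuple(float(v) for v in levels)
    classes = ("pure",) + tuple(f"{kind}_{v:g}" for v in levels)
    level_map = {("none", 0.0): "pure"}
    level_map.update({(kind, v): f"{kind}_{v:g}" for v in levels})
    return ClassTask("five_level_single_syrup", classes, (kind,), level_map)


def combined_task(levels: Sequence[float] = (10.0, 20.0, 30.0, 50.0)) -> ClassTask:
    """Pure + (rice, sugar_beet) x levels: 9 classes identifying kind and level."""
    levels = tuple(float(v) for v in levels)
    kinds = ("rice", "sugar_beet")
    classes = ("pure",) + tuple(f"{k}_{v:g}" for k in kinds for v in levels)
    level_map = {("none", 0.0): "pure"}
    for k in kinds:
        level_map.update({(k, v): f"{k}_{v:g}" for v in levels})
    return ClassTask("nine_level_combined", classes, kinds, level_map)


def binary_task(kind: str = "sugar_cane", levels: Sequence[float] = (20.0, 40.0, 60.0)) -> ClassTask:
    """Pure vs adulterated, collapsing all spiking levels."""
    level_map = {("none", 0.0): "pure"}
    level_map.update({(kind, float(v)): "adulterated" for v in levels})
    return ClassTask("binary_pure_vs_adulterated", ("pure", "adulterated"), (kind,), level_map)


def ordinal_levels_task(kind: str = "sugar_cane", levels: Sequence[float] = (20.0, 40.0, 60.0)) -> ClassTask:
    """Pure < low < medium < high ordinal levels (heather-style design)."""
    levels = tuple(sorted(float(v) for v in levels))
    names = ("low", "medium", "high")
    if len(levels) != 3:
        names = tuple(f"level_{v:g}" for v in levels)
    level_map = {("none", 0.0): "pure"}
    level_map.update({(kind, v): n for v, n in zip(levels, names)})
    return ClassTask("ordinal_levels", ("pure",) + names, (kind,), level_map)


def labels_for(task: ClassTask, meta) -> np.ndarray:
    """Class label for every metadata row."""
    return np.array([task.label(a, l) for a, l in zip(meta["adulterant"], meta["level_pct"])])


# ---------------------------------------------------------------------------
# configs and the fitted-model container

@dataclass
class RFConfig:
    n_trees: int = 500
    tune: bool = True
    grid: tuple[str, ...] = ("sqrt", "third", "tenth")  # features-per-split candidates
    cv_folds: int = 5
    tune_trees: int = 100  # forest size during grid search; final refit uses n_trees
    max_features: str | int = "sqrt"  # used when tune=False


@dataclass
class XGBConfig:
    n_rounds: int = 200
    max_depth: int = 3
    learning_rate: float = 0.1
    early_stopping_rounds: int = 10
    val_fraction: float = 0.2


@dataclass
class FittedModel:
    algorithm: str
    classes: tuple[str, ...] | None
    estimators: list
    importance: np.ndarray | None = None
    extra: dict = field(default_factory=dict)


def _check_classes(y: np.ndarray, classes: Sequence[str] | None) -> tuple[str, ...]:
    present = list(dict.fromkeys(y))
    if len(present) < 2:
        raise TaskError(f"need >= 2 classes present, got {present}")
    if classes is None:
        return tuple(sorted(present))
    missing = set(present) - set(classes)
    if missing:
        raise TaskError(f"labels outside declared classes: {sorted(missing)}")
    return tuple(classes)


def _grid_values(grid: Sequence[str | int], p: int) -> list[int]:
    mapped = []
    for g in grid:
        if g == "sqrt":
            v = int(round(np.sqrt(p)))
        elif g == "third":
            v = p // 3
        elif g == "tenth":
            v = p // 10
        else:
            v = int(g)
        mapped.append(max(1, min(v, p)))
    return list(dict.fromkeys(mapped))


def _proba_argmax(proba: np.ndarray, est_classes: Sequence[str], declared: Sequence[str]) -> np.ndarray:
    """Argmax over class probabilities in *declared* order (first-max ties)."""
    col = {c: i for i, c in enumerate(est_classes)}
    aligned = np.zeros((proba.shape[0], len(declared)))
    for j, c in enumerate(declared):
        if c in col:
            aligned[:, j] = proba[:, col[c]]
    idx = np.argmax(aligned, axis=1)
    return np.asarray(declared, dtype=object)[idx]


# ---------------------------------------------------------------------------
# PLS-DA

def fit_plsda(X: np.ndarray, y: np.ndarray, max_ncomp: int = 10, *,
              classes: Sequence[str] | None = None, cv_folds: int = 5, seed: int = 0) -> FittedModel:
    """PLS regression on one-hot class indicators, used as a classifier.

    The number of latent components is chosen by internal stratified CV
    accuracy over 1..max_ncomp; class decision is the max predicted
    indicator score, ties to the first class in declared order.
    """
    X, y = np.asarray(X, dtype=float), np.asarray(y, dtype=object)
    declared = _check_classes(y, classes)
    Y = np.column_stack([(y == c).astype(float) for c in declared])
    cap = min(max_ncomp, X.shape[1], X.shape[0] - 1)
    _, counts = np.unique(y, return_counts=True)
    folds = min(cv_folds, counts.min())
    best_k, best_acc = 1, -1.0
    if folds >= 2:
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        split_idx = list(skf.split(X, y))
        for k in range(1, cap + 1):
            correct = 0
            for tr, te in split_idx:
                kk = min(k, len(tr) - 1, X.shape[1])
                pls = PLSRegression(n_components=kk, scale=False).fit(X[tr], Y[tr])
                pred = _plsda_predict(pls, X[te], declared)
                correct += int(np.sum(pred == y[te]))
            acc = correct / len(y)
            if acc > best_acc:
                best_k, best_acc = k, acc
    else:
        best_k = cap
    pls = PLSRegression(n_components=best_k, scale=False).fit(X, Y)
    return FittedModel("plsda", declared, [pls], importance=None,
                       extra={"n_components": best_k, "cv_accuracy": best_acc})


def _plsda_predict(pls: PLSRegression, X: np.ndarray, declared: Sequence[str]) -> np.ndarray:
    scores = pls.predict(X)
    idx = np.argmax(scores, axis=1)
    return np.asarray(declared, dtype=object)[idx]


# ---------------------------------------------------------------------------
# random forests

def fit_rf(X: np.ndarray, y: np.ndarray, config: RFConfig | None = None, *,
           classes: Sequence[str] | None = None, seed: int = 0) -> FittedModel:
    """Random-forest classifier with features-per-split tuned by internal CV.

    Impurity importances are retained, rescaled so the top feature is 100.
    """
    config = config or RFConfig()
    X, y = np.asarray(X, dtype=float), np.asarray(y, dtype=object)
    declared = _check_classes(y, classes)
    p = X.shape[1]
    candidates = _grid_values(config.grid, p)
    chosen = candidates[0]
    if config.tune and len(candidates) > 1:
        _, counts = np.unique(y, return_counts=True)
        folds = min(config.cv_folds, counts.min())
        if folds >= 2:
            skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
            split_idx = list(skf.split(X, y))
            best_acc = -1.0
            for mf in candidates:
                correct = 0
                for tr, te in split_idx:
                    rf = RandomForestClassifier(
                        n_estimators=config.tune_trees, max_features=mf,
                        random_state=seed, n_jobs=1,
                    ).fit(X[tr], y[tr])
                    pred = _proba_argmax(rf.predict_proba(X[te]), rf.classes_, declared)
                    correct += int(np.sum(pred == y[te]))
                acc = correct / len(y)
                if acc > best_acc:
                    chosen, best_acc = mf, acc
    elif not config.tune:
        chosen = config.max_features if isinstance(config.max_features, int) else _grid_values([config.max_features], p)[0]
    rf = RandomForestClassifier(
        n_estimators=config.n_trees, max_features=chosen, random_state=seed, n_jobs=1,
    ).fit(X, y)
    imp = _scale_importance(rf.feature_importances_)
    return FittedModel("rf", declared, [rf], importance=imp, extra={"max_features": chosen})


class _ConstantProb:
    """Stand-in binary model for a degenerate (single-class) cumulative split."""

    def __init__(self, prob: float, n_features: int):
        self.prob = float(prob)
        self.feature_importances_ = np.zeros(n_features)

    def predict_gt(self, X: np.ndarray) -> np.ndarray:
        return np.full(X.shape[0], self.prob)


def fit_rf_ordinal(X: np.ndarray, y: np.ndarray, config: RFConfig | None = None, *,
                   classes: Sequence[str], seed: int = 0) -> FittedModel:
    """Frank-Hall ordinal forest over the declared (ordered) classes."""
    config = config or RFConfig()
    X, y = np.asarray(X, dtype=float), np.asarray(y, dtype=object)
    declared = _check_classes(y, classes)
    if classes is None or len(classes) < 2:
        raise TaskError("ordinal task needs a declared class order")
    rank = {c: i for i, c in enumerate(declared)}
    ranks = np.array([rank[c] for c in y])
    mf = _grid_values([config.max_features], X.shape[1])[0]
    forests: list = []
    for k in range(len(declared) - 1):
        target = (ranks > k).astype(int)
        if target.min() == target.max():
            forests.append(_ConstantProb(float(target[0]), X.shape[1]))
            continue
        rf = RandomForestClassifier(
            n_estimators=config.n_trees, max_features=mf, random_state=seed, n_jobs=1,
        ).fit(X, target)
        forests.append(rf)
    imps = [f.feature_importances_ for f in forests]
    imp = _scale_importance(np.mean(imps, axis=0))
    return FittedModel("rf_ordinal", declared, forests, importance=imp, extra={"max_features": mf})


def _ordinal_cumulative(model: FittedModel, X: np.ndarray) -> np.ndarray:
    """P(y > c_k) for k = 0..K-2, made non-increasing in k."""
    probs = []
    for f in model.estimators:
        if isinstance(f, _ConstantProb):
            probs.append(f.predict_gt(X))
        else:
            pr = f.predict_proba(X)
            col = list(f.classes_).index(1)
            probs.append(pr[:, col])
    cum = np.column_stack(probs)
    for k in range(cum.shape[1] - 2, -1, -1):
        cum[:, k] = np.maximum(cum[:, k], cum[:, k + 1])
    return cum


def fit_rf_regression(X: np.ndarray, level_pct: np.ndarray, config: RFConfig | None = None, *,
                      seed: int = 0) -> FittedModel:
    """Random-forest regression of the adulteration level (% w/w)."""
    config = config or RFConfig()
    X = np.asarray(X, dtype=float)
    yv = np.asarray(level_pct, dtype=float)
    if np.unique(yv).size < 2:
        raise TaskError("constant regression target")
    rf = RandomForestRegressor(n_estimators=config.n_trees, random_state=seed, n_jobs=1).fit(X, yv)
    imp = _scale_importance(rf.feature_importances_)
    return FittedModel("rf_regression", None, [rf], importance=imp)


# ---------------------------------------------------------------------------
# XGBoost

def fit_xgboost(X: np.ndarray, y: np.ndarray, config: XGBConfig | None = None, *,
                classes: Sequence[str] | None = None, seed: int = 0) -> FittedModel:
    """Gradient-boosted trees with a softmax objective and early stopping.

    An internal stratified validation fold drives early stopping; if the
    class counts cannot support a stratified carve-out, the full round
    budget is used instead.
    """
    config = config or XGBConfig()
    X, y = np.asarray(X, dtype=float), np.asarray(y, dtype=object)
    declared = _check_classes(y, classes)
    code = {c: i for i, c in enumerate(declared)}
    yi = np.array([code[c] for c in y])
    _, counts = np.unique(yi, return_counts=True)
    use_es = counts.min() >= 2 and config.early_stopping_rounds > 0
    params = dict(
        n_estimators=config.n_rounds, max_depth=config.max_depth,
        learning_rate=config.learning_rate, random_state=seed, n_jobs=1,
        num_class=len(declared), objective="multi:softprob",
    )
    if use_es:
        Xtr, Xval, ytr, yval = train_test_split(
            X, yi, test_size=config.val_fraction, stratify=yi, random_state=seed,
        )
        if np.unique(ytr).size == len(declared):
            clf = XGBClassifier(**params, early_stopping_rounds=config.early_stopping_rounds)
            clf.fit(Xtr, ytr, eval_set=[(Xval, yval)], verbose=False)
        else:
            use_es = False
    if not use_es:
        clf = XGBClassifier(**params)
        clf.fit(X, yi, verbose=False)
    imp = _scale_importance(clf.feature_importances_)
    return FittedModel("xgboost", declared, [clf], importance=imp,
                       extra={"early_stopping": use_es})


# ---------------------------------------------------------------------------
# prediction and importance

def predict(model: FittedModel, X: np.ndarray) -> np.ndarray:
    """Class labels or clipped level predictions for new spectra."""
    X = np.asarray(X, dtype=float)
    if model.algorithm == "plsda":
        return _plsda_predict(model.estimators[0], X, model.classes)
    if model.algorithm == "rf":
        rf = model.estimators[0]
        return _proba_argmax(rf.predict_proba(X), rf.classes_, model.classes)
    if model.algorithm == "rf_ordinal":
        cum = _ordinal_cumulative(model, X)
        rank = np.sum(cum > 0.5, axis=1)
        return np.asarray(model.classes, dtype=object)[rank]
    if model.algorithm == "xgboost":
        proba = model.estimators[0].predict_proba(X)
        return np.asarray(model.classes, dtype=object)[np.argmax(proba, axis=1)]
    if model.algorithm == "rf_regression":
        return np.clip(model.estimators[0].predict(X), 0.0, 100.0)
    raise UnsupportedModelError(model.algorithm)


def predict_proba(model: FittedModel, X: np.ndarray) -> np.ndarray:
    """Per-class probabilities (columns in declared class order)."""
    X = np.asarray(X, dtype=float)
    if model.algorithm == "xgboost":
        return model.estimators[0].predict_proba(X)
    if model.algorithm == "rf":
        rf = model.estimators[0]
        col = {c: i for i, c in enumerate(rf.classes_)}
        pr = rf.predict_proba(X)
        out = np.zeros((X.shape[0], len(model.classes)))
        for j, c in enumerate(model.classes):
            if c in col:
                out[:, j] = pr[:, col[c]]
        return out
    raise UnsupportedModelError(f"{model.algorithm} does not expose class probabilities")


def _scale_importance(raw: np.ndarray) -> np.ndarray:
    raw = np.asarray(raw, dtype=float)
    top = raw.max()
    return raw * (100.0 / top) if top > 0 else raw


def variable_importance(model: FittedModel, axis: np.ndarray) -> list[tuple[float, float]]:
    """Descending (wavenumber, importance) pairs, top importance = 100."""
    if model.importance is None:
        raise UnsupportedModelError(f"{model.algorithm} provides no variable importance")
    axis = np.asarray(axis, dtype=float)
    if axis.size != model.importance.size:
        raise TaskError(f"axis length {axis.size} != importance length {model.importance.size}")
    order = np.argsort(-model.importance, kind="stable")
    return [(float(axis[i]), float(model.importance[i])) for i in order]
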