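"""Leave-two-honey-types-out experiments and the error taxonomy.

Generalisation to unseen botanical origins is the point of the validation
scheme: every split withholds whole honey types (their pure and spiked
samples together), so a classifier can never have seen the test honeys'
base fingerprints.  For 14 types with 2 held out this yields C(14,2) = 91
splits, 10 test predictions each for a single-syrup task (910 in total, 182
of them on pure honey).

Errors are partitioned into:

* hard — pure honey predicted adulterated, or adulterated honey predicted
  pure (the commercially serious mistakes), reported as separate rates;
* soft — adulterated honey predicted adulterated but at the wrong level
  (or, in the combined task, the wrong adulterant at any level).

Rate denominators: the pure rate is over all pure-honey predictions, the
adulterated-as-pure and soft rates over all adulterated predictions, and
the total error over all predictions.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedShuffleSplit

from . import models
from .models import ClassTask, RFConfig, RegressionTask, TaskError, XGBConfig
from .spectra_io import SpectraSet


class DesignError(ValueError):
    pass


@dataclass(frozen=True)
class SplitPlan:
    """All leave-k-types-out partitions, at honey-type granularity."""

    splits: tuple[tuple[tuple[str, ...], tuple[str, ...]], ...]  # (train, test) pairs
    k_test: int


def enumerate_splits(honey_types: Sequence[str], k_test: int = 2) -> SplitPlan:
    """Every unordered choice of ``k_test`` held-out types, lexicographic."""
    types = sorted(honey_types)
    if len(set(types)) != len(types):
        raise DesignError("duplicate honey types")
    if not 0 < k_test < len(types):
        raise DesignError(f"k_test must be in (0, {len(types)}), got {k_test}")
    splits = []
    for test in itertools.combinations(types, k_test):
        train = tuple(t for t in types if t not in test)
        splits.append((train, test))
    return SplitPlan(tuple(splits), k_test)


def _task_mask(sset: SpectraSet, adulterants: tuple[str, ...]) -> np.ndarray:
    meta = sset.meta
    return ((meta["role"] == "honey")
            & meta["adulterant"].isin(("none",) + adulterants)).to_numpy()


def _check_design(meta: pd.DataFrame, task: ClassTask | RegressionTask) -> None:
    """Every honey type must carry the full pure + adulterant x level grid."""
    if isinstance(task, ClassTask):
        expected = {k for k in task.level_map if k != ("none", 0.0)}
    else:
        expected = set()
        for adu in task.adulterants:
            expected |= _levels_of(meta, adu)
    for honey_type, grp in meta.groupby("honey_type"):
        have = set(zip(grp["adulterant"], grp["level_pct"]))
        if ("none", 0.0) not in have:
            raise DesignError(f"honey type {honey_type!r} lacks a pure sample")
        gaps = expected - have
        if gaps:
            raise DesignError(f"honey type {honey_type!r} missing conditions: {sorted(gaps)}")


def _levels_of(meta: pd.DataFrame, adulterant: str) -> set[tuple[str, float]]:
    sub = meta[meta["adulterant"] == adulterant]
    return {(adulterant, float(lv)) for lv in sub["level_pct"].unique()}


def run_experiment(
    sset: SpectraSet,
    task: ClassTask | RegressionTask,
    algorithm: str,
    plan: SplitPlan,
    seed: int = 0,
    *,
    rf_config: RFConfig | None = None,
    xgb_config: XGBConfig | None = None,
) -> pd.DataFrame:
    """Train/predict over every split of the plan; returns the prediction log.

    The input must already be preprocessed and replicate-averaged (one row
    per sample).  Rows irrelevant to the task (other adulterants, syrup or
    blank measurements) are dropped before splitting.
    """
    mask = _task_mask(sset, task.adulterants)
    sub = sset.select(mask)
    _check_design(sub.meta, task)
    X = sub.intensities
    types = sub.meta["honey_type"].to_numpy()
    regression = isinstance(task, RegressionTask)
    if regression:
        truth = sub.meta["level_pct"].to_numpy(dtype=float)
    else:
        truth = models.labels_for(task, sub.meta)

    split_seeds = (np.random.SeedSequence(seed).generate_state(len(plan.splits)) % (2**31)).astype(int)
    records = []
    for i, (train_types, test_types) in enumerate(plan.splits):
        if set(train_types) & set(test_types):
            raise DesignError("split has overlapping train/test types")
        tr = np.isin(types, train_types)
        te = np.isin(types, test_types)
        s = int(split_seeds[i])
        if regression:
            model = models.fit_rf_regression(X[tr], truth[tr], rf_config, seed=s)
        elif algorithm == "plsda":
            model = models.fit_plsda(X[tr], truth[tr], classes=task.classes, seed=s)
        elif algorithm == "rf":
            model = models.fit_rf(X[tr], truth[tr], rf_config, classes=task.classes, seed=s)
        elif algorithm == "rf_ordinal":
            model = models.fit_rf_ordinal(X[tr], truth[tr], rf_config, classes=task.classes, seed=s)
        elif algorithm == "xgboost":
            model = models.fit_xgboost(X[tr], truth[tr], xgb_config, classes=task.classes, seed=s)
        else:
            raise TaskError(f"unknown algorithm {algorithm!r}")
        pred = models.predict(model, X[te])
        for sid, htype, yt, yp in zip(sub.meta.loc[te, "sample_id"], types[te], truth[te], pred):
            records.append(
                {
                    "sample_id": sid, "honey_type": htype, "split_index": i,
                    "algorithm": "rf_regression" if regression else algorithm,
                    ("true_level" if regression else "true_class"): yt,
                    ("predicted_level" if regression else "predicted_class"): yp,
                }
            )
    return pd.DataFrame(records)


# ---------------------------------------------------------------------------
# metrics

@dataclass
class MetricsSummary:
    """Hard/soft misclassification rates with their counts and denominators."""

    n_total: int
    n_pure: int
    n_adulterated: int
    n_correct: int
    n_pure_as_adulterated: int
    n_adulterated_as_pure: int
    n_soft: int
    pure_as_adulterated_pct: float
    adulterated_as_pure_pct: float
    soft_misclassified_pct: float
    total_error_pct: float
    per_split_accuracy: list[float] = field(default_factory=list)
    adulterant_confusion_pct: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        parts = self.n_correct + self.n_pure_as_adulterated + self.n_adulterated_as_pure + self.n_soft
        if parts != self.n_total:
            raise ValueError(f"error taxonomy does not partition predictions ({parts} != {self.n_total})")


def _adulterant_of(label: str) -> str:
    return "none" if label == "pure" else (label.rsplit("_", 1)[0] if "_" in label else label)


def hard_soft_metrics(log: pd.DataFrame) -> MetricsSummary:
    """Partition a classification log into correct / hard / soft errors."""
    if log.empty:
        raise DesignError("empty prediction log")
    true = log["true_class"].to_numpy(dtype=object)
    pred = log["predicted_class"].to_numpy(dtype=object)
    pure_true = true == "pure"
    pure_pred = pred == "pure"
    correct = true == pred

    n_total = len(log)
    n_pure = int(pure_true.sum())
    n_adulterated = n_total - n_pure
    n_p_as_a = int((pure_true & ~pure_pred).sum())
    n_a_as_p = int((~pure_true & pure_pred).sum())
    n_soft = int((~pure_true & ~pure_pred & ~correct).sum())

    per_split = [
        float(np.mean(grp["true_class"].to_numpy() == grp["predicted_class"].to_numpy()))
        for _, grp in log.groupby("split_index")
    ]

    confusion: dict[str, float] = {}
    kinds = {_adulterant_of(c) for c in true} - {"none"}
    if {"rice", "sugar_beet"} <= kinds:
        for a, b in (("rice", "sugar_beet"), ("sugar_beet", "rice")):
            is_a = np.array([_adulterant_of(c) == a for c in true])
            pred_b = np.array([_adulterant_of(c) == b for c in pred])
            confusion[f"{a}_as_{b}_pct"] = 100.0 * float((is_a & pred_b).sum()) / max(int(is_a.sum()), 1)

    return MetricsSummary(
        n_total=n_total, n_pure=n_pure, n_adulterated=n_adulterated,
        n_correct=int(correct.sum()),
        n_pure_as_adulterated=n_p_as_a, n_adulterated_as_pure=n_a_as_p, n_soft=n_soft,
        pure_as_adulterated_pct=100.0 * n_p_as_a / max(n_pure, 1),
        adulterated_as_pure_pct=100.0 * n_a_as_p / max(n_adulterated, 1),
        soft_misclassified_pct=100.0 * n_soft / max(n_adulterated, 1),
        total_error_pct=100.0 * (n_total - int(correct.sum())) / n_total,
        per_split_accuracy=per_split,
        adulterant_confusion_pct=confusion,
    )


def rmse(predicted: Sequence[float], actual: Sequence[float]) -> float:
    """Root mean squared prediction error, sqrt(sum((yhat - y)^2) / n)."""
    predicted = np.asarray(predicted, dtype=float)
    actual = np.asarray(actual, dtype=float)
    if predicted.shape != actual.shape or predicted.size == 0:
        raise ValueError("predicted and actual must be equal-length, non-empty")
    return float(np.sqrt(np.mean((predicted - actual) ** 2)))


@dataclass
class RegressionMetrics:
    """Per-split RMSE / R^2 and their spread across splits."""

    per_split_rmse: list[float]
    per_split_r2: list[float]
    mean_rmse: float
    sd_rmse: float
    min_rmse: float
    max_rmse: float
    mean_r2: float
    sd_r2: float


def regression_metrics(log: pd.DataFrame) -> RegressionMetrics:
    """Summarise a regression prediction log split by split."""
    if log.empty:
        raise DesignError("empty prediction log")
    rmses, r2s = [], []
    for _, grp in log.groupby("split_index"):
        y = grp["true_level"].to_numpy(dtype=float)
        yhat = grp["predicted_level"].to_numpy(dtype=float)
        rmses.append(rmse(yhat, y))
        ss_tot = np.sum((y - y.mean()) ** 2)
        r2s.append(float(1.0 - np.sum((yhat - y) ** 2) / ss_tot) if ss_tot > 0 else float("nan"))
    r = np.asarray(rmses)
    q = np.asarray(r2s)
    sd = float(r.std(ddof=1)) if r.size > 1 else 0.0
    sd2 = float(np.nanstd(q, ddof=1)) if q.size > 1 else 0.0
    return RegressionMetrics(
        per_split_rmse=rmses, per_split_r2=r2s,
        mean_rmse=float(r.mean()), sd_rmse=sd, min_rmse=float(r.min()), max_rmse=float(r.max()),
        mean_r2=float(np.nanmean(q)), sd_r2=sd2,
    )


def aggregate(per_split: Sequence[float]) -> dict[str, float]:
    """Boxplot-style summary of a per-split metric distribution.

    Returns mean, SD (n-1), five-number summary, and a skewness direction
    flag: +1 when median > mean (left skew), -1 when median < mean, 0 tie.
    """
    values = np.asarray(list(per_split), dtype=float)
    if values.size == 0:
        raise ValueError("empty metric list")
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    mean = float(values.mean())
    return {
        "mean": mean,
        "sd": float(values.std(ddof=1)) if values.size > 1 else 0.0,
        "min": float(values.min()),
        "q1": float(q1),
        "median": float(med),
        "q3": float(q3),
        "max": float(values.max()),
        "skew_direction": float(np.sign(med - mean)),
    }


# ---------------------------------------------------------------------------
# heather-style resampling experiment

@dataclass
class HeatherResult:
    """Binary + ordinal RF performance over random stratified resamples."""

    binary: MetricsSummary
    mean_accuracy: float
    sd_accuracy: float
    fraction_perfect: float
    pure_correct_pct: float
    adulterated_correct_pct: float
    ordinal: MetricsSummary
    ordinal_mean_accuracy: float


def heather_binary_experiment(
    sset: SpectraSet,
    n_models: int = 100,
    seed: int = 0,
    *,
    test_fraction: float = 0.25,
    rf_config: RFConfig | None = None,
) -> HeatherResult:
    """Pure-vs-adulterated RF stability over random stratified resamples.

    ``n_models`` random 75/25 stratified train/test resamples (stratified on
    the full pure/low/medium/high level label so every resample sees all
    levels); a binary RF and an ordinal RF are fitted on each.
    """
    rf_config = rf_config or RFConfig(tune=False)
    kinds = sorted(set(sset.meta["adulterant"]) - {"none"})
    if not kinds:
        raise TaskError("no adulterated samples present")
    kind = kinds[0]
    levels = sorted(
        float(v) for v in sset.meta.loc[sset.meta["adulterant"] == kind, "level_pct"].unique()
    )
    bin_task = models.binary_task(kind, levels)
    ord_task = models.ordinal_levels_task(kind, levels)
    sub = sset.select(_task_mask(sset, (kind,)))
    X = sub.intensities
    y_bin = models.labels_for(bin_task, sub.meta)
    y_ord = models.labels_for(ord_task, sub.meta)
    if len(set(y_bin)) < 2:
        raise TaskError("need both pure and adulterated samples")

    sss = StratifiedShuffleSplit(n_splits=n_models, test_size=test_fraction, random_state=seed)
    sub_seeds = (np.random.SeedSequence(seed).generate_state(n_models) % (2**31)).astype(int)
    bin_records, ord_records = [], []
    for i, (tr, te) in enumerate(sss.split(X, y_ord)):
        s = int(sub_seeds[i])
        bmodel = models.fit_rf(X[tr], y_bin[tr], rf_config, classes=bin_task.classes, seed=s)
        bpred = models.predict(bmodel, X[te])
        omodel = models.fit_rf_ordinal(X[tr], y_ord[tr], rf_config, classes=ord_task.classes, seed=s)
        opred = models.predict(omodel, X[te])
        for j, idx in enumerate(te):
            base = {
                "sample_id": sub.meta.loc[idx, "sample_id"],
                "honey_type": sub.meta.loc[idx, "honey_type"],
                "split_index": i,
            }
            bin_records.append({**base, "algorithm": "rf", "true_class": y_bin[idx], "predicted_class": bpred[j]})
            ord_records.append({**base, "algorithm": "rf_ordinal", "true_class": y_ord[idx], "predicted_class": opred[j]})

    bin_log = pd.DataFrame(bin_records)
    ord_log = pd.DataFrame(ord_records)
    bmetrics = hard_soft_metrics(bin_log)
    ometrics = hard_soft_metrics(ord_log)
    acc = np.asarray(bmetrics.per_split_accuracy)
    pure_rows = bin_log["true_class"] == "pure"
    pure_ok = float(np.mean(bin_log.loc[pure_rows, "predicted_class"] == "pure")) * 100
    adu_ok = float(np.mean(bin_log.loc[~pure_rows, "predicted_class"] == "adulterated")) * 100
    return HeatherResult(
        binary=bmetrics,
        mean_accuracy=float(acc.mean()),
        sd_accuracy=float(acc.std(ddof=1)) if acc.size > 1 else 0.0,
        fraction_perfect=float(np.mean(acc == 1.0)),
        pure_correct_pct=pure_ok,
        adulterated_correct_pct=adu_ok,
        ordinal=ometrics,
        ordinal_mean_accuracy=float(np.mean(np.asarray(ometrics.per_split_accuracy))),
    )
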