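"""Class balancing, model evaluation across algorithms/window sizes, and
whole-deployment annotation.

The evaluation protocol mirrors common practice for supervised behavior
classification from accelerometry: classes are balanced by subsampling
every class down to the rarest class, the balanced set is split 50/50
into train and test (stratified by class so all classes appear on both
sides), and each candidate — linear support vector machine, decision
tree, random forest — is fitted on the train half and scored on the test
half.  Accuracy, precision and recall are computed from the confusion
matrix (per class, one-vs-rest).  The model grid spans the three
algorithms, the two feature sets (all 41 statistics, or the reduced
mean/SD/ODBA set) and the window sizes; the selected model maximizes the
unweighted mean of macro accuracy, macro precision and macro recall.
"""

from __future__ import annotations

import dataclasses
import enum
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC
from sklearn.tree import DecisionTreeClassifier

from .core import AccelTrace, BEHAVIOR_NAMES, BehaviorClass
from .features import FEATURE_SETS, feature_table

logger = logging.getLogger(__name__)


class Algorithm(str, enum.Enum):
    LINEAR_SVM = "linear_svm"
    DECISION_TREE = "decision_tree"
    RANDOM_FOREST = "random_forest"


DEFAULT_WINDOW_SIZES: tuple[float, ...] = (1.0, 2.0, 3.0, 6.0, 9.0)


@dataclass(frozen=True)
class ModelSpec:
    algorithm: Algorithm
    feature_set: str  # "all" or "reduced"
    window_s: float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.feature_set not in FEATURE_SETS:
            raise ValueError(f"unknown feature set {self.feature_set!r}")

    def label(self) -> str:
        return f"{self.algorithm.value}/{self.feature_set}/{self.window_s:g}s"


@dataclass
class ModelReport:
    """Confusion matrix and derived metrics for one evaluated spec.

    The confusion matrix is 4x4 with rows = true class, columns =
    predicted class, in ``BEHAVIOR_NAMES`` order.  Per-class accuracy is
    one-vs-rest: (TP+TN)/total.
    """

    spec: ModelSpec
    confusion: np.ndarray
    train_sizes: dict[str, int]
    test_sizes: dict[str, int]

    per_class_accuracy: dict[str, float] = field(init=False)
    per_class_precision: dict[str, float] = field(init=False)
    per_class_recall: dict[str, float] = field(init=False)
    overall_accuracy: float = field(init=False)

    def __post_init__(self) -> None:
        cm = np.asarray(self.confusion, dtype=float)
        total = cm.sum()
        tp = np.diag(cm)
        fp = cm.sum(axis=0) - tp
        fn = cm.sum(axis=1) - tp
        tn = total - tp - fp - fn
        with np.errstate(invalid="ignore", divide="ignore"):
            prec = np.where(tp + fp > 0, tp / (tp + fp), 0.0)
            rec = np.where(tp + fn > 0, tp / (tp + fn), 0.0)
        acc = (tp + tn) / total
        self.per_class_accuracy = dict(zip(BEHAVIOR_NAMES, acc))
        self.per_class_precision = dict(zip(BEHAVIOR_NAMES, prec))
        self.per_class_recall = dict(zip(BEHAVIOR_NAMES, rec))
        self.overall_accuracy = float(tp.sum() / total)

    @property
    def macro_accuracy(self) -> float:
        return float(np.mean(list(self.per_class_accuracy.values())))

    @property
    def macro_precision(self) -> float:
        return float(np.mean(list(self.per_class_precision.values())))

    @property
    def macro_recall(self) -> float:
        return float(np.mean(list(self.per_class_recall.values())))

    @property
    def selection_score(self) -> float:
        """Unweighted mean of macro accuracy, precision and recall."""
        return (self.macro_accuracy + self.macro_precision + self.macro_recall) / 3.0

    def to_row(self) -> dict:
        row = {
            "algorithm": self.spec.algorithm.value,
            "feature_set": self.spec.feature_set,
            "window_s": self.spec.window_s,
            "overall_accuracy": self.overall_accuracy,
            "macro_accuracy": self.macro_accuracy,
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "selection_score": self.selection_score,
        }
        for b in BEHAVIOR_NAMES:
            row[f"accuracy_{b}"] = self.per_class_accuracy[b]
            row[f"precision_{b}"] = self.per_class_precision[b]
            row[f"recall_{b}"] = self.per_class_recall[b]
        for i, bt in enumerate(BEHAVIOR_NAMES):
            for j, bp in enumerate(BEHAVIOR_NAMES):
                row[f"n_{bt}_as_{bp}"] = int(self.confusion[i, j])
        return row


def balance_classes(
    table: pd.DataFrame, seed, label_col: str = "label"
) -> pd.DataFrame:
    """Subsample every class (without replacement) to the rarest class count."""
    labeled = table[table[label_col].isin(BEHAVIOR_NAMES)]
    counts = labeled[label_col].value_counts()
    missing = [b for b in BEHAVIOR_NAMES if b not in counts.index]
    if missing:
        raise ValueError(
            f"cannot balance: class(es) {missing} absent "
            f"(counts: {counts.to_dict()})"
        )
    n_min = int(counts.min())
    if n_min < 2:
        raise ValueError(f"rarest class has {n_min} window(s); need at least 2")
    rng = np.random.default_rng(seed)
    parts = []
    for b in BEHAVIOR_NAMES:
        idx = labeled.index[labeled[label_col] == b].to_numpy()
        take = np.sort(rng.choice(idx, size=n_min, replace=False))
        parts.append(labeled.loc[take])
    return pd.concat(parts).sort_index()


def split_train_test(
    table: pd.DataFrame, fraction: float = 0.5, seed=None, label_col: str = "label"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stratified random split; train gets ``round(fraction * n)`` per class."""
    if not 0.0 < fraction < 1.0:
        raise ValueError("train fraction must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    train_idx = []
    for b, group in table.groupby(label_col, sort=True):
        idx = group.index.to_numpy()
        n_train = int(round(fraction * len(idx)))
        n_train = min(max(n_train, 1), len(idx) - 1)
        train_idx.append(rng.choice(idx, size=n_train, replace=False))
    train_idx = np.sort(np.concatenate(train_idx))
    train = table.loc[train_idx]
    test = table.drop(index=train_idx)
    return train, test


def _make_estimator(spec: ModelSpec):
    # hyperparameters stay at library defaults; only seeds are pinned
    if spec.algorithm is Algorithm.LINEAR_SVM:
        return Pipeline(
            [
                ("scale", StandardScaler()),
                ("svm", LinearSVC(random_state=spec.seed)),
            ]
        )
    if spec.algorithm is Algorithm.DECISION_TREE:
        return DecisionTreeClassifier(random_state=spec.seed)
    return RandomForestClassifier(random_state=spec.seed)


def evaluate_model(
    spec: ModelSpec, train: pd.DataFrame, test: pd.DataFrame, label_col: str = "label"
) -> ModelReport:
    """Fit on train, predict test, and assemble the confusion-matrix report.

    Standardization for the SVM is fitted on the train half only, so no
    test-set statistics leak into the fit.
    """
    cols = list(FEATURE_SETS[spec.feature_set])
    for name, part in (("train", train), ("test", test)):
        bad = [c for c in cols if not np.isfinite(part[c].to_numpy(float)).all()]
        if bad:
            raise ValueError(f"non-finite feature values in {name} columns: {bad}")
    est = _make_estimator(spec)
    est.fit(train[cols].to_numpy(float), train[label_col].to_numpy())
    pred = est.predict(test[cols].to_numpy(float))
    truth = test[label_col].to_numpy()
    k = len(BEHAVIOR_NAMES)
    lut = {b: i for i, b in enumerate(BEHAVIOR_NAMES)}
    cm = np.zeros((k, k), dtype=int)
    for t, p in zip(truth, pred):
        cm[lut[t], lut[p]] += 1
    report = ModelReport(
        spec=spec,
        confusion=cm,
        train_sizes=train[label_col].value_counts().to_dict(),
        test_sizes=test[label_col].value_counts().to_dict(),
    )
    report._estimator = est  # retained for annotation
    return report


@dataclass
class SelectionResult:
    best: ModelReport
    leaderboard: pd.DataFrame
    reports: list[ModelReport]


def model_selection(
    tables: dict[float, pd.DataFrame],
    algorithms=tuple(Algorithm),
    feature_sets=("all", "reduced"),
    seed: int = 0,
    train_fraction: float = 0.5,
) -> SelectionResult:
    """Evaluate the full (algorithm, feature set, window size) grid.

    ``tables`` maps window size to its labeled feature table.  Balancing
    and splitting use the same derived seeds for every spec sharing a
    window size, so specs are compared on identical train/test halves.
    Ranking: selection score, ties broken by macro recall then smaller
    window, then spec label for determinism.
    """
    if not tables:
        raise ValueError("no feature tables supplied")
    reports: list[ModelReport] = []
    for w, table in sorted(tables.items()):
        balanced = balance_classes(table, seed=seed)
        train, test = split_train_test(balanced, fraction=train_fraction, seed=seed + 1)
        for fs in feature_sets:
            for algo in algorithms:
                spec = ModelSpec(
                    algorithm=Algorithm(algo), feature_set=fs, window_s=w, seed=seed
                )
                reports.append(evaluate_model(spec, train, test))
    reports.sort(
        key=lambda r: (
            -r.selection_score,
            -r.macro_recall,
            r.spec.window_s,
            r.spec.label(),
        )
    )
    leaderboard = pd.DataFrame([r.to_row() for r in reports])
    return SelectionResult(best=reports[0], leaderboard=leaderboard, reports=reports)


def annotate_deployment(
    trace: AccelTrace, report: ModelReport, label_col: str = "label"
) -> pd.DataFrame:
    """Predict a behavior for every complete window of a deployment.

    Returns a step function as a table (start, end, behavior); consecutive
    windows are not merged, one row per window.
    """
    est = getattr(report, "_estimator", None)
    if est is None:
        raise ValueError("report does not carry a fitted estimator")
    w = report.spec.window_s
    table = feature_table(trace, w)
    if table.empty:
        logger.warning(
            "annotate_deployment: trace %s shorter than one %g s window",
            trace.deployment_id,
            w,
        )
        return pd.DataFrame(columns=["deployment_id", "start", "end", "behavior"])
    cols = list(FEATURE_SETS[report.spec.feature_set])
    pred = est.predict(table[cols].to_numpy(float))
    out = pd.DataFrame(
        {
            "deployment_id": trace.deployment_id,
            "start": table["start"],
            "end": table["start"] + pd.to_timedelta(w, unit="s"),
            "behavior": pred,
        }
    )
    return out
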