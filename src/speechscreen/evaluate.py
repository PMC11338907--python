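"""Gender-stratified normalization, leave-one-out classification, and metrics.

Five classifier families (logistic regression, Gaussian naive Bayes, random
forest, RBF-kernel SVM, kNN) are each evaluated by leave-one-out
cross-validation over a small hyperparameter grid; the grid point with the
highest LOO accuracy (ties to the smallest value) is reported with its
confusion counts and accuracy / sensitivity / precision / F1.  The positive
class is the impaired group (AD, or CI = AD + MCI).

Grid-point selection is non-nested by default (the selected point's LOO
accuracy is the reported validation accuracy); a nested, leakage-free mode
re-selects the grid point inside every training fold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .schema import FEATURE_SETS, TASKS, validate_feature_table

MODEL_FAMILIES = ("logistic", "gnb", "rf", "svm", "knn")

#: Hyperparameter grids: (parameter name, values). Families without a grid
#: carry a single None placeholder so selection is a no-op.
GRIDS: dict[str, tuple[str | None, list]] = {
    "logistic": (None, [None]),
    "gnb": (None, [None]),
    "rf": ("n_estimators", list(range(3, 16))),
    "svm": ("C", [round(0.1 + 0.3 * i, 1) for i in range(9)]),  # 0.1, 0.4, ..., 2.5
    "knn": ("n_neighbors", list(range(1, 9))),
}


def make_estimator(family: str, param, seed: int = 0):
    """Instantiate one grid point of a classifier family."""
    if family == "logistic":
        return LogisticRegression(C=1.0, max_iter=2000)  # default L2 penalty
    if family == "gnb":
        return GaussianNB()
    if family == "rf":
        return RandomForestClassifier(n_estimators=int(param), random_state=seed)
    if family == "svm":
        return SVC(kernel="rbf", gamma="scale", C=float(param))
    if family == "knn":
        return KNeighborsClassifier(n_neighbors=int(param), weights="uniform")
    raise ValueError(f"unknown model family {family!r}")


# ---------------------------------------------------------------------------
# Normalization


class GenderStratifiedScaler(BaseEstimator, TransformerMixin):
    """Z-score each feature within each gender stratum.

    After transforming, each feature has mean 0 and population standard
    deviation 1 within every gender group, removing gender-driven offsets
    (e.g. F0) before classification.  A feature that is constant within a
    stratum is passed through as zeros for that stratum, with a warning; the
    affected (gender, feature) pairs are recorded in ``constant_cols_``.
    """

    def __init__(self, feature_cols: Sequence[str] | None = None, gender_col: str = "gender"):
        self.feature_cols = feature_cols
        self.gender_col = gender_col

    def fit(self, X: pd.DataFrame, y=None):  # noqa: N803 - sklearn API
        cols = list(self.feature_cols) if self.feature_cols is not None else [
            c for c in X.columns if np.issubdtype(X[c].dtype, np.number)
        ]
        self.feature_cols_ = cols
        self.means_ = {}
        self.stds_ = {}
        self.constant_cols_ = []
        for gender, sub in X.groupby(self.gender_col):
            if len(sub) < 2:
                raise ValueError(f"gender stratum {gender!r} has fewer than 2 subjects")
            mu = sub[cols].mean()
            sigma = sub[cols].std(ddof=0)
            const = sigma[sigma == 0].index.tolist()
            if const:
                warnings.warn(
                    f"features constant within gender {gender!r} zeroed: {const}",
                    stacklevel=2,
                )
                self.constant_cols_.extend((gender, c) for c in const)
            self.means_[gender] = mu
            self.stds_[gender] = sigma.replace(0.0, 1.0)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:  # noqa: N803
        out = X.copy()
        out[self.feature_cols_] = out[self.feature_cols_].astype(float)
        for gender in self.means_:
            mask = out[self.gender_col] == gender
            out.loc[mask, self.feature_cols_] = (
                out.loc[mask, self.feature_cols_] - self.means_[gender]
            ) / self.stds_[gender]
        return out


def zscore_by_gender(table: pd.DataFrame, feature_cols: Sequence[str] | None = None) -> pd.DataFrame:
    """Fit-and-transform convenience wrapper over :class:`GenderStratifiedScaler`."""
    return GenderStratifiedScaler(feature_cols=feature_cols).fit_transform(table)


# ---------------------------------------------------------------------------
# Metrics


@dataclass(frozen=True)
class Metrics:
    """Accuracy/sensitivity/precision in percent, F1 as a fraction.

    A metric whose denominator is zero is None (explicitly undefined),
    never silently 0.
    """

    accuracy_pct: float | None
    sensitivity_pct: float | None
    precision_pct: float | None
    f1: float | None


def metrics_from_counts(tp: int, fp: int, tn: int, fn: int) -> Metrics:
    """Exact metric evaluation from confusion counts."""
    for v in (tp, fp, tn, fn):
        if v < 0 or int(v) != v:
            raise ValueError("confusion counts must be nonnegative integers")
    n = tp + fp + tn + fn
    accuracy = 100.0 * (tp + tn) / n if n > 0 else None
    sensitivity = 100.0 * tp / (tp + fn) if (tp + fn) > 0 else None
    precision = 100.0 * tp / (tp + fp) if (tp + fp) > 0 else None
    if sensitivity is not None and precision is not None and (sensitivity + precision) > 0:
        s, p = sensitivity / 100.0, precision / 100.0
        f1 = 2.0 * s * p / (s + p)
    else:
        f1 = None
    return Metrics(accuracy, sensitivity, precision, f1)


#: Published operating points (sensitivity %, precision %, F1) from a
#: speech-based screening study, used as a regression fixture for the F1
#: identity f1 = 2sp/(s+p).  Cells whose printed triple is internally
#: inconsistent (the first number is the task accuracy, not sensitivity)
#: are excluded.
REFERENCE_OPERATING_POINTS: list[tuple[float, float, float]] = [
    (68.57, 80.00, 0.739), (77.42, 80.00, 0.787), (79.31, 76.67, 0.780),
    (70.00, 93.33, 0.800), (76.67, 76.67, 0.767), (71.05, 90.00, 0.794),
    (67.57, 83.33, 0.746), (77.42, 80.00, 0.787), (74.29, 86.67, 0.800),
    (68.42, 86.67, 0.765), (78.13, 83.33, 0.807), (83.33, 83.33, 0.833),
    (64.44, 96.67, 0.773), (79.31, 76.67, 0.780), (73.68, 93.33, 0.824),
    (78.21, 87.14, 0.824), (79.27, 92.86, 0.855),
    (74.29, 74.29, 0.743), (80.00, 74.29, 0.770),
    (77.91, 95.71, 0.859), (81.25, 92.86, 0.867),
    (76.09, 100.00, 0.864), (80.23, 98.57, 0.885),
    (77.27, 97.14, 0.861), (88.41, 87.14, 0.878),
]


def f1_from_percentages(sensitivity_pct: float, precision_pct: float) -> float:
    """Harmonic mean of sensitivity and precision given in percent."""
    s, p = sensitivity_pct / 100.0, precision_pct / 100.0
    if s + p == 0:
        raise ValueError("F1 undefined when sensitivity + precision = 0")
    return 2.0 * s * p / (s + p)


# ---------------------------------------------------------------------------
# Leave-one-out evaluation


@dataclass(frozen=True)
class EvalResult:
    task: str
    feature_set: str
    family: str
    chosen_param: float | int | None
    tp: int
    fp: int
    tn: int
    fn: int
    accuracy_pct: float | None
    sensitivity_pct: float | None
    precision_pct: float | None
    f1: float | None

    def to_dict(self) -> dict:
        return asdict(self)


def _loo_predictions(family: str, param, X: np.ndarray, y: np.ndarray, seed: int) -> np.ndarray:
    preds = np.empty(len(y), dtype=int)
    for i in range(len(y)):
        mask = np.ones(len(y), dtype=bool)
        mask[i] = False
        est = make_estimator(family, param, seed)
        est.fit(X[mask], y[mask])
        preds[i] = int(est.predict(X[i : i + 1])[0])
    return preds


class LOOGridClassifier(BaseEstimator, ClassifierMixin):
    """Leave-one-out grid search for one classifier family.

    ``fit`` runs full LOO for every grid point, selects the point with the
    highest LOO accuracy (ties to the smallest hyperparameter, so selection
    is deterministic), stores the selected point's held-out predictions, and
    refits the selected estimator on all data for ``predict``.

    Attributes set by ``fit``: ``best_param_``, ``best_loo_accuracy_``,
    ``loo_predictions_``, ``grid_accuracies_``, ``estimator_``.
    """

    def __init__(self, family: str = "svm", nested: bool = False, seed: int = 0):
        self.family = family
        self.nested = nested
        self.seed = seed

    def fit(self, X, y):  # noqa: N803 - sklearn API
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        classes, counts = np.unique(y, return_counts=True)
        if len(classes) != 2 or counts.min() < 2:
            raise ValueError("need two classes with at least 2 subjects each")
        self.classes_ = classes
        _, grid = GRIDS[self.family]
        if self.family == "knn":  # k cannot exceed the LOO training-fold size
            grid = [k for k in grid if k <= len(y) - 1] or [len(y) - 1]

        if self.nested:
            preds = np.empty(len(y), dtype=int)
            for i in range(len(y)):
                mask = np.ones(len(y), dtype=bool)
                mask[i] = False
                best_p, best_acc = None, -1.0
                for p in grid:
                    inner = _loo_predictions(self.family, p, X[mask], y[mask], self.seed)
                    acc = float(np.mean(inner == y[mask]))
                    if acc > best_acc:
                        best_p, best_acc = p, acc
                est = make_estimator(self.family, best_p, self.seed)
                est.fit(X[mask], y[mask])
                preds[i] = int(est.predict(X[i : i + 1])[0])
            self.best_param_ = None  # per-fold in nested mode
            self.grid_accuracies_ = {}
            self.loo_predictions_ = preds
            self.best_loo_accuracy_ = float(np.mean(preds == y))
            self.estimator_ = make_estimator(self.family, grid[0], self.seed).fit(X, y)
            return self

        self.grid_accuracies_ = {}
        best_p, best_acc, best_preds = None, -1.0, None
        for p in grid:
            preds = _loo_predictions(self.family, p, X, y, self.seed)
            acc = float(np.mean(preds == y))
            self.grid_accuracies_[p] = acc
            if acc > best_acc:  # strict: earlier (smaller) grid point wins ties
                best_p, best_acc, best_preds = p, acc, preds
        self.best_param_ = best_p
        self.best_loo_accuracy_ = best_acc
        self.loo_predictions_ = best_preds
        self.estimator_ = make_estimator(self.family, best_p, self.seed).fit(X, y)
        return self

    def predict(self, X):  # noqa: N803
        return self.estimator_.predict(np.asarray(X, dtype=float))


def loo_evaluate(
    table: pd.DataFrame,
    task: str,
    feature_set: str,
    family: str,
    seed: int = 0,
    nested: bool = False,
) -> EvalResult:
    """LOO-evaluate one classifier family on one task and feature set.

    The table must already be normalized.  Positive class = impaired.
    """
    if task not in TASKS:
        raise ValueError(f"unknown task {task!r}")
    cols = FEATURE_SETS[feature_set]
    impaired = TASKS[task]
    sub = table[table["group"].isin(("HC",) + impaired)]
    validate_feature_table(sub, feature_set)
    X = sub[cols].to_numpy(dtype=float)
    y = sub["group"].isin(impaired).to_numpy(dtype=int)

    clf = LOOGridClassifier(family=family, nested=nested, seed=seed).fit(X, y)
    preds = clf.loo_predictions_
    tp = int(np.sum((preds == 1) & (y == 1)))
    fp = int(np.sum((preds == 1) & (y == 0)))
    tn = int(np.sum((preds == 0) & (y == 0)))
    fn = int(np.sum((preds == 0) & (y == 1)))
    m = metrics_from_counts(tp, fp, tn, fn)
    return EvalResult(
        task=task,
        feature_set=feature_set,
        family=family,
        chosen_param=clf.best_param_,
        tp=tp, fp=fp, tn=tn, fn=fn,
        accuracy_pct=m.accuracy_pct,
        sensitivity_pct=m.sensitivity_pct,
        precision_pct=m.precision_pct,
        f1=m.f1,
    )


def compare_feature_sets(
    table: pd.DataFrame,
    seed: int = 0,
    tasks: Sequence[str] = ("HC_vs_AD", "HC_vs_CI"),
    feature_sets: Sequence[str] = ("acoustic", "linguistic", "all"),
    families: Sequence[str] = MODEL_FAMILIES,
    nested: bool = False,
) -> list[EvalResult]:
    """The full evaluation grid: tasks x feature sets x classifier families."""
    return [
        loo_evaluate(table, task, fset, family, seed=seed, nested=nested)
        for task in tasks
        for fset in feature_sets
        for family in families
    ]


def render_accuracy_table(results: Sequence[EvalResult]) -> str:
    """Markdown accuracy grid (per task: families x feature sets), best in bold."""
    lines = []
    for task in dict.fromkeys(r.task for r in results):
        rows = [r for r in results if r.task == task]
        fsets = list(dict.fromkeys(r.feature_set for r in rows))
        best = {f: max(r.accuracy_pct for r in rows if r.feature_set == f) for f in fsets}
        lines.append(f"### {task.replace('_', ' ')}")
        lines.append("| Model | " + " | ".join(fsets) + " |")
        lines.append("|---" * (len(fsets) + 1) + "|")
        for fam in dict.fromkeys(r.family for r in rows):
            cells = []
            for f in fsets:
                r = next(x for x in rows if x.family == fam and x.feature_set == f)
                v = f"{r.accuracy_pct:.2f}"
                cells.append(f"**{v}**" if r.accuracy_pct == best[f] else v)
            lines.append(f"| {fam} | " + " | ".join(cells) + " |")
        lines.append("")
    return "\n".join(lines)


def render_metrics_table(results: Sequence[EvalResult]) -> str:
    """Markdown sensitivity/precision/F1 grid, percentages to 2 d.p., F1 to 3."""
    lines = []
    for task in dict.fromkeys(r.task for r in results):
        rows = [r for r in results if r.task == task]
        fsets = list(dict.fromkeys(r.feature_set for r in rows))
        lines.append(f"### {task.replace('_', ' ')} (sensitivity / precision / F1)")
        lines.append("| Model | " + " | ".join(fsets) + " |")
        lines.append("|---" * (len(fsets) + 1) + "|")
        for fam in dict.fromkeys(r.family for r in rows):
            cells = []
            for f in fsets:
                r = next(x for x in rows if x.family == fam and x.feature_set == f)
                sens = "undef" if r.sensitivity_pct is None else f"{r.sensitivity_pct:.2f}"
                prec = "undef" if r.precision_pct is None else f"{r.precision_pct:.2f}"
                f1 = "undef" if r.f1 is None else f"{r.f1:.3f}"
                cells.append(f"{sens} / {prec} / {f1}")
            lines.append(f"| {fam} | " + " | ".join(cells) + " |")
        lines.append("")
    return "\n".join(lines)
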