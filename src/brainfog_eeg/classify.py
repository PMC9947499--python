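"""Two-class LDA on avalanche features with the five cohort comparisons.

The classifier is Gaussian linear discriminant analysis with a pooled
within-class covariance, optional shrinkage toward the scaled identity, and
priors estimated from training frequencies.  Evaluation follows the study
protocol: a stratified 70/30 train/test split that preserves cohort
proportions, k-fold cross-validation on the training portion (default 6
folds ≈ 17% fold size), and sensitivity/specificity/PPV/NPV computed from
confusion counts as TP/P, TN/N, TP/(TP+FP), TN/(TN+FN).

Comparison tasks: A&B vs C, B&C vs A, A vs B, A vs C, B vs C, where the
first-named side is the positive class.  Undefined metrics (zero
denominator) are reported as NaN with a warning, never silently as 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "LdaModel",
    "ConfusionCounts",
    "ComparisonTask",
    "CvReport",
    "STANDARD_TASKS",
    "lda_fit",
    "lda_predict",
    "confusion_metrics",
    "stratified_split",
    "kfold_cv",
    "run_comparisons",
]


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LdaModel:
    class_labels: tuple[str, str]
    class_means: np.ndarray          # (2, d)
    covariance: np.ndarray           # pooled, after shrinkage
    log_priors: np.ndarray
    shrinkage: float

    @property
    def n_features(self) -> int:
        return self.class_means.shape[1]


def lda_fit(features: np.ndarray, labels, shrinkage: float = 0.1) -> LdaModel:
    """Fit equal-covariance Gaussian LDA.

    The pooled within-class covariance is shrunk as
    ``(1 - λ) S + λ (tr S / d) I``; λ = 0 is allowed but raises if the raw
    covariance is singular.  Class labels are ordered lexicographically,
    which also fixes the prediction tie-break.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim != 2:
        raise ValueError("features must be 2-D (samples x features)")
    y = np.asarray([str(v) for v in labels])
    classes = sorted(set(y))
    if len(classes) != 2:
        raise ValueError(f"LDA here is two-class; got classes {classes}")
    n, d = X.shape
    means, counts = [], []
    scatter = np.zeros((d, d))
    for c in classes:
        Xc = X[y == c]
        if len(Xc) < 2:
            raise ValueError(f"class {c!r} has {len(Xc)} sample(s); need >= 2")
        mu = Xc.mean(axis=0)
        means.append(mu)
        counts.append(len(Xc))
        dev = Xc - mu
        scatter += dev.T @ dev
    cov = scatter / (n - 2)
    if shrinkage < 0 or shrinkage > 1:
        raise ValueError("shrinkage must be in [0, 1]")
    if shrinkage > 0:
        cov = (1 - shrinkage) * cov + shrinkage * (np.trace(cov) / d) * np.eye(d)
    eigvals = np.linalg.eigvalsh(cov)
    if eigvals[0] <= 1e-10 * max(eigvals[-1], 1e-300):
        raise ValueError("pooled covariance is singular; use shrinkage > 0")
    priors = np.array(counts, dtype=float) / n
    return LdaModel(
        class_labels=(classes[0], classes[1]),
        class_means=np.stack(means),
        covariance=cov,
        log_priors=np.log(priors),
        shrinkage=shrinkage,
    )


def lda_predict(model: LdaModel, features: np.ndarray):
    """Predict labels and return the discriminant score per sample.

    The score is δ₁(x) − δ₀(x) (positive favors the second label); exact
    ties go to the lexicographically first label.
    """
    X = np.atleast_2d(np.asarray(features, dtype=float))
    if X.shape[1] != model.n_features:
        raise ValueError(
            f"feature dimension {X.shape[1]} != model dimension "
            f"{model.n_features}"
        )
    inv = np.linalg.inv(model.covariance)
    deltas = []
    for k in range(2):
        mu = model.class_means[k]
        w = inv @ mu
        b = -0.5 * mu @ inv @ mu + model.log_priors[k]
        deltas.append(X @ w + b)
    score = deltas[1] - deltas[0]
    labels = np.where(score > 0, model.class_labels[1], model.class_labels[0])
    return labels, score


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self) -> None:
        for name in ("TP", "FP", "TN", "FN"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def P(self) -> int:
        return self.TP + self.FN

    @property
    def N(self) -> int:
        return self.TN + self.FP

    @property
    def total(self) -> int:
        return self.P + self.N


def _ratio(num: int, den: int, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); reporting NaN",
                      stacklevel=3)
        return float("nan")
    return num / den


def confusion_metrics(y_true, y_pred, positive_class: str) -> dict:
    """Sensitivity TP/P, specificity TN/N, PPV TP/(TP+FP), NPV TN/(TN+FN)."""
    y_true = np.asarray([str(v) for v in y_true])
    y_pred = np.asarray([str(v) for v in y_pred])
    labels = set(y_true) | set(y_pred)
    if len(labels - {positive_class}) > 1:
        raise ValueError(f"labels {sorted(labels)} are not binary around "
                         f"positive class {positive_class!r}")
    pos_t = y_true == positive_class
    pos_p = y_pred == positive_class
    counts = ConfusionCounts(
        TP=int(np.sum(pos_t & pos_p)),
        FP=int(np.sum(~pos_t & pos_p)),
        TN=int(np.sum(~pos_t & ~pos_p)),
        FN=int(np.sum(pos_t & ~pos_p)),
    )
    return {
        "counts": counts,
        "sensitivity": _ratio(counts.TP, counts.P, "sensitivity"),
        "specificity": _ratio(counts.TN, counts.N, "specificity"),
        "ppv": _ratio(counts.TP, counts.TP + counts.FP, "PPV"),
        "npv": _ratio(counts.TN, counts.TN + counts.FN, "NPV"),
        "accuracy": (counts.TP + counts.TN) / counts.total,
    }


# ---------------------------------------------------------------------------
# splitting and cross-validation
# ---------------------------------------------------------------------------

def stratified_split(table: pd.DataFrame, test_fraction: float = 0.3,
                     seed: int = 0, stratify_col: str = "cohort"):
    """Disjoint covering train/test split preserving per-cohort proportions."""
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    test_idx: list[int] = []
    for _, group in table.groupby(stratify_col, sort=True):
        if len(group) < 2:
            raise ValueError(
                f"stratum {group[stratify_col].iloc[0]!r} has < 2 members"
            )
        order = rng.permutation(len(group))
        n_test = int(round(test_fraction * len(group)))
        n_test = min(max(n_test, 1), len(group) - 1)
        test_idx.extend(group.index[order[:n_test]])
    test_mask = table.index.isin(test_idx)
    return table.loc[~test_mask].copy(), table.loc[test_mask].copy()


def _stratified_folds(y: np.ndarray, n_folds: int,
                      rng: np.random.Generator) -> list[np.ndarray]:
    folds: list[list[int]] = [[] for _ in range(n_folds)]
    for c in sorted(set(y)):
        idx = np.nonzero(y == c)[0]
        if len(idx) < n_folds:
            raise ValueError(
                f"class {c!r} has {len(idx)} samples for {n_folds} folds"
            )
        idx = rng.permutation(idx)
        for i, j in enumerate(idx):
            folds[i % n_folds].append(int(j))
    return [np.array(sorted(f)) for f in folds]


@dataclass
class CvReport:
    task_name: str
    per_fold_counts: list[ConfusionCounts]
    metrics_mean: dict
    metrics_std: dict
    fold_size: float
    seed: int


def kfold_cv(features: np.ndarray, labels, positive_class: str,
             n_folds: int = 6, seed: int = 0, shrinkage: float = 0.1,
             task_name: str = "") -> CvReport:
    """Stratified k-fold CV: every sample is validated exactly once.

    Reports mean and SD of sensitivity, specificity and PPV across folds;
    undefined per-fold metrics are NaN and excluded from the aggregation
    via nan-aware statistics.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray([str(v) for v in labels])
    rng = np.random.default_rng(seed)
    folds = _stratified_folds(y, n_folds, rng)
    per_fold = {"sensitivity": [], "specificity": [], "ppv": []}
    counts_list = []
    for k in range(n_folds):
        val = folds[k]
        train = np.setdiff1d(np.arange(len(y)), val)
        model = lda_fit(X[train], y[train], shrinkage)
        pred, _ = lda_predict(model, X[val])
        m = confusion_metrics(y[val], pred, positive_class)
        counts_list.append(m["counts"])
        for key in per_fold:
            per_fold[key].append(m[key])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = {k: float(np.nanmean(v)) for k, v in per_fold.items()}
        std = {k: float(np.nanstd(v)) for k, v in per_fold.items()}
    return CvReport(
        task_name=task_name, per_fold_counts=counts_list,
        metrics_mean=mean, metrics_std=std,
        fold_size=len(y) / n_folds, seed=seed,
    )


# ---------------------------------------------------------------------------
# the five comparison tasks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ComparisonTask:
    """Binary comparison over the cohorts; positive = first-named side."""

    name: str
    label_map: dict = field(hash=False)
    positive_class: str = "pos"

    def apply(self, table: pd.DataFrame) -> pd.DataFrame:
        keep = table["cohort"].isin(self.label_map)
        out = table.loc[keep].copy()
        if out.empty or set(out["cohort"].map(self.label_map)) != {
            self.positive_class, "neg"
        }:
            raise ValueError(f"task {self.name!r}: a cohort side is missing")
        out["y"] = out["cohort"].map(self.label_map)
        return out


STANDARD_TASKS = (
    ComparisonTask("A&B vs C", {"A": "pos", "B": "pos", "C": "neg"}),
    ComparisonTask("B&C vs A", {"B": "pos", "C": "pos", "A": "neg"}),
    ComparisonTask("A vs B", {"A": "pos", "B": "neg"}),
    ComparisonTask("A vs C", {"A": "pos", "C": "neg"}),
    ComparisonTask("B vs C", {"B": "pos", "C": "neg"}),
)

FEATURE_COLUMNS = ("alpha", "sigma")


def run_comparisons(
    features_table: pd.DataFrame,
    tasks=STANDARD_TASKS,
    test_fraction: float = 0.3,
    n_folds: int = 6,
    seed: int = 0,
    shrinkage: float = 0.1,
    feature_columns=FEATURE_COLUMNS,
):
    """Run the five binary comparisons end to end.

    For each task: stratified 70/30 split on the included cohorts, k-fold CV
    on the training portion, a final model on the full training portion
    evaluated on the held-out test set.  Returns ``(cv_table, test_table,
    raw)`` where the tables have one row per task (CV table: mean/SD of
    sensitivity, specificity, PPV and fold size; test table: the four
    confusion metrics) and ``raw`` maps task name to the CvReport and test
    confusion counts.
    """
    missing = {"cohort", *feature_columns} - set(features_table.columns)
    if missing:
        raise ValueError(f"features table missing columns {sorted(missing)}")
    present = set(features_table["cohort"])
    cv_rows, test_rows, raw = [], [], {}
    for task in tasks:
        needed = set(task.label_map)
        if not needed <= present:
            raise ValueError(
                f"task {task.name!r} needs cohorts {sorted(needed)}; "
                f"table has {sorted(present)}"
            )
        sub = task.apply(features_table)
        train, test = stratified_split(sub, test_fraction, seed=seed)
        X_tr = train.loc[:, feature_columns].to_numpy(dtype=float)
        y_tr = train["y"].to_numpy()
        smallest = min(np.sum(y_tr == c) for c in set(y_tr))
        folds = min(n_folds, int(smallest))
        if folds < n_folds:
            warnings.warn(
                f"task {task.name!r}: clamping folds {n_folds} -> {folds} "
                f"(smallest training class has {smallest} samples)",
                stacklevel=2,
            )
        report = kfold_cv(X_tr, y_tr, task.positive_class, n_folds=folds,
                          seed=seed, shrinkage=shrinkage, task_name=task.name)
        model = lda_fit(X_tr, y_tr, shrinkage)
        X_te = test.loc[:, feature_columns].to_numpy(dtype=float)
        pred, _ = lda_predict(model, X_te)
        m = confusion_metrics(test["y"].to_numpy(), pred, task.positive_class)
        cv_rows.append({
            "task": task.name,
            "sensitivity": report.metrics_mean["sensitivity"],
            "sensitivity_std": report.metrics_std["sensitivity"],
            "specificity": report.metrics_mean["specificity"],
            "specificity_std": report.metrics_std["specificity"],
            "ppv": report.metrics_mean["ppv"],
            "ppv_std": report.metrics_std["ppv"],
            "fold_size": report.fold_size,
        })
        test_rows.append({
            "task": task.name,
            "sensitivity": m["sensitivity"],
            "specificity": m["specificity"],
            "ppv": m["ppv"],
            "npv": m["npv"],
        })
        raw[task.name] = {"cv": report, "test_counts": m["counts"],
                          "test_accuracy": m["accuracy"]}
    return pd.DataFrame(cv_rows), pd.DataFrame(test_rows), raw
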