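"""Metrics, subject-wise cross-validation and experiment drivers.

Classification quality is summarized by a class-by-class confusion table:
entry (i, j) counts windows of true class i predicted as class j.  From it,

* accuracy  = diagonal sum / total x 100,
* recall(i) = diagonal(i) / row total(i) x 100,
* precision(i) = diagonal(i) / column total(i) x 100,

with zero-denominator entries reported as undefined (NaN), never as zero.

Cross-validation is subject-wise: subjects (not windows) are partitioned
into folds, so no subject's windows ever appear on both sides of a split.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier

from . import solvers
from .dcs import compress_windows, make_measurement_scheme, measurements_for_ratio
from .jsrc import (
    JointCoefficients,
    NeighborJSRCClassifier,
    build_dictionary,
    residual_classify,
)
from .synthetic import LabeledDataset

__all__ = [
    "ConfusionTable",
    "confusion_metrics",
    "CVPlan",
    "make_cv_plan",
    "ModelSettings",
    "CVResult",
    "run_cv",
    "baseline_classify",
    "cr_sweep",
]


@dataclass
class ConfusionTable:
    """L x L nonnegative integer counts; entry (i, j) = true i, predicted j."""

    counts: np.ndarray
    class_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("confusion counts must be a square matrix")
        if np.any(self.counts < 0):
            raise ValueError("confusion counts must be nonnegative")
        if self.class_names is not None and len(self.class_names) != self.counts.shape[0]:
            raise ValueError("one class name per row is required")

    @classmethod
    def from_predictions(
        cls, y_true: np.ndarray, y_pred: np.ndarray, classes: np.ndarray
    ) -> "ConfusionTable":
        classes = np.asarray(classes)
        index = {c: i for i, c in enumerate(classes.tolist())}
        counts = np.zeros((classes.size, classes.size), dtype=int)
        for t, p in zip(np.asarray(y_true).ravel(), np.asarray(y_pred).ravel()):
            counts[index[t], index[p]] += 1
        return cls(counts=counts, class_names=[str(c) for c in classes])

    def __add__(self, other: "ConfusionTable") -> "ConfusionTable":
        if self.counts.shape != other.counts.shape:
            raise ValueError("cannot pool confusion tables of different sizes")
        return ConfusionTable(
            counts=self.counts + other.counts, class_names=self.class_names
        )

    @property
    def n_total(self) -> int:
        return int(self.counts.sum())

    @property
    def n_correct(self) -> int:
        return int(np.trace(self.counts))


def confusion_metrics(table: ConfusionTable) -> dict[str, np.ndarray | float]:
    """Accuracy and per-class precision/recall, all in percent."""
    counts = table.counts.astype(float)
    total = counts.sum()
    if total <= 0:
        raise ValueError("confusion table is empty")
    diag = np.diag(counts)
    row = counts.sum(axis=1)
    col = counts.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        recall = np.where(row > 0, diag / row * 100.0, np.nan)
        precision = np.where(col > 0, diag / col * 100.0, np.nan)
    return {
        "accuracy": float(diag.sum() / total * 100.0),
        "recall": recall,
        "precision": precision,
    }


@dataclass
class CVPlan:
    """Subject-wise fold assignments: outer folds plus nested inner folds.

    ``outer[f]`` is the array of subjects held out in outer fold f;
    ``inner[f][g]`` partitions that fold's training subjects for nested
    model development.
    """

    outer: list[np.ndarray]
    inner: list[list[np.ndarray]]
    seed: int

    def __post_init__(self) -> None:
        all_subjects = np.concatenate(self.outer)
        if len(np.unique(all_subjects)) != all_subjects.size:
            raise ValueError("outer folds must partition subjects (no repeats)")
        for f, groups in enumerate(self.inner):
            train = np.concatenate(groups) if groups else np.array([])
            if np.intersect1d(train, self.outer[f]).size:
                raise ValueError(f"inner folds of outer fold {f} leak test subjects")

    @property
    def subjects(self) -> np.ndarray:
        return np.sort(np.concatenate(self.outer))


def make_cv_plan(
    subjects, outer_folds: int = 10, inner_folds: int = 9, seed: int = 0
) -> CVPlan:
    """Seeded random subject partition with a nested inner partition.

    Every subject is held out in exactly one outer fold; within each outer
    training set the remaining subjects are partitioned again into
    ``inner_folds`` groups.
    """
    uniq = np.unique(np.asarray(subjects))
    if outer_folds < 1 or outer_folds > uniq.size:
        raise ValueError(
            f"outer_folds={outer_folds} must lie in 1..{uniq.size} subjects"
        )
    rng = np.random.default_rng(seed)
    shuffled = rng.permutation(uniq)
    outer = [np.sort(g) for g in np.array_split(shuffled, outer_folds)]
    inner: list[list[np.ndarray]] = []
    for f in range(outer_folds):
        train = np.concatenate([outer[g] for g in range(outer_folds) if g != f])
        if inner_folds < 1 or inner_folds > train.size:
            raise ValueError(
                f"inner_folds={inner_folds} must lie in 1..{train.size} "
                "training subjects"
            )
        perm = rng.permutation(train)
        inner.append([np.sort(g) for g in np.array_split(perm, inner_folds)])
    return CVPlan(outer=outer, inner=inner, seed=seed)


@dataclass(frozen=True)
class ModelSettings:
    """One experiment's classifier and measurement configuration."""

    cr: float = 50.0
    scheme_kind: str = "sparse_binary"
    scheme_seed: int = 0
    lam: float = 1e-3
    m: int = 40
    k: int = 20
    solver: str = "greedy"
    neighbor_method: str = "srcc"


@dataclass
class CVResult:
    """Pooled and per-fold confusion tables plus summary metrics."""

    pooled: ConfusionTable
    fold_tables: list[ConfusionTable]
    metrics: dict
    mean_time_per_sample: float
    settings: ModelSettings
    plan: CVPlan = field(repr=False, default=None)
    neighbor_sizes: list[int] = field(repr=False, default_factory=list)

    @property
    def accuracy(self) -> float:
        return self.metrics["accuracy"]


def run_cv(
    dataset: LabeledDataset,
    settings: ModelSettings,
    plan: CVPlan | None = None,
    outer_folds: int = 10,
    inner_folds: int | None = None,
    seed: int = 0,
) -> CVResult:
    """Subject-wise cross-validation of the compressed-domain classifier.

    One measurement scheme is drawn (from ``settings.scheme_seed``) and
    shared by all folds, training and test alike; all windows are compressed
    once up front.  Per fold the classifier trains on the outer-training
    subjects only and predicts the held-out subjects; predictions accumulate
    into one pooled confusion table.  Wall-clock time per classification is
    recorded for information only.
    """
    subjects = dataset.subjects
    if plan is None:
        uniq = np.unique(subjects)
        if inner_folds is None:
            inner_folds = max(1, min(outer_folds - 1, uniq.size - 1))
        plan = make_cv_plan(uniq, outer_folds, inner_folds, seed)
    if np.setdiff1d(subjects, plan.subjects).size:
        raise ValueError("the CV plan does not cover every dataset subject")

    h = dataset.window_len
    M = measurements_for_ratio(h, settings.cr)
    scheme = make_measurement_scheme(
        dataset.n_sensors, h, M, kind=settings.scheme_kind, seed=settings.scheme_seed
    )
    Z = compress_windows(dataset.as_array(), scheme)
    labels = dataset.labels
    classes = np.arange(1, dataset.n_classes + 1)

    fold_tables: list[ConfusionTable] = []
    neighbor_sizes: list[int] = []
    elapsed = 0.0
    n_classified = 0
    for test_subjects in plan.outer:
        test_mask = np.isin(subjects, test_subjects)
        train_mask = ~test_mask
        if np.any(test_mask & train_mask):  # pragma: no cover - defensive
            raise RuntimeError("subject leakage between train and test split")
        clf = NeighborJSRCClassifier(
            scheme,
            lam=settings.lam,
            m=settings.m,
            k=settings.k,
            solver=settings.solver,
            neighbor_method=settings.neighbor_method,
        ).fit(Z[train_mask], labels[train_mask])
        t0 = time.perf_counter()
        pred = clf.predict(Z[test_mask])
        elapsed += time.perf_counter() - t0
        n_classified += int(test_mask.sum())
        neighbor_sizes.extend(clf.neighbor_sizes)
        fold_tables.append(
            ConfusionTable.from_predictions(labels[test_mask], pred, classes)
        )
    pooled = fold_tables[0]
    for t in fold_tables[1:]:
        pooled = pooled + t
    return CVResult(
        pooled=pooled,
        fold_tables=fold_tables,
        metrics=confusion_metrics(pooled),
        mean_time_per_sample=elapsed / max(n_classified, 1),
        settings=settings,
        plan=plan,
        neighbor_sizes=neighbor_sizes,
    )


def baseline_classify(
    test: np.ndarray,
    train: np.ndarray,
    labels: np.ndarray,
    method: str = "src",
    params: dict | None = None,
) -> np.ndarray | int:
    """Single-measurement baseline classifiers on compressed vectors.

    ``src`` codes the concatenated vector with greedy pursuit (``k`` atoms,
    default 20) over the training dictionary and applies the minimal
    residual rule; ``knn`` majority-votes the ``k`` nearest training
    vectors (default 1); ``nbc`` is Gaussian naive Bayes on the vector
    entries.  ``test`` may be one vector or a (T, D) stack.
    """
    params = params or {}
    train = np.atleast_2d(np.asarray(train, dtype=float))
    if train.shape[0] == 0:
        raise ValueError("training set is empty")
    labels = np.asarray(labels, dtype=int)
    tests = np.atleast_2d(np.asarray(test, dtype=float))
    single = np.asarray(test).ndim == 1

    if method == "knn":
        clf = KNeighborsClassifier(n_neighbors=int(params.get("k", 1)))
        pred = clf.fit(train, labels).predict(tests)
    elif method == "nbc":
        pred = GaussianNB().fit(train, labels).predict(tests)
    elif method == "src":
        dictionary = build_dictionary(train, labels, n_sensors=1)
        k = int(params.get("k", 20))
        pred = np.empty(tests.shape[0], dtype=int)
        for i, y in enumerate(tests):
            res = solvers.somp([y], [dictionary.atoms], min(k, dictionary.n))
            coeffs = JointCoefficients(
                W=res.coefficients,
                support=res.support,
                k=k,
                solver="greedy",
                residuals=y - dictionary.atoms @ res.coefficients[:, 0],
            )
            pred[i] = residual_classify(y, dictionary, coeffs).label
    else:
        raise ValueError(f"unknown baseline method {method!r}")
    return int(pred[0]) if single else pred


def cr_sweep(
    dataset: LabeledDataset,
    cr_grid,
    m_grid,
    solvers_grid=("greedy",),
    seed: int = 0,
    outer_folds: int = 10,
    out_csv=None,
) -> pd.DataFrame:
    """Accuracy/time grid over compression ratios, neighbor counts, solvers.

    Every grid point reruns the identical subject-wise CV plan (same seed)
    so rows differ only in the swept parameter.  The per-sample time column
    is informational only.  Returns a tidy DataFrame and optionally writes
    it to CSV.
    """
    cr_grid = list(cr_grid)
    m_grid = list(m_grid)
    if not cr_grid or not m_grid:
        raise ValueError("cr_grid and m_grid must be nonempty")
    for cr in cr_grid:
        if not 0 <= cr < 100:
            raise ValueError(f"compression ratio {cr} outside [0, 100)")
    uniq = np.unique(dataset.subjects)
    inner = max(1, min(outer_folds - 1, uniq.size - 1))
    plan = make_cv_plan(uniq, outer_folds, inner, seed)
    rows = []
    for solver in solvers_grid:
        for cr in cr_grid:
            for m in m_grid:
                settings = ModelSettings(cr=cr, m=m, solver=solver, scheme_seed=seed)
                result = run_cv(dataset, settings, plan=plan)
                rows.append(
                    {
                        "cr": cr,
                        "m": m,
                        "solver": solver,
                        "accuracy": result.accuracy,
                        "mean_time_per_sample": result.mean_time_per_sample,
                    }
                )
    frame = pd.DataFrame(rows)
    if out_csv is not None:
        frame.to_csv(out_csv, index=False)
    return frame
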