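"""Compressed-domain joint sparse representation classification (JSRC).

The dictionary atoms are the compressed training windows themselves, one
unit-normalized column per sample, grouped contiguously by class.  A test
window, compressed with the *same* measurement scheme, is coded jointly
over the atoms — one coding task per sensor, coupled by a shared row
support — and labeled by the class whose atoms reconstruct it with the
smallest residual.

Before coding, the dictionary is pruned per test sample: the ridge
(l2-regularized) representation of the test vector over all atoms is
solved per sensor in closed form, the per-atom coefficient magnitudes are
averaged across sensors (the SRCC score), and only the m highest-scoring
atoms of each class are kept.  A plain nearest-neighbor pruning is provided
as a comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from . import solvers
from .dcs import MeasurementScheme, compress_window
from .preprocessing import GaitWindowSample

logger = logging.getLogger(__name__)

__all__ = [
    "TrainingDictionary",
    "NeighborDictionary",
    "JointCoefficients",
    "ClassificationResult",
    "PipelineModel",
    "build_dictionary",
    "RidgeScorer",
    "srcc_neighbors",
    "knn_neighbors",
    "solve_joint",
    "residual_classify",
    "classify_pipeline",
]


def _sensor_slices(n_rows: int, n_sensors: int) -> list[slice]:
    if n_rows % n_sensors != 0:
        raise ValueError(
            f"{n_rows} rows cannot be partitioned into {n_sensors} equal "
            "sensor blocks"
        )
    d = n_rows // n_sensors
    return [slice(j * d, (j + 1) * d) for j in range(n_sensors)]


@dataclass
class TrainingDictionary:
    """Over-complete dictionary of compressed training samples.

    ``atoms`` is (D, n) with unit-norm columns grouped contiguously by
    ascending class label; ``labels`` gives the class of each column.  Rows
    are partitioned into ``n_sensors`` equal contiguous blocks, one per
    sensor, in sensor order.
    """

    atoms: np.ndarray
    labels: np.ndarray
    n_sensors: int

    def __post_init__(self) -> None:
        self.atoms = np.asarray(self.atoms, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.atoms.ndim != 2 or self.atoms.shape[1] != self.labels.size:
            raise ValueError("atoms must be (D, n) with one label per column")
        if np.any(np.diff(self.labels) < 0):
            raise ValueError("columns must be grouped by ascending class label")
        _sensor_slices(self.atoms.shape[0], self.n_sensors)

    @property
    def n(self) -> int:
        return self.atoms.shape[1]

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.labels)

    @property
    def class_counts(self) -> dict[int, int]:
        vals, counts = np.unique(self.labels, return_counts=True)
        return dict(zip(vals.tolist(), counts.tolist()))

    @property
    def sensor_slices(self) -> list[slice]:
        return _sensor_slices(self.atoms.shape[0], self.n_sensors)


@dataclass
class NeighborDictionary:
    """A per-test-sample pruned dictionary: min(m, n_i) atoms per class.

    ``indices`` point back into the parent dictionary's columns; ``scores``
    are the selection scores (SRCC ridge magnitudes, or negative distances
    for nearest-neighbor pruning).
    """

    atoms: np.ndarray
    labels: np.ndarray
    n_sensors: int
    indices: np.ndarray
    scores: np.ndarray
    m: int
    ridge_lambda: float | None = None

    def __post_init__(self) -> None:
        self.atoms = np.asarray(self.atoms, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        self.indices = np.asarray(self.indices, dtype=int)
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("selection scores must be finite")

    @property
    def n(self) -> int:
        return self.atoms.shape[1]

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.labels)

    @property
    def sensor_slices(self) -> list[slice]:
        return _sensor_slices(self.atoms.shape[0], self.n_sensors)


def build_dictionary(
    train: np.ndarray | list[np.ndarray], labels: np.ndarray, n_sensors: int
) -> TrainingDictionary:
    """Assemble the over-complete dictionary from compressed training samples.

    Samples become columns, sorted stably by class label so class blocks are
    contiguous, and each column is scaled to unit Euclidean norm.
    """
    X = np.atleast_2d(np.asarray(train, dtype=float))
    labels = np.asarray(labels, dtype=int)
    if X.shape[0] == 0:
        raise ValueError("training set is empty")
    if X.shape[0] != labels.size:
        raise ValueError("one label per training sample is required")
    order = np.argsort(labels, kind="stable")
    atoms = X[order].T.copy()
    norms = np.linalg.norm(atoms, axis=0)
    if np.any(norms <= 0):
        raise ValueError("training samples must be nonzero to become atoms")
    atoms /= norms
    return TrainingDictionary(
        atoms=atoms, labels=labels[order], n_sensors=n_sensors
    )


class RidgeScorer:
    """Closed-form per-sensor ridge coder against a fixed dictionary.

    For sensor block ``A_j`` (rows of the dictionary belonging to sensor j)
    and test block ``y_j``, the ridge coefficients are
    ``w_j = (A_j^T A_j + lambda I)^-1 A_j^T y_j``, evaluated through the
    dual identity ``A_j^T (A_j A_j^T + lambda I)^-1 y_j`` so the factorized
    system has the (smaller) row dimension and can be reused across test
    samples.
    """

    def __init__(self, dictionary: TrainingDictionary | NeighborDictionary, lam: float):
        if lam <= 0:
            raise ValueError(f"ridge penalty lambda must be positive, got {lam}")
        self.dictionary = dictionary
        self.lam = lam
        self._factors = []
        for sl in dictionary.sensor_slices:
            B = dictionary.atoms[sl]
            G = B @ B.T + lam * np.eye(B.shape[0])
            self._factors.append((B, scipy.linalg.cho_factor(G, lower=True)))

    def coefficients(self, tests: np.ndarray) -> np.ndarray:
        """Per-sensor ridge coefficients, shape (J, n_atoms, T)."""
        Y = np.asarray(tests, dtype=float)
        squeeze = Y.ndim == 1
        if squeeze:
            Y = Y[:, None]
        out = np.empty((len(self._factors), self.dictionary.n, Y.shape[1]))
        for j, (sl, (B, cho)) in enumerate(
            zip(self.dictionary.sensor_slices, self._factors)
        ):
            out[j] = B.T @ scipy.linalg.cho_solve(cho, Y[sl])
        return out[:, :, 0] if squeeze else out

    def scores(self, tests: np.ndarray) -> np.ndarray:
        """SRCC score per atom: mean absolute ridge coefficient over sensors."""
        return np.mean(np.abs(self.coefficients(tests)), axis=0)


def _select_top_per_class(
    scores: np.ndarray, labels: np.ndarray, m: int
) -> np.ndarray:
    """Indices of the min(m, n_i) highest-scoring atoms within each class.

    Ties break toward the lower column index; the returned indices are
    sorted ascending, which keeps class blocks contiguous.
    """
    selected = []
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        order = np.argsort(-scores[idx], kind="stable")
        selected.append(idx[order[: min(m, idx.size)]])
    return np.sort(np.concatenate(selected))


def srcc_neighbors(
    test: np.ndarray,
    dictionary: TrainingDictionary,
    lam: float = 1e-3,
    m: int = 40,
    pooled: bool = False,
) -> NeighborDictionary:
    """Prune the dictionary with the sparse-representation-coefficient rule.

    Solves the per-sensor ridge representation of ``test`` over all atoms,
    averages coefficient magnitudes across sensors, and keeps the
    min(m, n_i) top-scoring atoms of every class.  With ``pooled=True`` a
    single ridge problem over the full stacked rows is solved instead of
    one per sensor (an interpretation variant, not the default).
    """
    if m < 1:
        raise ValueError(f"m must be >= 1, got {m}")
    if pooled:
        pooled_dict = TrainingDictionary(
            atoms=dictionary.atoms, labels=dictionary.labels, n_sensors=1
        )
        scores = RidgeScorer(pooled_dict, lam).scores(test)
    else:
        scores = RidgeScorer(dictionary, lam).scores(test)
    indices = _select_top_per_class(scores, dictionary.labels, m)
    return NeighborDictionary(
        atoms=dictionary.atoms[:, indices],
        labels=dictionary.labels[indices],
        n_sensors=dictionary.n_sensors,
        indices=indices,
        scores=scores[indices],
        m=m,
        ridge_lambda=lam,
    )


def knn_neighbors(
    test: np.ndarray, dictionary: TrainingDictionary, m: int
) -> NeighborDictionary:
    """Prune to the min(m, n_i) atoms per class nearest to the test vector.

    The test vector is unit-normalized before the Euclidean comparison so
    the selection, like the atoms, is scale-free.
    """
    if m < 1:
        raise ValueError(f"m must be >= 1, got {m}")
    y = np.asarray(test, dtype=float).ravel()
    norm = np.linalg.norm(y)
    if norm > 0:
        y = y / norm
    distances = np.linalg.norm(dictionary.atoms - y[:, None], axis=0)
    indices = _select_top_per_class(-distances, dictionary.labels, m)
    return NeighborDictionary(
        atoms=dictionary.atoms[:, indices],
        labels=dictionary.labels[indices],
        n_sensors=dictionary.n_sensors,
        indices=indices,
        scores=-distances[indices],
        m=m,
        ridge_lambda=None,
    )


@dataclass
class JointCoefficients:
    """Row-sparse coding of one test sample over a (pruned) dictionary.

    ``W`` is (n_atoms, J): column j codes sensor j's measurement block.
    ``residuals`` is the stacked fit residual ``Y - A W`` (per-sensor blocks
    concatenated).  ``alpha``/``beta0`` hold the Bayesian solver's
    hyperparameters (per-atom prior precisions and noise precision) and are
    ``None`` for the greedy solver.
    """

    W: np.ndarray
    support: np.ndarray
    k: int
    solver: str
    residuals: np.ndarray
    alpha: np.ndarray | None = None
    beta0: float | None = None
    converged: bool = True

    @property
    def n_active_rows(self) -> int:
        return int(np.sum(np.any(self.W != 0.0, axis=1)))


def _split_blocks(Y: np.ndarray, dictionary) -> tuple[list, list]:
    Y = np.asarray(Y, dtype=float).ravel()
    if Y.size != dictionary.atoms.shape[0]:
        raise ValueError(
            f"measurement length {Y.size} does not match dictionary rows "
            f"{dictionary.atoms.shape[0]}"
        )
    ys = [Y[sl] for sl in dictionary.sensor_slices]
    Ds = [dictionary.atoms[sl] for sl in dictionary.sensor_slices]
    return ys, Ds


def solve_joint(
    Y: np.ndarray,
    A: NeighborDictionary | TrainingDictionary,
    k: int = 20,
    method: str = "greedy",
    tol: float = 1e-6,
    max_iter: int = 200,
) -> JointCoefficients:
    """Estimate the shared-row-support coefficient matrix W for one sample.

    ``greedy`` runs simultaneous OMP across the J sensor tasks with at most
    ``k`` active rows; ``mbcs`` runs the multitask Bayesian solver (k is
    ignored there — row sparsity emerges from the prior).  Non-convergence
    of the Bayesian solver is flagged on the result and logged, not raised.
    """
    ys, Ds = _split_blocks(Y, A)
    if method == "greedy":
        if k < 1:
            raise ValueError("greedy solver needs k >= 1")
        res = solvers.somp(ys, Ds, min(k, A.atoms.shape[1]))
        W, support, alpha, beta0, converged = (
            res.coefficients,
            res.support,
            None,
            None,
            True,
        )
    elif method == "mbcs":
        res = solvers.mbcs(ys, Ds, tol=tol, max_iter=max_iter)
        W, support, alpha, beta0, converged = (
            res.coefficients,
            res.support,
            res.alpha,
            res.beta0,
            res.converged,
        )
        if not converged:
            logger.warning("MBCS did not converge within %d iterations", max_iter)
    else:
        raise ValueError(f"unknown solver {method!r}; expected 'greedy' or 'mbcs'")
    residuals = np.concatenate(
        [y - D @ W[:, j] for j, (y, D) in enumerate(zip(ys, Ds))]
    )
    return JointCoefficients(
        W=W,
        support=support,
        k=k,
        solver=method,
        residuals=residuals,
        alpha=alpha,
        beta0=beta0,
        converged=converged,
    )


@dataclass
class ClassificationResult:
    """Minimal-residual-rule outcome for one test sample.

    ``residuals[i]`` is the l2 reconstruction error using only class
    ``classes[i]``'s rows of W (the class-indicator mask); the label is the
    argmin with ties broken toward the smallest class index.
    ``masked_coefficients`` maps each class to its indicator-masked
    coefficient matrix; the masks partition W exactly.
    """

    label: int
    classes: np.ndarray
    residuals: np.ndarray
    masked_coefficients: dict[int, np.ndarray] = field(repr=False, default_factory=dict)


def residual_classify(
    Y: np.ndarray,
    A: NeighborDictionary | TrainingDictionary,
    coefficients: JointCoefficients,
    all_classes: np.ndarray | None = None,
) -> ClassificationResult:
    """Label a sample by the class whose atoms reconstruct it best.

    For each class i the coefficient rows of other classes are zeroed and
    the residual ``||Y - A delta_i(W)||_2`` is computed over the full
    stacked measurement vector.  Classes in ``all_classes`` missing from the
    dictionary score ``||Y||_2`` (an all-zero mask).
    """
    ys, Ds = _split_blocks(Y, A)
    W = coefficients.W
    if W.shape[0] != A.atoms.shape[1]:
        raise ValueError("coefficient rows do not match dictionary atoms")
    classes = np.unique(all_classes) if all_classes is not None else A.classes
    y_norm = float(np.linalg.norm(np.asarray(Y, dtype=float)))
    residuals = np.empty(classes.size)
    masked: dict[int, np.ndarray] = {}
    for i, c in enumerate(classes):
        mask = A.labels == c
        delta = np.where(mask[:, None], W, 0.0)
        masked[int(c)] = delta
        if not np.any(mask):
            residuals[i] = y_norm
            continue
        sq = 0.0
        for j, (y, D) in enumerate(zip(ys, Ds)):
            sq += float(np.sum((y - D[:, mask] @ W[mask, j]) ** 2))
        residuals[i] = np.sqrt(sq)
    label = int(classes[int(np.argmin(residuals))])  # argmin: first min wins
    return ClassificationResult(
        label=label, classes=classes, residuals=residuals, masked_coefficients=masked
    )


@dataclass
class PipelineModel:
    """Everything needed to classify a raw window end to end.

    The measurement scheme is drawn once per experiment and shared by the
    training atoms and every test sample: compressed-domain coding requires
    both to live in the same measurement space.
    """

    scheme: MeasurementScheme
    dictionary: TrainingDictionary
    lam: float = 1e-3
    m: int = 40
    k: int = 20
    solver: str = "greedy"
    neighbor_method: str = "srcc"


def classify_pipeline(
    sample: GaitWindowSample, model: PipelineModel
) -> ClassificationResult:
    """Compress -> prune neighbors -> joint solve -> residual rule."""
    y = compress_window(sample, model.scheme)
    if model.neighbor_method == "srcc":
        neighbors = srcc_neighbors(y, model.dictionary, lam=model.lam, m=model.m)
    elif model.neighbor_method == "knn":
        neighbors = knn_neighbors(y, model.dictionary, m=model.m)
    else:
        raise ValueError(f"unknown neighbor method {model.neighbor_method!r}")
    coeffs = solve_joint(y, neighbors, k=model.k, method=model.solver)
    return residual_classify(y, neighbors, coeffs, all_classes=model.dictionary.classes)


class NeighborJSRCClassifier:
    """Batch front end over the pipeline stages for cross-validation runs.

    Precomputes the per-sensor ridge factorization once per training set so
    scoring all test samples is two triangular solves per sensor; the
    per-sample pruning, joint solve and residual rule are the same public
    functions used one sample at a time.  ``neighbor_sizes`` records the
    pruned-dictionary column count of every prediction.
    """

    def __init__(
        self,
        scheme: MeasurementScheme,
        lam: float = 1e-3,
        m: int = 40,
        k: int = 20,
        solver: str = "greedy",
        neighbor_method: str = "srcc",
    ):
        self.scheme = scheme
        self.lam = lam
        self.m = m
        self.k = k
        self.solver = solver
        self.neighbor_method = neighbor_method
        self.dictionary: TrainingDictionary | None = None
        self._scorer: RidgeScorer | None = None
        self.neighbor_sizes: list[int] = []

    def fit(self, compressed_train: np.ndarray, labels: np.ndarray):
        self.dictionary = build_dictionary(
            compressed_train, labels, n_sensors=self.scheme.n_sensors
        )
        if self.neighbor_method == "srcc":
            self._scorer = RidgeScorer(self.dictionary, self.lam)
        return self

    def predict(self, compressed_tests: np.ndarray) -> np.ndarray:
        if self.dictionary is None:
            raise RuntimeError("classifier is not fitted")
        tests = np.atleast_2d(np.asarray(compressed_tests, dtype=float))
        if self.neighbor_method == "srcc":
            all_scores = self._scorer.scores(tests.T)  # (n_atoms, T)
        out = np.empty(tests.shape[0], dtype=int)
        for i, y in enumerate(tests):
            if self.neighbor_method == "srcc":
                idx = _select_top_per_class(
                    all_scores[:, i], self.dictionary.labels, self.m
                )
                neighbors = NeighborDictionary(
                    atoms=self.dictionary.atoms[:, idx],
                    labels=self.dictionary.labels[idx],
                    n_sensors=self.dictionary.n_sensors,
                    indices=idx,
                    scores=all_scores[idx, i],
                    m=self.m,
                    ridge_lambda=self.lam,
                )
            else:
                neighbors = knn_neighbors(y, self.dictionary, m=self.m)
            self.neighbor_sizes.append(neighbors.n)
            coeffs = solve_joint(y, neighbors, k=self.k, method=self.solver)
            out[i] = residual_classify(
                y, neighbors, coeffs, all_classes=self.dictionary.classes
            ).label
        return out
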