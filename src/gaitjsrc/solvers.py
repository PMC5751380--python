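"""Joint row-sparse solvers for multiple-measurement-vector problems.

All solvers address J coupled linear systems ``y_j ~ D_j w_j`` whose
coefficient vectors share one support (row-sparsity of the stacked
coefficient matrix W):

* :func:`somp` — Simultaneous Orthogonal Matching Pursuit: at each of k
  iterations select the atom maximizing the summed squared normalized
  correlation with every task's current residual, then re-fit all tasks by
  least squares on the selected set.
* :func:`osga` — One-Step Greedy Algorithm: rank atoms by the same summed
  correlation score of the *initial* residuals and take the top k in a
  single pass; a deliberately weak baseline.
* :func:`mbcs` — Multitask Bayesian compressive sensing: a hierarchical
  Gaussian model with per-atom prior precisions shared across tasks and a
  common noise precision, fit by evidence maximization with pruning of
  atoms whose precision diverges.

Ties in atom selection are always broken by the smallest index.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

__all__ = ["PursuitResult", "MbcsResult", "somp", "osga", "mbcs"]

_ZERO_NORM = 1e-12


@dataclass
class PursuitResult:
    """Outcome of a greedy joint pursuit.

    ``coefficients`` has shape (n_atoms, J); ``residual_norms`` has one row
    per completed iteration (plus the initial state), one column per task.
    ``selection_order`` lists atoms in the order they were picked.
    """

    support: np.ndarray
    coefficients: np.ndarray
    residual_norms: np.ndarray
    selection_order: list[int] = field(default_factory=list)

    @property
    def n_selected(self) -> int:
        return self.support.size


def _as_task_lists(ys, Ds):
    ys = [np.asarray(y, dtype=float).ravel() for y in ys]
    Ds = [np.asarray(D, dtype=float) for D in Ds]
    if len(ys) != len(Ds) or not ys:
        raise ValueError("need one dictionary per measurement vector")
    n_atoms = Ds[0].shape[1]
    for j, (y, D) in enumerate(zip(ys, Ds)):
        if D.shape[1] != n_atoms:
            raise ValueError(f"task {j}: dictionaries disagree on atom count")
        if D.shape[0] != y.size:
            raise ValueError(
                f"task {j}: dictionary rows {D.shape[0]} != measurement "
                f"length {y.size}"
            )
    return ys, Ds, n_atoms


def _correlation_scores(residuals, Ds, norms) -> np.ndarray:
    """Sum over tasks of squared normalized correlations, per atom."""
    n_atoms = Ds[0].shape[1]
    scores = np.zeros(n_atoms)
    for r, D, nrm in zip(residuals, Ds, norms):
        c = D.T @ r
        np.divide(c, nrm, out=c, where=nrm > _ZERO_NORM)
        c[nrm <= _ZERO_NORM] = 0.0
        scores += c**2
    return scores


def _refit(ys, Ds, support):
    """Per-task least squares on the selected atoms; returns coeffs + residuals."""
    coeffs = []
    residuals = []
    for y, D in zip(ys, Ds):
        sub = D[:, support]
        w, *_ = scipy.linalg.lstsq(sub, y, lapack_driver="gelsy")
        coeffs.append(w)
        residuals.append(y - sub @ w)
    return coeffs, residuals


def somp(ys: list[np.ndarray], Ds: list[np.ndarray], k: int) -> PursuitResult:
    """Simultaneous OMP over J tasks, selecting at most ``k`` shared atoms.

    Stops early if every task's residual correlation vanishes (exact fit or
    exhausted dictionary).
    """
    if k < 0:
        raise ValueError("k must be nonnegative")
    ys, Ds, n_atoms = _as_task_lists(ys, Ds)
    J = len(ys)
    norms = [np.linalg.norm(D, axis=0) for D in Ds]
    residuals = [y.copy() for y in ys]
    res_norms = [[np.linalg.norm(r) for r in residuals]]
    order: list[int] = []
    coeffs = [np.zeros(0)] * J
    for _ in range(min(k, n_atoms)):
        scores = _correlation_scores(residuals, Ds, norms)
        if order:
            scores[np.asarray(order)] = -np.inf
        idx = int(np.argmax(scores))  # argmax is stable: first max wins
        if not np.isfinite(scores[idx]) or scores[idx] <= _ZERO_NORM:
            break
        order.append(idx)
        coeffs, residuals = _refit(ys, Ds, order)
        res_norms.append([np.linalg.norm(r) for r in residuals])
    support = np.sort(np.asarray(order, dtype=int))
    W = np.zeros((n_atoms, J))
    if order:
        # _refit returned coefficients in selection order.
        for col, w in enumerate(coeffs):
            W[np.asarray(order, dtype=int), col] = w
    return PursuitResult(
        support=support,
        coefficients=W,
        residual_norms=np.asarray(res_norms),
        selection_order=order,
    )


def osga(ys: list[np.ndarray], Ds: list[np.ndarray], k: int) -> PursuitResult:
    """One-pass joint selection: top-``k`` atoms by initial correlation score."""
    if k < 0:
        raise ValueError("k must be nonnegative")
    ys, Ds, n_atoms = _as_task_lists(ys, Ds)
    J = len(ys)
    norms = [np.linalg.norm(D, axis=0) for D in Ds]
    res_norms = [[np.linalg.norm(y) for y in ys]]
    k = min(k, n_atoms)
    W = np.zeros((n_atoms, J))
    order: list[int] = []
    if k > 0:
        scores = _correlation_scores(ys, Ds, norms)
        order = list(np.argsort(-scores, kind="stable")[:k])
        coeffs, residuals = _refit(ys, Ds, order)
        for col, w in enumerate(coeffs):
            W[np.asarray(order, dtype=int), col] = w
        res_norms.append([np.linalg.norm(r) for r in residuals])
    return PursuitResult(
        support=np.sort(np.asarray(order, dtype=int)),
        coefficients=W,
        residual_norms=np.asarray(res_norms),
        selection_order=[int(i) for i in order],
    )


@dataclass
class MbcsResult:
    """Posterior summary of the multitask Bayesian solve.

    ``coefficients`` holds the per-task posterior means (n_atoms, J);
    ``alpha`` the shared per-atom prior precisions, ``beta0`` the noise
    precision.  Atoms whose precision diverged were
    pruned and have exactly zero coefficients.
    """

    coefficients: np.ndarray
    alpha: np.ndarray
    beta0: float
    active: np.ndarray
    converged: bool
    n_iter: int

    @property
    def support(self) -> np.ndarray:
        return np.flatnonzero(self.active)


def mbcs(
    ys: list[np.ndarray],
    Ds: list[np.ndarray],
    tol: float = 1e-6,
    max_iter: int = 200,
    prune_threshold: float = 1e8,
    beta0_max: float = 1e10,
) -> MbcsResult:
    """Multitask Bayesian compressive sensing by evidence maximization.

    Model: ``y_j ~ N(D_j w_j, 1/beta0 I)`` with a shared zero-mean Gaussian
    prior ``w_{j,i} ~ N(0, 1/alpha_i)`` coupling the tasks through one
    precision per atom.  Hyperparameters are re-estimated with MacKay
    fixed-point updates each sweep; atoms whose precision exceeds
    ``prune_threshold`` are removed from the model (their coefficients are
    exactly zero), which is what makes the posterior row-sparse.

    Iterates until the largest relative hyperparameter change drops below
    ``tol`` or ``max_iter`` sweeps elapse; non-convergence is flagged on the
    result, not raised.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    ys, Ds, n_atoms = _as_task_lists(ys, Ds)
    J = len(ys)
    total_rows = sum(y.size for y in ys)

    active = np.ones(n_atoms, dtype=bool)
    alpha = np.ones(n_atoms)
    y_var = np.mean([np.var(y) for y in ys])
    beta0 = 1.0 / max(0.1 * y_var, 1e-9)

    grams = [D.T @ D for D in Ds]
    proj = [D.T @ y for D, y in zip(Ds, ys)]

    mus = np.zeros((n_atoms, J))
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        idx = np.flatnonzero(active)
        if idx.size == 0:
            converged = True
            break
        sum_mu2 = np.zeros(idx.size)
        sum_gamma = np.zeros(idx.size)
        err = 0.0
        mus = np.zeros((n_atoms, J))
        for j in range(J):
            H = beta0 * grams[j][np.ix_(idx, idx)] + np.diag(alpha[idx])
            cho = scipy.linalg.cho_factor(H, lower=True)
            sigma = scipy.linalg.cho_solve(cho, np.eye(idx.size))
            mu = beta0 * (sigma @ proj[j][idx])
            mus[idx, j] = mu
            gamma = np.clip(1.0 - alpha[idx] * np.diag(sigma), 0.0, 1.0)
            sum_mu2 += mu**2
            sum_gamma += gamma
            err += np.sum((ys[j] - Ds[j][:, idx] @ mu) ** 2)
        alpha_new = np.where(
            sum_mu2 > _ZERO_NORM, sum_gamma / np.maximum(sum_mu2, _ZERO_NORM), np.inf
        )
        beta0_new = min(
            max(total_rows - np.sum(sum_gamma), _ZERO_NORM) / max(err, _ZERO_NORM),
            beta0_max,
        )
        keep = alpha_new < prune_threshold
        delta_alpha = np.abs(alpha_new[keep] - alpha[idx][keep]) / np.maximum(
            alpha[idx][keep], _ZERO_NORM
        )
        delta = max(
            delta_alpha.max(initial=0.0), abs(beta0_new - beta0) / max(beta0, _ZERO_NORM)
        )
        pruned_any = not np.all(keep)
        alpha[idx] = np.where(keep, np.maximum(alpha_new, _ZERO_NORM), np.inf)
        active[idx[~keep]] = False
        beta0 = beta0_new
        if not pruned_any and delta < tol:
            converged = True
            break
    mus[~active, :] = 0.0
    return MbcsResult(
        coefficients=mus,
        alpha=alpha,
        beta0=beta0,
        active=active,
        converged=converged,
        n_iter=n_iter,
    )
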