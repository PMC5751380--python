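"""Distributed compressed sensing of multi-sensor ensembles (JSM-2).

Each of the J sensors compresses its own length-N signal independently with
a per-sensor random block Phi_j (M x N), so the ensemble measurement
operator is block-diagonal.  Because the sensors share one sparse support
(JSM-2), the ensemble can be jointly reconstructed from far fewer rows than
independent single-signal recovery would need; the greedy joint solvers are
in :mod:`gaitjsrc.solvers`.

The compression ratio CR = (N - M)/N x 100% accounts energy savings on the
sensor: only M of every N samples are transmitted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import solvers
from .preprocessing import GaitWindowSample

__all__ = [
    "SensorEnsemble",
    "MeasurementScheme",
    "CompressedEnsemble",
    "make_measurement_scheme",
    "compress",
    "compress_window",
    "compress_windows",
    "compression_ratio",
    "measurements_for_ratio",
    "joint_reconstruct",
]


@dataclass
class SensorEnsemble:
    """J per-sensor signals of common length N, stacked as a (J, N) array."""

    signals: np.ndarray

    def __post_init__(self) -> None:
        self.signals = np.atleast_2d(np.asarray(self.signals, dtype=float))
        if not np.all(np.isfinite(self.signals)):
            raise ValueError("ensemble signals must be finite")

    @property
    def n_sensors(self) -> int:
        return self.signals.shape[0]

    @property
    def signal_len(self) -> int:
        return self.signals.shape[1]


@dataclass
class MeasurementScheme:
    """Block-diagonal measurement operator with per-sensor blocks Phi_j.

    ``kind`` is ``sparse_binary`` (exactly two unit entries per column, at
    distinct uniformly drawn rows) or ``gaussian`` (i.i.d. N(0, 1/M)).
    """

    blocks: list[np.ndarray]
    kind: str
    seed: int

    def __post_init__(self) -> None:
        self.blocks = [np.asarray(b, dtype=float) for b in self.blocks]
        if not self.blocks:
            raise ValueError("scheme needs at least one block")
        N = self.blocks[0].shape[1]
        for j, b in enumerate(self.blocks):
            if b.ndim != 2 or b.shape[1] != N:
                raise ValueError(f"block {j} has shape {b.shape}, expected (*, {N})")
            if self.kind == "sparse_binary":
                nnz = np.count_nonzero(b, axis=0)
                if np.any(nnz != 2):
                    raise ValueError(
                        f"sparse_binary block {j} must have exactly 2 nonzeros "
                        "per column"
                    )

    @property
    def n_sensors(self) -> int:
        return len(self.blocks)

    @property
    def signal_len(self) -> int:
        return self.blocks[0].shape[1]

    @property
    def measurements_per_sensor(self) -> list[int]:
        return [b.shape[0] for b in self.blocks]

    @property
    def M(self) -> int:
        """Common per-sensor row count (errors if blocks differ)."""
        ms = set(self.measurements_per_sensor)
        if len(ms) != 1:
            raise ValueError("blocks have differing row counts; no single M")
        return ms.pop()

    @property
    def compression_ratio(self) -> float:
        return compression_ratio(self.signal_len, self.M)

    def full_operator(self) -> np.ndarray:
        """The assembled block-diagonal operator (sum M_j) x (J N)."""
        from scipy.linalg import block_diag

        return block_diag(*self.blocks)


@dataclass
class CompressedEnsemble:
    """Per-sensor measurements y_j = Phi_j x_j plus the producing scheme."""

    measurements: list[np.ndarray]
    scheme: MeasurementScheme = field(repr=False)

    @property
    def stacked(self) -> np.ndarray:
        """Concatenation Y = [y_1; ...; y_J] in sensor order."""
        return np.concatenate(self.measurements)


def make_measurement_scheme(
    J: int, N: int, M: int, kind: str = "sparse_binary", seed: int = 0
) -> MeasurementScheme:
    """Draw J independent per-sensor measurement blocks of shape (M, N)."""
    if J < 1:
        raise ValueError(f"J must be >= 1, got {J}")
    if not 1 <= M <= N:
        raise ValueError(f"M must satisfy 1 <= M <= N, got M={M}, N={N}")
    if kind not in {"sparse_binary", "gaussian"}:
        raise ValueError(f"unknown scheme kind {kind!r}")
    if kind == "sparse_binary" and M < 2:
        raise ValueError("sparse_binary requires M >= 2 (two distinct rows/column)")
    rng = np.random.default_rng(seed)
    blocks = []
    for _ in range(J):
        if kind == "gaussian":
            blocks.append(rng.standard_normal((M, N)) / np.sqrt(M))
        else:
            b = np.zeros((M, N))
            for col in range(N):
                b[rng.choice(M, size=2, replace=False), col] = 1.0
            blocks.append(b)
    return MeasurementScheme(blocks=blocks, kind=kind, seed=seed)


def compress(X: SensorEnsemble, scheme: MeasurementScheme) -> CompressedEnsemble:
    """Apply the block-diagonal scheme: y_j = Phi_j x_j, sensor by sensor."""
    if scheme.n_sensors != X.n_sensors:
        raise ValueError(
            f"scheme has {scheme.n_sensors} blocks but ensemble has "
            f"{X.n_sensors} sensors"
        )
    if scheme.signal_len != X.signal_len:
        raise ValueError(
            f"scheme expects signals of length {scheme.signal_len}, "
            f"got {X.signal_len}"
        )
    measurements = [b @ x for b, x in zip(scheme.blocks, X.signals)]
    return CompressedEnsemble(measurements=measurements, scheme=scheme)


def compress_window(sample: GaitWindowSample, scheme: MeasurementScheme) -> np.ndarray:
    """Compress one multi-channel window into a stacked measurement vector.

    Each sensor's channel rows are compressed individually by that sensor's
    block (shared within the sensor), then concatenated channel-major within
    sensor and sensor-major overall: the result has length
    ``J * n_channels * M``.
    """
    return compress_windows(sample.data[None, :, :], scheme)[0]


def compress_windows(data: np.ndarray, scheme: MeasurementScheme) -> np.ndarray:
    """Vectorized :func:`compress_window` over an (n, rows, h) stack."""
    data = np.asarray(data, dtype=float)
    n, rows, h = data.shape
    J = scheme.n_sensors
    if rows % J != 0:
        raise ValueError(f"{rows} channel rows not divisible by {J} sensors")
    if h != scheme.signal_len:
        raise ValueError(
            f"scheme expects window length {scheme.signal_len}, got {h}"
        )
    c = rows // J
    out_blocks = []
    for j, block in enumerate(scheme.blocks):
        seg = data[:, j * c : (j + 1) * c, :]  # (n, c, h)
        y = np.einsum("mh,nch->ncm", block, seg)  # (n, c, M_j)
        out_blocks.append(y.reshape(n, -1))
    return np.concatenate(out_blocks, axis=1)


def compression_ratio(N: int, M: int) -> float:
    """CR = (N - M)/N x 100, the percentage of samples removed."""
    if not 1 <= M <= N:
        raise ValueError(f"M must satisfy 1 <= M <= N, got M={M}, N={N}")
    return (N - M) / N * 100.0


def measurements_for_ratio(N: int, cr: float) -> int:
    """Invert the compression ratio: per-sensor row count M for a given CR%."""
    if not 0 <= cr < 100:
        raise ValueError(f"cr must lie in [0, 100), got {cr}")
    M = int(round(N * (1.0 - cr / 100.0)))
    return max(1, min(N, M))


def joint_reconstruct(
    Y: CompressedEnsemble,
    basis: np.ndarray,
    k: int,
    method: str = "somp",
):
    """Jointly reconstruct a JSM-2 ensemble from its compressed measurements.

    Runs the chosen greedy joint solver on the per-sensor systems
    ``y_j = (Phi_j Psi) theta_j`` under a shared support of size ``k`` and
    returns the estimated :class:`~gaitjsrc.synthetic.SparseModel` together
    with the reconstruction ``x_hat_j = Psi theta_hat_j``.
    """
    from .synthetic import SparseModel  # deferred: avoids an import cycle

    if method not in {"somp", "osga"}:
        raise ValueError(f"unknown reconstruction method {method!r}")
    if k < 0:
        raise ValueError("k must be nonnegative")
    scheme = Y.scheme
    if k > min(scheme.measurements_per_sensor):
        raise ValueError(
            f"k={k} exceeds the smallest per-sensor measurement count "
            f"{min(scheme.measurements_per_sensor)}"
        )
    psi = np.asarray(basis, dtype=float)
    dictionaries = [b @ psi for b in scheme.blocks]
    solve = solvers.somp if method == "somp" else solvers.osga
    result = solve(Y.measurements, dictionaries, k)
    coefficients = result.coefficients.T  # (J, N)
    model = SparseModel(
        basis=psi,
        coefficients=coefficients,
        support=result.support,
        sparsity=result.support.size,
    )
    return model, SensorEnsemble(signals=coefficients @ psi.T)
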