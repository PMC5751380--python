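"""Synthetic generators with known ground truth.

Two families of inputs are generated here so that every downstream stage is
testable without external recordings:

* **Jointly sparse sensor ensembles** under the shared-support joint
  sparsity model (JSM-2): every sensor's signal is sparse in one common
  orthonormal basis, all sensors share a single support set, and the
  nonzero coefficient values differ per sensor.
* **Labeled multi-subject gait-like datasets** that emulate the shape of a
  wearable-sensor activity database: per class a band-limited quasi-periodic
  template per channel, per subject a small amplitude/timing perturbation,
  per window additive Gaussian noise.

Both generators are deterministic given their seed and return the ground
truth (support sets, class templates) needed by oracle tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.fft

from .dcs import SensorEnsemble
from .preprocessing import CHANNELS_PER_SENSOR, GaitWindowSample

__all__ = [
    "SparseModel",
    "LabeledDataset",
    "make_dictionary_basis",
    "simulate_jsm2_ensemble",
    "simulate_gait_dataset",
]

#: Orthonormality tolerance for sparsifying bases.
ORTHONORMALITY_TOL = 1e-10


def make_dictionary_basis(N: int, kind: str = "identity") -> np.ndarray:
    """Return an N x N orthonormal sparsifying basis.

    ``identity`` gives canonical (time-domain) sparsity; ``dct`` gives an
    orthonormal type-II discrete cosine basis for frequency-domain sparsity.
    """
    if N < 1:
        raise ValueError(f"N must be >= 1, got {N}")
    if kind == "identity":
        return np.eye(N)
    if kind == "dct":
        return scipy.fft.dct(np.eye(N), axis=0, norm="ortho")
    raise ValueError(f"unknown basis kind {kind!r}; expected 'identity' or 'dct'")


@dataclass
class SparseModel:
    """Ground truth of a jointly sparse ensemble.

    Attributes
    ----------
    basis
        The common orthonormal sparsifying basis Psi (N x N).
    coefficients
        Per-sensor coefficient vectors, shape (J, N); row j is theta_j.
    support
        Sorted shared support set Omega, indices into 0..N-1.
    sparsity
        k = ``len(support)``.
    """

    basis: np.ndarray
    coefficients: np.ndarray
    support: np.ndarray
    sparsity: int

    def __post_init__(self) -> None:
        self.basis = np.asarray(self.basis, dtype=float)
        self.coefficients = np.atleast_2d(np.asarray(self.coefficients, dtype=float))
        self.support = np.asarray(self.support, dtype=int)
        N = self.basis.shape[0]
        if self.basis.shape != (N, N):
            raise ValueError("basis must be square")
        gram_dev = np.max(np.abs(self.basis.T @ self.basis - np.eye(N)))
        if gram_dev > ORTHONORMALITY_TOL:
            raise ValueError(f"basis is not orthonormal (max deviation {gram_dev:.2e})")
        if self.sparsity != self.support.size or self.sparsity > N:
            raise ValueError("sparsity must equal |support| and be <= N")
        off_support = np.setdiff1d(np.arange(N), self.support)
        if off_support.size and np.any(self.coefficients[:, off_support] != 0.0):
            raise ValueError("nonzero coefficients found outside the shared support")

    @property
    def n_sensors(self) -> int:
        return self.coefficients.shape[0]


def simulate_jsm2_ensemble(
    J: int,
    N: int,
    k: int,
    noise_sd: float = 0.0,
    seed: int = 0,
    basis: str | np.ndarray = "identity",
) -> tuple[SensorEnsemble, SparseModel]:
    """Draw a JSM-2 ensemble: shared support, per-sensor coefficients.

    Each sensor signal is ``x_j = Psi theta_j + noise`` where all theta_j
    share one uniformly drawn support of size ``k`` and their nonzero values
    are independent standard normals.  Noise is i.i.d. Gaussian with
    standard deviation ``noise_sd``.

    Returns the noisy ensemble together with the noiseless ground-truth
    :class:`SparseModel`.
    """
    if J < 1:
        raise ValueError(f"J must be >= 1, got {J}")
    if not 0 <= k <= N:
        raise ValueError(f"k must satisfy 0 <= k <= N, got k={k}, N={N}")
    if noise_sd < 0:
        raise ValueError(f"noise_sd must be nonnegative, got {noise_sd}")
    psi = basis if isinstance(basis, np.ndarray) else make_dictionary_basis(N, basis)
    rng = np.random.default_rng(seed)
    support = np.sort(rng.choice(N, size=k, replace=False))
    coefficients = np.zeros((J, N))
    if k:
        coefficients[:, support] = rng.standard_normal((J, k))
    signals = coefficients @ psi.T
    if noise_sd > 0:
        signals = signals + rng.normal(0.0, noise_sd, size=signals.shape)
    model = SparseModel(
        basis=psi, coefficients=coefficients, support=support, sparsity=k
    )
    return SensorEnsemble(signals=signals), model


@dataclass
class LabeledDataset:
    """A labeled multi-subject, multi-class collection of sensor windows.

    Labels are dense class indices 1..L; every sample carries a subject
    identifier so subject-wise cross-validation splits never leak.
    ``class_templates`` (when produced by the generator) holds the noiseless
    per-class channel templates, shape (L, rows, window_len), for oracle
    tests.
    """

    samples: list[GaitWindowSample]
    labels: np.ndarray
    subjects: np.ndarray
    n_classes: int
    class_templates: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.subjects = np.asarray(self.subjects)
        n = len(self.samples)
        if self.labels.shape != (n,) or self.subjects.shape != (n,):
            raise ValueError("labels and subjects must have one entry per sample")
        if n and (self.labels.min() < 1 or self.labels.max() > self.n_classes):
            raise ValueError(f"labels must lie in 1..{self.n_classes}")
        if n:
            first = self.samples[0]
            for s in self.samples:
                if (
                    s.n_sensors != first.n_sensors
                    or s.n_channels != first.n_channels
                    or s.window_len != first.window_len
                ):
                    raise ValueError("all samples must share sensor/window geometry")

    @property
    def n(self) -> int:
        return len(self.samples)

    @property
    def n_sensors(self) -> int:
        return self.samples[0].n_sensors

    @property
    def window_len(self) -> int:
        return self.samples[0].window_len

    @property
    def class_counts(self) -> np.ndarray:
        """Per-class sample counts n_i, i = 1..L."""
        return np.bincount(self.labels, minlength=self.n_classes + 1)[1:]

    def as_array(self) -> np.ndarray:
        """All samples stacked into one (n, rows, window_len) array."""
        return np.stack([s.data for s in self.samples])


def simulate_gait_dataset(
    n_subjects: int,
    n_classes: int,
    windows_per_class: int,
    J: int = 5,
    window_len: int = 200,
    class_sep: float = 1.0,
    noise_sd: float = 0.1,
    seed: int = 0,
    sampling_rate: float = 20.0,
    n_channels: int = CHANNELS_PER_SENSOR,
) -> LabeledDataset:
    """Generate a labeled multi-subject gait-like dataset.

    Per class and channel row, a template is drawn once as a sum of 2-4
    random-phase sinusoids with frequencies below a class-specific cutoff
    (mimicking quasi-periodic gait harmonics), scaled by ``class_sep``.
    Per subject, the class template is perturbed by a small amplitude jitter
    (10% s.d.) and a small timing shift (50 ms s.d.).  Per window, i.i.d.
    Gaussian noise of standard deviation ``noise_sd`` is added.

    The total sample count is ``n_subjects * n_classes * windows_per_class``.
    """
    for name, val in (
        ("n_subjects", n_subjects),
        ("n_classes", n_classes),
        ("windows_per_class", windows_per_class),
        ("J", J),
        ("window_len", window_len),
    ):
        if val < 1:
            raise ValueError(f"{name} must be >= 1, got {val}")
    if class_sep <= 0:
        raise ValueError(f"class_sep must be positive, got {class_sep}")
    if noise_sd < 0:
        raise ValueError(f"noise_sd must be nonnegative, got {noise_sd}")

    rng = np.random.default_rng(seed)
    rows = J * n_channels
    t = np.arange(window_len) / sampling_rate

    # Per class: sinusoid parameters for every channel row, drawn before any
    # subject data so template identity is independent of the cohort size.
    class_params: list[list[tuple[np.ndarray, np.ndarray, np.ndarray]]] = []
    for _ in range(n_classes):
        cutoff = rng.uniform(1.5, 5.0)  # Hz; class-specific harmonic band
        row_params = []
        for _ in range(rows):
            n_comp = int(rng.integers(2, 5))
            freqs = rng.uniform(0.3, cutoff, size=n_comp)
            amps = rng.uniform(0.5, 1.0, size=n_comp)
            phases = rng.uniform(0.0, 2.0 * np.pi, size=n_comp)
            row_params.append((freqs, amps, phases))
        class_params.append(row_params)

    def evaluate(ci: int, amp_scale: np.ndarray, shift: float) -> np.ndarray:
        out = np.empty((rows, window_len))
        for r, (freqs, amps, phases) in enumerate(class_params[ci]):
            waves = np.sin(
                2.0 * np.pi * freqs[:, None] * (t[None, :] + shift) + phases[:, None]
            )
            out[r] = class_sep * amp_scale[r] * (amps @ waves)
        return out

    templates = np.stack(
        [evaluate(ci, np.ones(rows), 0.0) for ci in range(n_classes)]
    )

    samples: list[GaitWindowSample] = []
    labels: list[int] = []
    subjects: list[int] = []
    for subject in range(1, n_subjects + 1):
        for ci in range(n_classes):
            amp_scale = 1.0 + 0.1 * rng.standard_normal(rows)
            shift = rng.normal(0.0, 0.05)  # seconds
            base = evaluate(ci, amp_scale, shift)
            noise = rng.normal(0.0, noise_sd, size=(windows_per_class, rows, window_len))
            for w in range(windows_per_class):
                samples.append(
                    GaitWindowSample(
                        data=base + noise[w], n_sensors=J, n_channels=n_channels
                    )
                )
                labels.append(ci + 1)
                subjects.append(subject)

    return LabeledDataset(
        samples=samples,
        labels=np.array(labels),
        subjects=np.array(subjects),
        n_classes=n_classes,
        class_templates=templates,
    )
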