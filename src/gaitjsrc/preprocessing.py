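"""Filtering, windowing and feature stacking for multi-sensor inertial recordings.

A recording from a body-worn sensor network is a matrix of channel rows over
time: each of the J sensor nodes contributes five channels (triaxial
accelerometer x, y, z plus biaxial gyroscope pitch and roll).  The pipeline
order is fixed: low-pass filter each channel, cut the record into
fixed-length overlapping windows, then stack the per-sensor channel blocks
sensor-major into a single (5J x h) sample matrix.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import signal as sps

logger = logging.getLogger(__name__)

#: Channels recorded by one sensor node (3-axis accelerometer + 2-axis gyroscope).
CHANNELS_PER_SENSOR = 5


@dataclass(frozen=True)
class WindowConfig:
    """Segmentation and denoising settings for raw recordings.

    Parameters
    ----------
    window_len
        Window length h in samples.
    overlap_fraction
        Fractional overlap between consecutive windows, in [0, 1).
    sampling_rate
        Sampling rate in Hz.
    filter_order
        Butterworth low-pass filter order.
    filter_cutoff
        Low-pass cutoff frequency in Hz.  If the cutoff is at or above the
        Nyquist frequency the filter is unrealizable and
        :func:`lowpass_filter` passes the signal through unchanged.
    """

    window_len: int = 200
    overlap_fraction: float = 0.5
    sampling_rate: float = 20.0
    filter_order: int = 5
    filter_cutoff: float = 30.0

    def __post_init__(self) -> None:
        if self.window_len < 2:
            raise ValueError(f"window_len must be >= 2, got {self.window_len}")
        if not 0.0 <= self.overlap_fraction < 1.0:
            raise ValueError(
                f"overlap_fraction must lie in [0, 1), got {self.overlap_fraction}"
            )
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.filter_order < 1:
            raise ValueError("filter_order must be a positive integer")
        if self.filter_cutoff <= 0:
            raise ValueError("filter_cutoff must be positive")

    @property
    def stride(self) -> int:
        """Window start increment: round(h * (1 - overlap)), at least 1."""
        return max(1, int(round(self.window_len * (1.0 - self.overlap_fraction))))


@dataclass
class GaitWindowSample:
    """One fixed-length window of stacked multi-sensor channel rows.

    ``data`` has shape (n_channels * n_sensors, window_len); row
    ``n_channels * (j - 1) + c`` is channel c of sensor j (sensor-major).
    """

    data: np.ndarray
    n_sensors: int
    n_channels: int = CHANNELS_PER_SENSOR

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("sample data must be a 2-D matrix")
        expected = self.n_sensors * self.n_channels
        if self.data.shape[0] != expected:
            raise ValueError(
                f"sample has {self.data.shape[0]} rows, expected "
                f"{expected} (= {self.n_sensors} sensors x {self.n_channels} channels)"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("sample data must be finite")

    @property
    def window_len(self) -> int:
        return self.data.shape[1]

    def sensor_block(self, j: int) -> np.ndarray:
        """Rows of sensor ``j`` (0-based), shape (n_channels, window_len)."""
        start = j * self.n_channels
        return self.data[start : start + self.n_channels]


def lowpass_filter(signal: np.ndarray, config: WindowConfig) -> np.ndarray:
    """Zero-phase Butterworth low-pass filtering along the last axis.

    Forward-backward (``sosfiltfilt``) application avoids phase distortion
    inside windows.  If the configured cutoff is at or above Nyquist the
    signal is returned unchanged and a warning is logged: the filter cannot
    be realized at that sampling rate.
    """
    x = np.asarray(signal, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("signal contains non-finite values")
    if x.shape[-1] < 3 * config.filter_order:
        raise ValueError(
            f"signal length {x.shape[-1]} is shorter than 3 x filter order "
            f"({3 * config.filter_order})"
        )
    nyquist = config.sampling_rate / 2.0
    if config.filter_cutoff >= nyquist:
        logger.warning(
            "low-pass cutoff %.3g Hz is at or above Nyquist %.3g Hz; "
            "returning the signal unchanged",
            config.filter_cutoff,
            nyquist,
        )
        return x.copy()
    sos = sps.butter(
        config.filter_order,
        config.filter_cutoff,
        btype="lowpass",
        fs=config.sampling_rate,
        output="sos",
    )
    return sps.sosfiltfilt(sos, x, axis=-1)


def segment_windows(signal: np.ndarray, config: WindowConfig) -> list[np.ndarray]:
    """Slice a (channels x T) record into overlapping (channels x h) windows.

    Window starts are 0, s, 2s, ... while start + h <= T, with stride
    s = round(h * (1 - overlap_fraction)).  A record shorter than one window
    yields an empty list with a logged warning.
    """
    x = np.atleast_2d(np.asarray(signal, dtype=float))
    h = config.window_len
    T = x.shape[-1]
    if T < h:
        logger.warning("record length %d is shorter than window length %d", T, h)
        return []
    s = config.stride
    starts = range(0, T - h + 1, s)
    return [x[:, start : start + h].copy() for start in starts]


def stack_features(per_sensor_windows: list[np.ndarray]) -> GaitWindowSample:
    """Stack J per-sensor channel blocks into one sensor-major sample matrix.

    Each block must have the same shape (n_channels x h); block j occupies
    rows ``n_channels * j`` .. ``n_channels * (j + 1) - 1`` of the result.
    """
    if len(per_sensor_windows) == 0:
        raise ValueError("at least one sensor block is required")
    blocks = [np.atleast_2d(np.asarray(b, dtype=float)) for b in per_sensor_windows]
    shape = blocks[0].shape
    if any(b.shape != shape for b in blocks):
        raise ValueError(
            f"ragged sensor blocks: shapes {[b.shape for b in blocks]} differ"
        )
    return GaitWindowSample(
        data=np.vstack(blocks), n_sensors=len(blocks), n_channels=shape[0]
    )


_TRIAL_RE = re.compile(r"a(\d+)t(\d+)\.csv$")


def read_ward_layout(
    path: str | Path,
    config: WindowConfig | None = None,
    windows_per_class: int = 10,
    selection: str = "first",
    seed: int = 0,
):
    """Read a WARD-style directory of per-subject trial files into a dataset.

    Expected layout::

        <root>/Subject<id>/a<class>t<trial>.csv

    Each trial file is a headerless CSV with one row per time sample and
    5J columns (channel-major within sensor, sensors in order).  Every
    channel is low-pass filtered, the record is segmented into windows, and
    ``windows_per_class`` windows are kept per subject and class — the first
    ones by default, or a seeded random subset with ``selection="random"``.

    Returns a :class:`~gaitjsrc.synthetic.LabeledDataset`.
    """
    from .synthetic import LabeledDataset  # deferred: avoids an import cycle

    if config is None:
        config = WindowConfig()
    if selection not in {"first", "random"}:
        raise ValueError(f"selection must be 'first' or 'random', got {selection!r}")
    root = Path(path)
    subject_dirs = sorted(d for d in root.glob("Subject*") if d.is_dir())
    if not subject_dirs:
        raise IOError(f"no Subject* directories found under {root}")
    rng = np.random.default_rng(seed)

    samples: list[GaitWindowSample] = []
    labels: list[int] = []
    subjects: list[str] = []
    n_sensors: int | None = None
    all_classes: set[int] = set()

    for sdir in subject_dirs:
        subject_id = sdir.name.removeprefix("Subject")
        trials: dict[int, list[Path]] = {}
        for f in sorted(sdir.glob("*.csv")):
            match = _TRIAL_RE.search(f.name)
            if match is None:
                raise IOError(f"unrecognized trial file name: {f}")
            trials.setdefault(int(match.group(1)), []).append(f)
        if not trials:
            raise IOError(f"no trial files found in {sdir}")
        for class_id in sorted(trials):
            windows: list[np.ndarray] = []
            for f in trials[class_id]:
                try:
                    raw = np.loadtxt(f, delimiter=",", ndmin=2)
                except Exception as exc:  # noqa: BLE001 - re-raise naming the file
                    raise IOError(f"failed to parse trial file {f}: {exc}") from exc
                if raw.shape[1] % CHANNELS_PER_SENSOR != 0:
                    raise IOError(
                        f"{f}: {raw.shape[1]} columns is not a multiple of "
                        f"{CHANNELS_PER_SENSOR}"
                    )
                J = raw.shape[1] // CHANNELS_PER_SENSOR
                if n_sensors is None:
                    n_sensors = J
                elif J != n_sensors:
                    raise IOError(f"{f}: sensor count {J} differs from {n_sensors}")
                channels = raw.T  # (5J, T)
                filtered = lowpass_filter(channels, config)
                windows.extend(segment_windows(filtered, config))
            if selection == "random" and len(windows) > windows_per_class:
                keep = sorted(
                    rng.choice(len(windows), size=windows_per_class, replace=False)
                )
                windows = [windows[i] for i in keep]
            else:
                windows = windows[:windows_per_class]
            for w in windows:
                samples.append(
                    GaitWindowSample(data=w, n_sensors=n_sensors)
                )
                labels.append(class_id)
                subjects.append(subject_id)
            all_classes.add(class_id)

    # Re-map class ids to a dense 1..L range preserving order.
    class_map = {c: i + 1 for i, c in enumerate(sorted(all_classes))}
    dense = np.array([class_map[c] for c in labels], dtype=int)
    return LabeledDataset(
        samples=samples,
        labels=dense,
        subjects=np.asarray(subjects),
        n_classes=len(class_map),
    )
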