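"""Serialization glue: datasets, schemes, trained models, run configuration.

Two dataset formats round-trip losslessly:

* a single archived-array container (NumPy ``.npz``), and
* a directory of per-sample CSV files plus a ``manifest.csv`` naming each
  sample's file, label and subject.

Schemes and trained models serialize to ``.npz`` archives that embed the
seed and a hash of the configuration that produced them, so experiments
replay exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .dcs import MeasurementScheme
from .evaluation import ModelSettings
from .jsrc import PipelineModel, TrainingDictionary
from .preprocessing import GaitWindowSample, WindowConfig
from .synthetic import LabeledDataset

__all__ = [
    "save_dataset_npz",
    "load_dataset_npz",
    "save_dataset_csv",
    "load_dataset_csv",
    "save_scheme",
    "load_scheme",
    "save_model",
    "load_model",
    "RunConfig",
    "config_hash",
]


def save_dataset_npz(dataset: LabeledDataset, path: str | Path) -> None:
    """Write a dataset to one archived-array container."""
    extra = {}
    if dataset.class_templates is not None:
        extra["class_templates"] = dataset.class_templates
    np.savez_compressed(
        path,
        data=dataset.as_array(),
        labels=dataset.labels,
        subjects=dataset.subjects,
        n_classes=np.array(dataset.n_classes),
        n_sensors=np.array(dataset.n_sensors),
        n_channels=np.array(dataset.samples[0].n_channels),
        **extra,
    )


def load_dataset_npz(path: str | Path) -> LabeledDataset:
    with np.load(path, allow_pickle=False) as archive:
        data = archive["data"]
        n_sensors = int(archive["n_sensors"])
        n_channels = int(archive["n_channels"])
        samples = [
            GaitWindowSample(data=w, n_sensors=n_sensors, n_channels=n_channels)
            for w in data
        ]
        templates = (
            archive["class_templates"] if "class_templates" in archive else None
        )
        return LabeledDataset(
            samples=samples,
            labels=archive["labels"],
            subjects=archive["subjects"],
            n_classes=int(archive["n_classes"]),
            class_templates=templates,
        )


def save_dataset_csv(dataset: LabeledDataset, directory: str | Path) -> None:
    """Write per-sample CSV files plus a manifest into ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, sample in enumerate(dataset.samples):
        name = f"sample_{i:05d}.csv"
        np.savetxt(directory / name, sample.data, delimiter=",")
        rows.append(
            f"{name},{dataset.labels[i]},{dataset.subjects[i]},"
            f"{sample.n_sensors},{sample.n_channels}"
        )
    manifest = directory / "manifest.csv"
    header = "file,label,subject,n_sensors,n_channels"
    manifest.write_text("\n".join([header, *rows]) + "\n")


def load_dataset_csv(directory: str | Path) -> LabeledDataset:
    directory = Path(directory)
    manifest = directory / "manifest.csv"
    if not manifest.exists():
        raise IOError(f"missing manifest: {manifest}")
    lines = manifest.read_text().strip().splitlines()[1:]
    samples, labels, subjects = [], [], []
    n_classes = 0
    for line in lines:
        name, label, subject, n_sensors, n_channels = line.split(",")
        data = np.loadtxt(directory / name, delimiter=",", ndmin=2)
        samples.append(
            GaitWindowSample(
                data=data, n_sensors=int(n_sensors), n_channels=int(n_channels)
            )
        )
        labels.append(int(label))
        subjects.append(subject)
        n_classes = max(n_classes, int(label))
    return LabeledDataset(
        samples=samples,
        labels=np.array(labels),
        subjects=np.array(subjects),
        n_classes=n_classes,
    )


def save_scheme(scheme: MeasurementScheme, path: str | Path) -> None:
    blocks = {f"block_{j}": b for j, b in enumerate(scheme.blocks)}
    np.savez_compressed(
        path,
        kind=np.array(scheme.kind),
        seed=np.array(scheme.seed),
        n_blocks=np.array(len(scheme.blocks)),
        **blocks,
    )


def load_scheme(path: str | Path) -> MeasurementScheme:
    with np.load(path, allow_pickle=False) as archive:
        n = int(archive["n_blocks"])
        return MeasurementScheme(
            blocks=[archive[f"block_{j}"] for j in range(n)],
            kind=str(archive["kind"]),
            seed=int(archive["seed"]),
        )


def save_model(model: PipelineModel, path: str | Path, config: dict | None = None) -> None:
    """Archive a trained pipeline (scheme + dictionary + hyperparameters)."""
    blocks = {f"block_{j}": b for j, b in enumerate(model.scheme.blocks)}
    np.savez_compressed(
        path,
        scheme_kind=np.array(model.scheme.kind),
        scheme_seed=np.array(model.scheme.seed),
        n_blocks=np.array(len(model.scheme.blocks)),
        atoms=model.dictionary.atoms,
        labels=model.dictionary.labels,
        n_sensors=np.array(model.dictionary.n_sensors),
        lam=np.array(model.lam),
        m=np.array(model.m),
        k=np.array(model.k),
        solver=np.array(model.solver),
        neighbor_method=np.array(model.neighbor_method),
        config_hash=np.array(config_hash(config or {})),
        **blocks,
    )


def load_model(path: str | Path) -> PipelineModel:
    with np.load(path, allow_pickle=False) as archive:
        n = int(archive["n_blocks"])
        scheme = MeasurementScheme(
            blocks=[archive[f"block_{j}"] for j in range(n)],
            kind=str(archive["scheme_kind"]),
            seed=int(archive["scheme_seed"]),
        )
        dictionary = TrainingDictionary(
            atoms=archive["atoms"],
            labels=archive["labels"],
            n_sensors=int(archive["n_sensors"]),
        )
        return PipelineModel(
            scheme=scheme,
            dictionary=dictionary,
            lam=float(archive["lam"]),
            m=int(archive["m"]),
            k=int(archive["k"]),
            solver=str(archive["solver"]),
            neighbor_method=str(archive["neighbor_method"]),
        )


@dataclass
class RunConfig:
    """Complete run configuration; round-trips through YAML losslessly."""

    window: WindowConfig = field(default_factory=WindowConfig)
    model: ModelSettings = field(default_factory=ModelSettings)
    cv_outer_folds: int = 10
    cv_inner_folds: int = 9
    cv_seed: int = 0
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "window": dataclasses.asdict(self.window),
            "model": dataclasses.asdict(self.model),
            "cv_outer_folds": self.cv_outer_folds,
            "cv_inner_folds": self.cv_inner_folds,
            "cv_seed": self.cv_seed,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        kwargs = dict(d)
        if "window" in kwargs:
            kwargs["window"] = WindowConfig(**kwargs["window"])
        if "model" in kwargs:
            kwargs["model"] = ModelSettings(**kwargs["model"])
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration mapping, for artifact tagging."""
    payload = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]
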