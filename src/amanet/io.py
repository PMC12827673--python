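"""Containers and configuration files.

Epoched EEG travels as NPZ or HDF5 with arrays ``X`` (trials, C, T), ``y``
(trials,) and a scalar ``sfreq``; run configurations are YAML.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import yaml

from .augment import AugConfig, SpatialFilterBank
from .exceptions import SchemaError, SpecError
from .model import ModelConfig
from .synthetic import RawTrialSet
from .train import CVReport, TrainConfig

__all__ = [
    "RunConfig",
    "load_trialset",
    "save_trialset",
    "save_filterbank",
    "load_filterbank",
    "save_checkpoint",
    "load_checkpoint",
    "save_report",
    "load_report",
]


def _infer_layout(path: Path, layout: str | None) -> str:
    if layout:
        return layout
    suffix = path.suffix.lower()
    if suffix in (".h5", ".hdf5"):
        return "hdf5"
    return "npz"


def save_trialset(trials: RawTrialSet, path: str | Path, layout: str | None = None) -> None:
    path = Path(path)
    layout = _infer_layout(path, layout)
    if layout == "hdf5":
        with h5py.File(path, "w") as f:
            f.create_dataset("X", data=trials.data)
            f.create_dataset("y", data=trials.labels)
            f.attrs["sfreq"] = trials.sfreq
    else:
        np.savez(path, X=trials.data, y=trials.labels, sfreq=trials.sfreq)


def load_trialset(path: str | Path, layout: str | None = None) -> tuple[RawTrialSet, dict[int, int]]:
    """Load and validate a trial container.

    Labels are remapped to contiguous 0..K-1; the mapping
    ``{original: remapped}`` is returned alongside the data.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    layout = _infer_layout(path, layout)
    if layout == "hdf5":
        with h5py.File(path, "r") as f:
            arrays = {k: np.asarray(f[k]) for k in f.keys()}
            if "sfreq" in f.attrs:
                arrays["sfreq"] = np.asarray(f.attrs["sfreq"])
    else:
        with np.load(path) as npz:
            arrays = {k: npz[k] for k in npz.files}
    for key in ("X", "y", "sfreq"):
        if key not in arrays:
            raise SchemaError(f"container {path} is missing required array {key!r}")
    x = np.asarray(arrays["X"], dtype=np.float64)
    y = np.asarray(arrays["y"]).ravel().astype(np.int64)
    if x.ndim != 3:
        raise SpecError(f"X must be (trials, C, T), got shape {x.shape}")
    if y.shape[0] != x.shape[0]:
        raise SpecError(
            f"y has {y.shape[0]} labels for {x.shape[0]} trials"
        )
    unique = np.unique(y)
    mapping = {int(orig): new for new, orig in enumerate(unique)}
    remapped = np.searchsorted(unique, y)
    return RawTrialSet(x, remapped, float(np.asarray(arrays["sfreq"]).item())), mapping


def save_filterbank(bank: SpatialFilterBank, path: str | Path) -> None:
    np.savez(
        Path(path),
        W=bank.filters,
        eigenvalues=bank.eigenvalues,
        class_of_filter=bank.class_of_filter,
        n_source_channels=bank.n_source_channels,
    )


def load_filterbank(path: str | Path) -> SpatialFilterBank:
    with np.load(Path(path)) as npz:
        return SpatialFilterBank(
            filters=npz["W"],
            eigenvalues=npz["eigenvalues"],
            class_of_filter=npz["class_of_filter"],
            n_source_channels=int(npz["n_source_channels"]),
        )


def save_checkpoint(model, path: str | Path) -> None:
    """Serialize model weights (NPZ) with a JSON config sidecar."""
    path = Path(path)
    np.savez(path, **model.state_dict())
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps(dataclasses.asdict(model.cfg), indent=2) + "\n")


def load_checkpoint(path: str | Path):
    """Rebuild a model from a checkpoint written by :func:`save_checkpoint`."""
    from .model import build_model

    path = Path(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    raw = json.loads(sidecar.read_text())
    raw["ms_kernels"] = tuple(raw["ms_kernels"])
    model = build_model(ModelConfig(**raw))
    with np.load(path) as npz:
        model.load_state_dict({k: npz[k] for k in npz.files})
    return model


def save_report(report, path: str | Path) -> None:
    """Write a CVReport as JSON or a sweep table as CSV (by extension)."""
    path = Path(path)
    if isinstance(report, CVReport):
        payload = report.to_dict()
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    else:  # pandas DataFrame sweep table
        report.to_csv(path, index=False)


def load_report(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


@dataclass
class RunConfig:
    """Everything one command needs, round-trippable through YAML."""

    data_in: str | None = None
    data_out: str | None = None
    aug: AugConfig = field(default_factory=AugConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    ablation: str | None = None
    sweep_grid: dict | None = None

    def to_dict(self) -> dict:
        def clean(obj):
            if dataclasses.is_dataclass(obj):
                return {k: clean(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, tuple):
                return [clean(v) for v in obj]
            if isinstance(obj, dict):
                return {k: clean(v) for k, v in obj.items()}
            if isinstance(obj, list):
                return [clean(v) for v in obj]
            return obj

        return {
            "data_in": self.data_in,
            "data_out": self.data_out,
            "aug": clean(self.aug),
            "model": clean(self.model),
            "train": clean(self.train),
            "ablation": self.ablation,
            "sweep_grid": clean(self.sweep_grid) if self.sweep_grid else None,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        aug = AugConfig(**d.get("aug", {}))
        model_kwargs = dict(d.get("model", {}))
        if "ms_kernels" in model_kwargs:
            model_kwargs["ms_kernels"] = tuple(model_kwargs["ms_kernels"])
        model = ModelConfig(**model_kwargs)
        train = TrainConfig(**d.get("train", {}))
        return cls(
            data_in=d.get("data_in"),
            data_out=d.get("data_out"),
            aug=aug,
            model=model,
            train=train,
            ablation=d.get("ablation"),
            sweep_grid=d.get("sweep_grid"),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})
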