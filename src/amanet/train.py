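"""Training protocol, metrics, cross-validation, ablations and sweeps."""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .augment import AugConfig, EpochSet, augment, n_windows
from .exceptions import (
    ConfigurationError,
    InsufficientDataError,
    NumericalError,
    SpecError,
)
from .model import AMANet, ModelConfig, build_model
from .nn import Adam
from .synthetic import RawTrialSet

__all__ = [
    "TrainConfig",
    "FoldResult",
    "CVReport",
    "AblationSpec",
    "cohen_kappa",
    "confusion_matrix",
    "softmax_cross_entropy",
    "train_fold",
    "cross_validate",
    "ablation_variant",
    "ABLATION_NAMES",
    "run_sweep",
    "register_attention",
    "paired_permutation_test",
]


@dataclass(frozen=True)
class TrainConfig:
    lr: float = 0.001
    batch_size: int = 32
    epochs: int = 300
    optimizer: str = "adam"
    seed: int = 1234
    folds: int = 10
    standardize: bool = True

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ConfigurationError(f"epochs must be >= 1, got {self.epochs}")
        if self.folds < 2:
            raise ConfigurationError(f"folds must be >= 2, got {self.folds}")
        if self.lr <= 0:
            raise ConfigurationError(f"lr must be positive, got {self.lr}")
        if self.optimizer != "adam":
            raise ConfigurationError(f"unsupported optimizer {self.optimizer!r}")


@dataclass
class FoldResult:
    fold_id: int
    window_accuracy: float
    trial_accuracy: float
    kappa: float
    confusion: np.ndarray
    loss_curve: list[float]
    n_train_windows: int = 0
    n_val_windows: int = 0

    def to_dict(self) -> dict:
        return {
            "fold_id": self.fold_id,
            "window_accuracy": self.window_accuracy,
            "trial_accuracy": self.trial_accuracy,
            "kappa": self.kappa,
            "confusion": np.asarray(self.confusion, dtype=int).tolist(),
            "loss_curve": [float(v) for v in self.loss_curve],
            "n_train_windows": self.n_train_windows,
            "n_val_windows": self.n_val_windows,
        }


@dataclass
class CVReport:
    folds: list[FoldResult]
    mean_window_accuracy: float
    sd_window_accuracy: float
    mean_trial_accuracy: float
    sd_trial_accuracy: float
    mean_kappa: float
    sd_kappa: float
    split_level: str = "trial"

    @classmethod
    def from_folds(cls, folds: list[FoldResult]) -> "CVReport":
        wacc = np.array([f.window_accuracy for f in folds])
        tacc = np.array([f.trial_accuracy for f in folds])
        kap = np.array([f.kappa for f in folds])
        return cls(
            folds=folds,
            mean_window_accuracy=float(wacc.mean()),
            sd_window_accuracy=float(wacc.std(ddof=1)) if len(folds) > 1 else 0.0,
            mean_trial_accuracy=float(tacc.mean()),
            sd_trial_accuracy=float(tacc.std(ddof=1)) if len(folds) > 1 else 0.0,
            mean_kappa=float(kap.mean()),
            sd_kappa=float(kap.std(ddof=1)) if len(folds) > 1 else 0.0,
        )

    def to_dict(self) -> dict:
        return {
            "schema_version": 1,
            "split_level": self.split_level,
            "mean_window_accuracy": self.mean_window_accuracy,
            "sd_window_accuracy": self.sd_window_accuracy,
            "mean_trial_accuracy": self.mean_trial_accuracy,
            "sd_trial_accuracy": self.sd_trial_accuracy,
            "mean_kappa": self.mean_kappa,
            "sd_kappa": self.sd_kappa,
            "folds": [f.to_dict() for f in self.folds],
        }


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def confusion_matrix(true_labels, predicted_labels, n_classes: int) -> np.ndarray:
    """Counts with entry (i, j) = true class i predicted as class j."""
    t = np.asarray(true_labels, dtype=np.int64)
    p = np.asarray(predicted_labels, dtype=np.int64)
    if t.shape != p.shape:
        raise SpecError("label sequences must have equal length")
    if t.size and (t.min() < 0 or t.max() >= n_classes or p.min() < 0 or p.max() >= n_classes):
        raise SpecError(f"labels out of range [0, {n_classes})")
    cm = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(cm, (t, p), 1)
    return cm


def cohen_kappa(confusion: np.ndarray) -> float:
    """Chance-corrected agreement from a square confusion-count matrix."""
    cm = np.asarray(confusion, dtype=np.float64)
    if np.any(cm < 0):
        raise SpecError("confusion counts must be non-negative")
    total = cm.sum()
    if total <= 0:
        raise SpecError("confusion matrix is empty")
    p_o = np.trace(cm) / total
    p_e = float(np.sum(cm.sum(axis=1) * cm.sum(axis=0))) / total**2
    if np.isclose(1.0 - p_e, 0.0):
        return 0.0
    return float((p_o - p_e) / (1.0 - p_e))


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy from raw logits (stable log-softmax) and its gradient."""
    z = logits - logits.max(axis=1, keepdims=True)
    logsumexp = np.log(np.exp(z).sum(axis=1, keepdims=True))
    log_probs = z - logsumexp
    n = logits.shape[0]
    loss = -float(log_probs[np.arange(n), labels].mean())
    grad = np.exp(log_probs)
    grad[np.arange(n), labels] -= 1.0
    return loss, grad / n


def paired_permutation_test(
    a: np.ndarray, b: np.ndarray, n_permutations: int = 10000, seed: int = 0
) -> float:
    """Two-sided paired sign-flip permutation p-value for mean(a - b) != 0."""
    d = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    rng = np.random.default_rng(seed)
    observed = abs(d.mean())
    signs = rng.choice([-1.0, 1.0], size=(n_permutations, d.size))
    stats = np.abs((signs * d).mean(axis=1))
    return float((np.sum(stats >= observed - 1e-15) + 1) / (n_permutations + 1))


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _majority_vote(pred: np.ndarray, source: np.ndarray, truth: np.ndarray, n_classes: int):
    """Trial-level predictions by majority vote (ties -> lowest label)."""
    trial_pred, trial_true = [], []
    for tid in np.unique(source):
        mask = source == tid
        votes = np.bincount(pred[mask], minlength=n_classes)
        trial_pred.append(int(np.argmax(votes)))
        trial_true.append(int(truth[mask][0]))
    return np.array(trial_true), np.array(trial_pred)


def _predict(model: AMANet, data: np.ndarray, batch_size: int) -> np.ndarray:
    model.eval()
    out = []
    for i in range(0, data.shape[0], batch_size):
        out.append(model(data[i : i + batch_size]))
    return np.concatenate(out, axis=0)


def train_fold(
    train_epochs: EpochSet,
    val_epochs: EpochSet,
    mcfg: ModelConfig,
    tcfg: TrainConfig,
    fold_id: int = 0,
) -> FoldResult:
    """Train one model on window-level samples and evaluate at the final epoch."""
    if train_epochs.n_windows == 0 or val_epochs.n_windows == 0:
        raise InsufficientDataError("empty training or validation split")
    x_train = train_epochs.data
    x_val = val_epochs.data
    if tcfg.standardize:
        mean = x_train.mean(axis=(0, 2), keepdims=True)
        sd = x_train.std(axis=(0, 2), keepdims=True)
        sd[sd == 0] = 1.0
        x_train = (x_train - mean) / sd
        x_val = (x_val - mean) / sd
    y_train = train_epochs.labels
    n_classes = mcfg.n_classes

    model = build_model(mcfg)
    optimizer = Adam(model.parameters(), lr=tcfg.lr)
    shuffle_rng = np.random.default_rng((tcfg.seed, fold_id, 0x5F))

    loss_curve: list[float] = []
    n = x_train.shape[0]
    for _epoch in range(tcfg.epochs):
        model.train()
        order = shuffle_rng.permutation(n)
        epoch_loss, n_batches = 0.0, 0
        for i in range(0, n, tcfg.batch_size):
            idx = order[i : i + tcfg.batch_size]
            logits = model(x_train[idx])
            loss, grad = softmax_cross_entropy(logits, y_train[idx])
            if not np.isfinite(loss):
                raise NumericalError(
                    f"loss became non-finite at epoch {_epoch}; reduce the "
                    "learning rate or check the input scaling"
                )
            optimizer.zero_grad()
            model.backward(grad)
            optimizer.step()
            epoch_loss += loss
            n_batches += 1
        loss_curve.append(epoch_loss / n_batches)

    logits = _predict(model, x_val, tcfg.batch_size)
    pred = logits.argmax(axis=1)
    cm = confusion_matrix(val_epochs.labels, pred, n_classes)
    window_acc = float(np.trace(cm) / cm.sum())
    t_true, t_pred = _majority_vote(pred, val_epochs.source_trial, val_epochs.labels, n_classes)
    trial_acc = float(np.mean(t_true == t_pred))
    return FoldResult(
        fold_id=fold_id,
        window_accuracy=window_acc,
        trial_accuracy=trial_acc,
        kappa=cohen_kappa(cm),
        confusion=cm,
        loss_curve=loss_curve,
        n_train_windows=train_epochs.n_windows,
        n_val_windows=val_epochs.n_windows,
    )


def _adapt_model_config(mcfg: ModelConfig, acfg: AugConfig, n_channels: int, n_classes: int) -> ModelConfig:
    """Tie the model input geometry to the augmentation output."""
    in_channels = acfg.n_components if acfg.use_csp else n_channels
    return replace(
        mcfg,
        in_channels=in_channels,
        in_samples=acfg.window_size,
        n_classes=n_classes,
    )


def cross_validate(
    trials: RawTrialSet,
    acfg: AugConfig,
    mcfg: ModelConfig,
    tcfg: TrainConfig,
) -> CVReport:
    """Stratified trial-level k-fold: CSP fitted per fold on training trials only."""
    n_classes = trials.n_classes
    counts = np.bincount(trials.labels, minlength=n_classes)
    limiting = int(np.argmin(counts))
    if counts[limiting] < tcfg.folds:
        raise InsufficientDataError(
            f"class {limiting} has {counts[limiting]} trials, fewer than "
            f"{tcfg.folds} folds"
        )
    skf = StratifiedKFold(n_splits=tcfg.folds, shuffle=True, random_state=tcfg.seed)
    folds: list[FoldResult] = []
    for fold_id, (tr_idx, va_idx) in enumerate(skf.split(trials.data, trials.labels)):
        train_set = RawTrialSet(trials.data[tr_idx], trials.labels[tr_idx], trials.sfreq)
        val_set = RawTrialSet(trials.data[va_idx], trials.labels[va_idx], trials.sfreq)
        tr_epochs, va_epochs, _bank = augment(train_set, val_set, acfg)
        # leakage audit: windows on either side come from disjoint trials
        tr_trials = set(tr_idx[tr_epochs.source_trial])
        va_trials = set(va_idx[va_epochs.source_trial])
        if tr_trials & va_trials:  # pragma: no cover - guarded by construction
            raise NumericalError("leakage: CSP-fit trials intersect validation trials")
        fold_mcfg = _adapt_model_config(mcfg, acfg, trials.n_channels, n_classes)
        folds.append(train_fold(tr_epochs, va_epochs, fold_mcfg, tcfg, fold_id=fold_id))
    return CVReport.from_folds(folds)


# ---------------------------------------------------------------------------
# ablations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AblationSpec:
    name: str
    use_augment_scaling: bool = True
    use_windows: bool = True
    use_csp: bool = True
    use_multiscale: bool = True
    use_eca: bool = True
    use_st_block: bool = True
    use_dsf_block: bool = True


#: Named model variants plus independent block toggles.
ABLATION_NAMES = (
    "AMANet",
    "AMNet",
    "CMNet",
    "WMANet",
    "WMNet",
    "no_multiscale",
    "no_attention",
    "no_augmentation",
    "no_st_block",
    "no_dsf_block",
)

_VARIANTS: dict[str, dict[str, bool]] = {
    "AMANet": {},
    "AMNet": {"use_eca": False},
    "CMNet": {"use_windows": False, "use_augment_scaling": False, "use_eca": False},
    "WMANet": {"use_csp": False},
    "WMNet": {"use_csp": False, "use_eca": False},
    "no_multiscale": {"use_multiscale": False},
    "no_attention": {"use_eca": False},
    "no_augmentation": {"use_windows": False, "use_augment_scaling": False},
    "no_st_block": {"use_st_block": False},
    "no_dsf_block": {"use_dsf_block": False},
}


def ablation_variant(
    name: str,
    mcfg: ModelConfig | None = None,
    acfg: AugConfig | None = None,
) -> tuple[AblationSpec, ModelConfig, AugConfig]:
    """Resolve a named variant to its flag set and derived configurations."""
    if name not in _VARIANTS:
        raise ConfigurationError(
            f"unknown ablation {name!r}; valid names: {', '.join(ABLATION_NAMES)}"
        )
    spec = AblationSpec(name=name, **_VARIANTS[name])
    mcfg = mcfg or ModelConfig()
    acfg = acfg or AugConfig()
    mcfg = replace(
        mcfg,
        use_multiscale=spec.use_multiscale,
        use_eca=spec.use_eca,
        use_st_block=spec.use_st_block,
        use_dsf_block=spec.use_dsf_block,
    )
    acfg = replace(
        acfg,
        use_csp=spec.use_csp,
        use_windows=spec.use_windows,
        use_scaling=spec.use_augment_scaling,
    )
    return spec, mcfg, acfg


# ---------------------------------------------------------------------------
# sweeps
# ---------------------------------------------------------------------------

_ATTENTION_REGISTRY: dict[str, dict] = {
    "eca": {"use_eca": True},
    "none": {"use_eca": False},
}


def register_attention(name: str, model_overrides: dict) -> None:
    """Register an attention option for the sweep harness."""
    _ATTENTION_REGISTRY[name] = dict(model_overrides)


_SWEEP_KEYS = ("ms_kernels", "attention", "window_size", "stride", "params")


def run_sweep(
    grid: dict[str, list],
    trials: RawTrialSet,
    acfg: AugConfig,
    mcfg: ModelConfig,
    tcfg: TrainConfig,
) -> pd.DataFrame:
    """Cross-validate every cell of a cartesian parameter grid.

    Grid keys: ``ms_kernels`` (triplets), ``attention`` ({'eca', 'none'} or
    registered extensions), ``window_size``, ``stride`` and ``params``
    (tuples (F1, F2, K1, K2, fc_width)).
    """
    for key in grid:
        if key not in _SWEEP_KEYS:
            raise ConfigurationError(
                f"unknown sweep key {key!r}; valid keys: {', '.join(_SWEEP_KEYS)}"
            )
    keys = list(grid)
    rows = []
    for combo in itertools.product(*(grid[k] for k in keys)):
        cell = dict(zip(keys, combo))
        cell_acfg, cell_mcfg = acfg, mcfg
        if "window_size" in cell:
            cell_acfg = replace(cell_acfg, window_size=int(cell["window_size"]))
        if "stride" in cell:
            cell_acfg = replace(cell_acfg, stride=int(cell["stride"]))
        if "ms_kernels" in cell:
            cell_mcfg = replace(cell_mcfg, ms_kernels=tuple(cell["ms_kernels"]))
        if "params" in cell:
            f1, f2, k1, k2, fc = cell["params"]
            cell_mcfg = replace(cell_mcfg, F1=f1, F2=f2, K1=k1, K2=k2, fc_width=fc, D=f2 // f1)
        if "attention" in cell:
            option = cell["attention"]
            if option not in _ATTENTION_REGISTRY:
                raise ConfigurationError(
                    f"attention {option!r} is not registered; available: "
                    f"{', '.join(sorted(_ATTENTION_REGISTRY))}"
                )
            cell_mcfg = replace(cell_mcfg, **_ATTENTION_REGISTRY[option])
        report = cross_validate(trials, cell_acfg, cell_mcfg, tcfg)
        row = {k: (str(v) if isinstance(v, (tuple, list)) else v) for k, v in cell.items()}
        row["n_windows_per_trial"] = n_windows(
            trials.n_samples, cell_acfg.window_size, cell_acfg.stride
        )
        row["mean_acc"] = report.mean_window_accuracy
        row["sd_acc"] = report.sd_window_accuracy
        row["mean_kappa"] = report.mean_kappa
        rows.append(row)
    return pd.DataFrame(rows)
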