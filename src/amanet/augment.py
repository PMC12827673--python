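"""Data-augmentation stage: sliding windows, CSP spatial filtering, scaling.

The spatial filter bank is always fitted on training windows only and then
applied to both sides; amplitude scaling perturbs training windows only by
default, so the evaluation data stays untouched.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .exceptions import (
    ConfigurationError,
    DimensionError,
    InsufficientDataError,
    NumericalError,
    SegmentationError,
    SpecError,
)
from .synthetic import RawTrialSet

__all__ = [
    "AugConfig",
    "SpatialFilterBank",
    "EpochSet",
    "sliding_window",
    "n_windows",
    "csp_fit",
    "csp_apply",
    "amplitude_scale",
    "augment",
]


@dataclass(frozen=True)
class AugConfig:
    """Windowing / CSP / scaling configuration.

    ``n_pairs`` counts CSP filter pairs, so the projected channel count is
    ``C1 = 2 * n_pairs`` (12 for the default four-class setting, 2 for
    binary with one pair).
    """

    window_size: int = 500
    stride: int = 125
    n_pairs: int = 6
    beta_low: float = 0.9
    beta_high: float = 1.1
    beta_distribution: str = "uniform"
    scale_train_only: bool = True
    scale_per_epoch: bool = False
    use_csp: bool = True
    use_windows: bool = True
    use_scaling: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.stride <= self.window_size):
            raise ConfigurationError(
                f"need 0 < stride <= window_size, got stride={self.stride}, "
                f"window_size={self.window_size}"
            )
        if not (self.beta_low <= 1.0 <= self.beta_high):
            raise ConfigurationError(
                f"scaling bounds must bracket 1: [{self.beta_low}, {self.beta_high}]"
            )
        if self.beta_low <= 0:
            raise ConfigurationError(f"beta_low must be positive, got {self.beta_low}")
        if self.n_pairs < 1:
            raise ConfigurationError(f"n_pairs must be >= 1, got {self.n_pairs}")
        if self.beta_distribution not in ("uniform", "truncated-normal"):
            raise ConfigurationError(
                f"unknown beta_distribution {self.beta_distribution!r}"
            )

    @property
    def n_components(self) -> int:
        return 2 * self.n_pairs


@dataclass
class SpatialFilterBank:
    """Fitted CSP projection: ``filters`` is the (C1, C) matrix W."""

    filters: np.ndarray
    eigenvalues: np.ndarray
    class_of_filter: np.ndarray
    n_source_channels: int
    fitted_on: str = ""  # hash of the windows used for fitting (leakage audit)

    def __post_init__(self) -> None:
        self.filters = np.asarray(self.filters, dtype=np.float64)
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=np.float64)
        self.class_of_filter = np.asarray(self.class_of_filter, dtype=np.int64)
        if self.filters.ndim != 2 or self.filters.shape[1] != self.n_source_channels:
            raise DimensionError(
                f"filters must be (C1, {self.n_source_channels}), got {self.filters.shape}"
            )
        if not np.all(np.isfinite(self.filters)):
            raise NumericalError("filter bank contains non-finite coefficients")

    @property
    def n_components(self) -> int:
        return self.filters.shape[0]


@dataclass
class EpochSet:
    """Window-level samples: ``data`` is (windows, C1, T1)."""

    data: np.ndarray
    labels: np.ndarray
    source_trial: np.ndarray
    sfreq: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.source_trial = np.asarray(self.source_trial, dtype=np.int64)
        n = self.data.shape[0]
        if self.labels.shape != (n,) or self.source_trial.shape != (n,):
            raise DimensionError(
                f"labels/source_trial must have length {n}, got "
                f"{self.labels.shape} and {self.source_trial.shape}"
            )

    @property
    def n_windows(self) -> int:
        return self.data.shape[0]


def n_windows(n_samples: int, window_size: int, stride: int) -> int:
    """Closed-form count of full windows: floor((T - w) / s) + 1."""
    if window_size > n_samples:
        raise SegmentationError(
            f"window_size {window_size} exceeds trial length {n_samples}"
        )
    return (n_samples - window_size) // stride + 1


def sliding_window(trial: np.ndarray, window_size: int, stride: int) -> list[np.ndarray]:
    """Cut one (C, T) trial into full overlapping (C, window_size) segments.

    Windows start at 0, stride, 2*stride, ...; partial windows are dropped.
    """
    trial = np.asarray(trial)
    if trial.ndim != 2:
        raise DimensionError(f"trial must be 2-d (C, T), got shape {trial.shape}")
    t = trial.shape[1]
    count = n_windows(t, window_size, stride)
    return [trial[:, i * stride : i * stride + window_size].copy() for i in range(count)]


def _mean_class_covariance(epochs: np.ndarray, ridge: float) -> np.ndarray:
    """Average of per-window trace-normalized covariances, plus ridge."""
    covs = epochs @ epochs.transpose(0, 2, 1)
    traces = np.trace(covs, axis1=1, axis2=2)
    if np.any(traces <= 0):
        raise NumericalError(
            "zero-power window encountered; cannot trace-normalize covariance"
        )
    mean = (covs / traces[:, None, None]).mean(axis=0)
    eps = ridge * np.mean(np.diag(mean))
    return mean + eps * np.eye(mean.shape[0])


def _fix_sign(w: np.ndarray) -> np.ndarray:
    """Make the largest-magnitude coefficient of each row positive."""
    w = np.asarray(w, dtype=float).copy()
    for row in w:
        j = int(np.argmax(np.abs(row)))
        if row[j] < 0:
            row *= -1.0
    return w


def _solve_pair(sigma_a: np.ndarray, sigma_b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Generalized eigenproblem sigma_a w = lam (sigma_a + sigma_b) w.

    Returns eigenvalues ascending with matching eigenvector columns.
    """
    composite = sigma_a + sigma_b
    try:
        lam, vecs = scipy.linalg.eigh(sigma_a, composite)
    except scipy.linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise NumericalError(
            "generalized eigendecomposition failed; composite covariance is "
            "singular — increase the ridge parameter"
        ) from exc
    return lam, vecs


def csp_fit(
    epochs: np.ndarray,
    labels: np.ndarray,
    n_components: int,
    ridge: float = 1e-8,
) -> SpatialFilterBank:
    """Fit a CSP filter bank on labeled windows.

    Binary: solve ``Sigma_1 w = lam (Sigma_1 + Sigma_2) w`` on the per-class
    trace-normalized mean covariances and keep the ``n_components/2``
    largest- and smallest-eigenvalue vectors (filter pairs). Multiclass:
    one-vs-rest, keeping the ``n_components / n_classes`` most
    variance-maximizing vectors of each class-vs-rest problem.
    """
    epochs = np.asarray(epochs, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.int64)
    if epochs.ndim != 3:
        raise DimensionError(f"epochs must be (windows, C, T), got shape {epochs.shape}")
    if labels.shape != (epochs.shape[0],):
        raise DimensionError("labels length must match the number of windows")
    c = epochs.shape[1]
    classes = np.unique(labels)
    n_classes = classes.size
    if n_classes < 2:
        raise InsufficientDataError("CSP needs at least 2 classes")
    if n_components > c:
        raise ConfigurationError(
            f"cannot retain {n_components} filters from {c} channels"
        )
    counts = {int(k): int(np.sum(labels == k)) for k in classes}
    for k, cnt in counts.items():
        if cnt < 2:
            raise InsufficientDataError(
                f"class {k} has only {cnt} window(s); need at least 2"
            )

    covs = {int(k): _mean_class_covariance(epochs[labels == k], ridge) for k in classes}
    fitted_on = hashlib.sha256(epochs.tobytes() + labels.tobytes()).hexdigest()

    if n_classes == 2:
        if n_components % 2 != 0:
            raise ConfigurationError(
                f"binary CSP needs an even component count, got {n_components}"
            )
        half = n_components // 2
        k0, k1 = int(classes[0]), int(classes[1])
        lam, vecs = _solve_pair(covs[k0], covs[k1])
        # ascending lam: smallest favor class k1, largest favor class k0
        top = vecs[:, ::-1][:, :half]
        top_lam = lam[::-1][:half]
        bottom = vecs[:, :half]
        bottom_lam = lam[:half]
        filters = np.concatenate([top.T, bottom.T], axis=0)
        eigenvalues = np.concatenate([top_lam, bottom_lam])
        provenance = np.concatenate([np.full(half, k0), np.full(half, k1)])
    else:
        if n_components % n_classes != 0:
            raise ConfigurationError(
                f"{n_components} components not divisible by {n_classes} classes"
            )
        per_class = n_components // n_classes
        rows, eigs, provs = [], [], []
        for k in classes:
            k = int(k)
            rest = [covs[int(j)] for j in classes if int(j) != k]
            sigma_rest = np.mean(rest, axis=0)
            lam, vecs = _solve_pair(covs[k], sigma_rest)
            rows.append(vecs[:, ::-1][:, :per_class].T)
            eigs.append(lam[::-1][:per_class])
            provs.append(np.full(per_class, k))
        filters = np.concatenate(rows, axis=0)
        eigenvalues = np.concatenate(eigs)
        provenance = np.concatenate(provs)

    return SpatialFilterBank(
        filters=_fix_sign(filters),
        eigenvalues=eigenvalues,
        class_of_filter=provenance,
        n_source_channels=c,
        fitted_on=fitted_on,
    )


def csp_apply(bank: SpatialFilterBank, window: np.ndarray) -> np.ndarray:
    """Project one (C, T) window — or a (N, C, T) stack — through the bank."""
    window = np.asarray(window, dtype=np.float64)
    if window.shape[-2] != bank.n_source_channels:
        raise DimensionError(
            f"window has {window.shape[-2]} channels, bank expects "
            f"{bank.n_source_channels}"
        )
    return bank.filters @ window


def amplitude_scale(window: np.ndarray, beta: float) -> np.ndarray:
    """Multiply every sample by the scaling factor ``beta`` (> 0)."""
    if beta <= 0:
        raise SpecError(f"scaling factor must be positive, got {beta}")
    return np.asarray(window) * beta


def sample_betas(cfg: AugConfig, size: int, rng: np.random.Generator) -> np.ndarray:
    """Draw scaling factors from the configured distribution within bounds."""
    if cfg.beta_distribution == "uniform":
        return rng.uniform(cfg.beta_low, cfg.beta_high, size=size)
    # truncated normal centered at 1, sd = half-width / 3, clipped to bounds
    sd = (cfg.beta_high - cfg.beta_low) / 6.0
    draws = rng.normal(1.0, sd, size=size)
    return np.clip(draws, cfg.beta_low, cfg.beta_high)


def _window_trialset(trials: RawTrialSet, cfg: AugConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    t = trials.n_samples
    if cfg.use_windows:
        count = n_windows(t, cfg.window_size, cfg.stride)
        starts = [i * cfg.stride for i in range(count)]
    else:
        # single centered window (augmentation-off ablation)
        starts = [(t - cfg.window_size) // 2]
        count = 1
    data = np.empty((trials.n_trials * count, trials.n_channels, cfg.window_size))
    labels = np.empty(trials.n_trials * count, dtype=np.int64)
    source = np.empty(trials.n_trials * count, dtype=np.int64)
    i = 0
    for trial_id in range(trials.n_trials):
        for s in starts:
            data[i] = trials.data[trial_id, :, s : s + cfg.window_size]
            labels[i] = trials.labels[trial_id]
            source[i] = trial_id
            i += 1
    return data, labels, source


def augment(
    train: RawTrialSet,
    test: RawTrialSet,
    cfg: AugConfig,
) -> tuple[EpochSet, EpochSet, SpatialFilterBank | None]:
    """Window both sets, fit CSP on training windows only, scale train only.

    Returns ``(train_epochs, test_epochs, bank)``; ``bank`` is ``None`` when
    ``cfg.use_csp`` is off.
    """
    if train.n_channels != test.n_channels or train.n_samples != test.n_samples:
        raise DimensionError(
            f"train {train.data.shape[1:]} and test {test.data.shape[1:]} "
            "trial shapes differ"
        )
    if train.sfreq != test.sfreq:
        raise DimensionError("train and test sampling rates differ")
    if cfg.window_size > train.n_samples:
        raise SegmentationError(
            f"window_size {cfg.window_size} exceeds trial length {train.n_samples}"
        )
    missing = set(np.unique(test.labels)) - set(np.unique(train.labels))
    if missing:
        warnings.warn(
            f"test classes {sorted(missing)} absent from training set; "
            "filters are applied regardless",
            stacklevel=2,
        )

    tr_data, tr_labels, tr_source = _window_trialset(train, cfg)
    te_data, te_labels, te_source = _window_trialset(test, cfg)

    bank: SpatialFilterBank | None = None
    if cfg.use_csp:
        bank = csp_fit(tr_data, tr_labels, n_components=cfg.n_components)
        tr_data = csp_apply(bank, tr_data)
        te_data = csp_apply(bank, te_data)

    if cfg.use_scaling:
        rng = np.random.default_rng(cfg.seed)
        betas = sample_betas(cfg, tr_data.shape[0], rng)
        tr_data = tr_data * betas[:, None, None]
        if not cfg.scale_train_only:
            te_betas = sample_betas(cfg, te_data.shape[0], rng)
            te_data = te_data * te_betas[:, None, None]

    train_epochs = EpochSet(tr_data, tr_labels, tr_source, train.sfreq)
    test_epochs = EpochSet(te_data, te_labels, te_source, test.sfreq)
    return train_epochs, test_epochs, bank
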