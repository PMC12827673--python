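"""Synthetic motor-imagery EEG generator.

Trials are built as class-specific spatial patterns carrying band-limited
oscillations (amplitude-modulated sinusoids with per-trial random phase)
plus broadband noise, so that every downstream stage — spatial filtering,
windowing, the network — can be exercised without external recordings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import SpecError

__all__ = ["SyntheticSpec", "RawTrialSet", "generate_trialset", "make_separable_spec"]

#: (center frequency Hz, bandwidth Hz, amplitude) of one rhythm.
Band = tuple[float, float, float]


@dataclass(frozen=True)
class SyntheticSpec:
    """Full description of a synthetic motor-imagery dataset.

    ``class_bands[k]`` lists the rhythms of class ``k``; ``mixing[k]`` is the
    unit-norm spatial pattern those rhythms are projected onto.
    """

    n_channels: int
    sfreq: float
    n_samples: int
    n_trials_per_class: int
    n_classes: int
    class_bands: tuple[tuple[Band, ...], ...]
    mixing: tuple[tuple[float, ...], ...]
    noise_sd: float
    seed: int = 0
    pink_noise: bool = False

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise SpecError(f"need at least 2 classes, got {self.n_classes}")
        if self.n_channels < 1 or self.n_samples < 1 or self.n_trials_per_class < 1:
            raise SpecError("n_channels, n_samples and n_trials_per_class must be positive")
        if len(self.class_bands) != self.n_classes:
            raise SpecError(
                f"class_bands has {len(self.class_bands)} entries for {self.n_classes} classes"
            )
        if len(self.mixing) != self.n_classes:
            raise SpecError(
                f"mixing has {len(self.mixing)} vectors for {self.n_classes} classes"
            )
        for k, vec in enumerate(self.mixing):
            v = np.asarray(vec, dtype=float)
            if v.shape != (self.n_channels,):
                raise SpecError(f"mixing vector {k} has length {v.size}, expected {self.n_channels}")
            norm = float(np.linalg.norm(v))
            if not np.isclose(norm, 1.0, atol=1e-6):
                raise SpecError(f"mixing vector {k} has norm {norm:.6g}, expected unit norm")
        for k, bands in enumerate(self.class_bands):
            for (f0, bw, amp) in bands:
                if amp < 0:
                    raise SpecError(f"negative amplitude {amp} in class {k}")
                if f0 < 0 or bw < 0:
                    raise SpecError(f"negative frequency parameters in class {k}")
        if self.noise_sd < 0:
            raise SpecError(f"noise_sd must be >= 0, got {self.noise_sd}")

    @property
    def n_trials(self) -> int:
        return self.n_classes * self.n_trials_per_class

    @property
    def duration(self) -> float:
        return self.n_samples / self.sfreq


@dataclass
class RawTrialSet:
    """Labeled epoched EEG: ``data`` is (trials, C, T), ``labels`` is (trials,)."""

    data: np.ndarray
    labels: np.ndarray
    sfreq: float
    channel_names: list[str] | None = field(default=None)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.data.ndim != 3:
            raise SpecError(f"data must be 3-d (trials, C, T), got shape {self.data.shape}")
        if self.labels.shape != (self.data.shape[0],):
            raise SpecError(
                f"labels length {self.labels.shape} does not match {self.data.shape[0]} trials"
            )
        if self.labels.size and self.labels.min() < 0:
            raise SpecError("labels must be non-negative class ids")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def n_classes(self) -> int:
        return int(self.labels.max()) + 1 if self.labels.size else 0


def _oscillation(bands: tuple[Band, ...], t: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Sum of amplitude-modulated sinusoids, one per band, random phases."""
    out = np.zeros_like(t)
    for (f0, bw, amp) in bands:
        phase = rng.uniform(0.0, 2.0 * np.pi)
        if bw > 0:
            env_phase = rng.uniform(0.0, 2.0 * np.pi)
            envelope = 1.0 + 0.5 * np.sin(2.0 * np.pi * (bw / 2.0) * t + env_phase)
        else:
            envelope = 1.0
        out = out + amp * envelope * np.sin(2.0 * np.pi * f0 * t + phase)
    return out


def _pink_noise(rng: np.random.Generator, shape: tuple[int, ...], sd: float) -> np.ndarray:
    """1/f-shaped Gaussian noise along the last axis, scaled to standard deviation ``sd``."""
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(shape[-1])
    weights = np.zeros_like(freqs)
    np.divide(1.0, np.sqrt(freqs, out=weights, where=freqs > 0), out=weights, where=freqs > 0)
    shaped = np.fft.irfft(spec * weights, n=shape[-1], axis=-1)
    std = shaped.std()
    if std > 0:
        shaped = shaped / std * sd
    return shaped


def generate_trialset(spec: SyntheticSpec) -> RawTrialSet:
    """Generate a class-balanced :class:`RawTrialSet` from ``spec``.

    Deterministic: identical spec (including seed) yields bit-identical arrays.
    """
    rng = np.random.default_rng(spec.seed)
    t = np.arange(spec.n_samples) / spec.sfreq
    n = spec.n_trials
    data = np.zeros((n, spec.n_channels, spec.n_samples))
    labels = np.zeros(n, dtype=np.int64)

    i = 0
    for k in range(spec.n_classes):
        pattern = np.asarray(spec.mixing[k], dtype=float)
        for _ in range(spec.n_trials_per_class):
            source = _oscillation(spec.class_bands[k], t, rng)
            trial = np.outer(pattern, source)
            if spec.noise_sd > 0:
                if spec.pink_noise:
                    trial = trial + _pink_noise(rng, trial.shape, spec.noise_sd)
                else:
                    trial = trial + spec.noise_sd * rng.standard_normal(trial.shape)
            data[i] = trial
            labels[i] = k
            i += 1
    return RawTrialSet(data=data, labels=labels, sfreq=spec.sfreq)


def _orthogonal_mixing(n_channels: int, n_classes: int) -> tuple[tuple[float, ...], ...]:
    vecs = []
    for k in range(n_classes):
        v = np.zeros(n_channels)
        v[k % n_channels] = 1.0
        vecs.append(tuple(v))
    return tuple(vecs)


def _overlapping_mixing(n_channels: int, n_classes: int) -> tuple[tuple[float, ...], ...]:
    """Unit vectors v_k = (e_0 + e_k)/sqrt(2): pairwise cosine similarity 0.5."""
    if n_channels < n_classes + 1:
        raise SpecError(f"need at least {n_classes + 1} channels for {n_classes} overlapping classes")
    a = np.sqrt(0.5)
    vecs = []
    for k in range(n_classes):
        v = np.zeros(n_channels)
        v[0] = a
        v[k + 1] = a
        vecs.append(tuple(v))
    return tuple(vecs)


def make_separable_spec(n_channels: int, difficulty: str = "easy", seed: int = 0) -> SyntheticSpec:
    """Canonical acceptance-suite specs.

    ``easy``: two classes, mu rhythm on orthogonal channels, high SNR.
    ``hard``: four classes, overlapping spatial patterns (pairwise cosine
    0.5) and low SNR.
    """
    if n_channels < 2:
        raise SpecError(f"need at least 2 channels, got {n_channels}")
    if difficulty == "easy":
        return SyntheticSpec(
            n_channels=n_channels,
            sfreq=250.0,
            n_samples=1000,
            n_trials_per_class=40,
            n_classes=2,
            class_bands=(((10.0, 2.0, 1.0),), ((10.0, 2.0, 1.0),)),
            mixing=_orthogonal_mixing(n_channels, 2),
            noise_sd=0.25,
            seed=seed,
        )
    if difficulty == "hard":
        if n_channels < 5:
            raise SpecError("hard spec needs at least 5 channels")
        return SyntheticSpec(
            n_channels=n_channels,
            sfreq=250.0,
            n_samples=1000,
            n_trials_per_class=40,
            n_classes=4,
            class_bands=(
                ((10.0, 2.0, 1.0),),
                ((10.0, 2.0, 1.0),),
                ((22.0, 4.0, 1.0),),
                ((22.0, 4.0, 1.0),),
            ),
            mixing=_overlapping_mixing(n_channels, 4),
            noise_sd=1.0,
            seed=seed,
        )
    raise SpecError(f"unknown difficulty {difficulty!r}; expected 'easy' or 'hard'")
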