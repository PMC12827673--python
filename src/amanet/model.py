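"""The AMANet architecture.

Layer order: multi-scale temporal block -> fusion -> spatial/temporal
refinement block -> efficient channel attention -> depthwise-separable
fusion block -> dense classifier. Every stage's output shape is derivable
from the configuration alone (:func:`stage_shapes`), and the forward pass
is checked against that chain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import nn
from .exceptions import ConfigurationError, DimensionError
from .nn.layers import Layer, Parameter

__all__ = [
    "ModelConfig",
    "StageShapes",
    "AMANet",
    "ECA",
    "build_model",
    "stage_shapes",
    "eca_kernel_size",
    "global_avg_pool",
    "count_parameters",
]


@dataclass(frozen=True)
class ModelConfig:
    """All architecture hyperparameters.

    Defaults correspond to the four-class configuration: 12 input spatial
    channels, 500-sample windows, F1=8 temporal filters, D=2 spatial
    multiplier, F2=16 pointwise filters, kernels (8, 16, 24), K1=64, K2=32.
    """

    in_channels: int = 12
    in_samples: int = 500
    n_classes: int = 4
    F1: int = 8
    D: int = 2
    F2: int = 16
    ms_kernels: tuple[int, int, int] = (8, 16, 24)
    K1: int = 64
    K2: int = 32
    pool1: int = 4
    pool2: int = 8
    eca_mode: str = "fixed"
    eca_k: int = 3
    eca_gamma: float = 2.0
    eca_b: float = 1.0
    eca_padding: str = "zeros"
    fc_width: int = 32
    dropout: float = 0.3
    ms_fusion: str = "pointwise"
    use_multiscale: bool = True
    use_eca: bool = True
    use_st_block: bool = True
    use_dsf_block: bool = True
    dtype: str = "float64"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ConfigurationError(f"need >= 2 classes, got {self.n_classes}")
        if any(k < 1 for k in self.ms_kernels) or self.K1 < 4 or self.K2 < 1:
            raise ConfigurationError("all kernel lengths must be >= 1 (K1 >= 4)")
        if self.eca_k % 2 == 0:
            raise ConfigurationError(f"ECA kernel must be odd, got {self.eca_k}")
        if not 0.0 <= self.dropout < 1.0:
            raise ConfigurationError(f"dropout must be in [0, 1), got {self.dropout}")
        if self.eca_mode not in ("fixed", "adaptive"):
            raise ConfigurationError(f"unknown eca_mode {self.eca_mode!r}")
        if self.ms_fusion not in ("pointwise", "sum"):
            raise ConfigurationError(f"unknown ms_fusion {self.ms_fusion!r}")
        if self.eca_padding not in ("zeros", "circular"):
            raise ConfigurationError(f"unknown eca_padding {self.eca_padding!r}")
        if self.dtype not in ("float32", "float64"):
            raise ConfigurationError(f"unsupported dtype {self.dtype!r}")
        if self.use_dsf_block and self.F2 != self.F1 * self.D:
            raise ConfigurationError(
                f"F2 ({self.F2}) must equal F1*D ({self.F1 * self.D}); the "
                "architecture ties the pointwise output width to the "
                "depthwise channel count"
            )
        if self.in_samples // (self.pool1 * self.pool2) < 1:
            raise ConfigurationError(
                f"in_samples={self.in_samples} too short for the pooling "
                f"chain (needs >= {self.pool1 * self.pool2})"
            )


@dataclass(frozen=True)
class StageShapes:
    """Per-sample output shape after each stage, derived from config only."""

    ms_out: tuple[int, int, int]
    st_out: tuple[int, int, int]
    eca_out: tuple[int, int, int]
    dsf_out: tuple[int, int, int]
    flat: int
    hidden: int
    logits: int


def stage_shapes(cfg: ModelConfig) -> StageShapes:
    f1d = cfg.F1 * cfg.D
    t_pooled = cfg.in_samples // cfg.pool1
    t_final = t_pooled // cfg.pool2
    ms = (cfg.F1, cfg.in_channels, cfg.in_samples)
    st = (f1d, 1, t_pooled)
    dsf = (f1d, 1, t_final)
    return StageShapes(
        ms_out=ms,
        st_out=st,
        eca_out=st,
        dsf_out=dsf,
        flat=f1d * t_final,
        hidden=cfg.fc_width,
        logits=cfg.n_classes,
    )


def eca_kernel_size(n_channels: int, gamma: float = 2.0, b: float = 1.0) -> int:
    """Adaptive attention kernel: nearest odd integer to (log2(C)+b)/gamma.

    Ties between two odd candidates round up. Always >= 1.
    """
    if n_channels < 1:
        raise ConfigurationError(f"channel count must be >= 1, got {n_channels}")
    value = (math.log2(n_channels) + b) / gamma
    if value <= 1.0:
        return 1
    lower = 2 * int((value - 1.0) // 2.0) + 1  # largest odd <= value (or value-2)
    while lower + 2 <= value:
        lower += 2
    upper = lower + 2
    return lower if (value - lower) < (upper - value) else upper


def global_avg_pool(x: np.ndarray) -> np.ndarray:
    """Mean over the trailing spatial axes: (N, C, H, W) -> (N, C)."""
    x = np.asarray(x)
    if x.ndim != 4 or x.shape[2] * x.shape[3] < 1:
        raise DimensionError(f"need a non-empty (N, C, H, W) array, got {x.shape}")
    return x.mean(axis=(2, 3))


class ECA(Layer):
    """Efficient channel attention.

    Globally average-pools each channel to a scalar descriptor, runs a
    bias-free 1-d convolution of odd size ``k`` across the channel axis,
    squashes through a sigmoid and rescales the input channel-wise.
    """

    def __init__(
        self,
        n_channels: int,
        k: int = 3,
        padding: str = "zeros",
        rng: np.random.Generator | None = None,
    ) -> None:
        if k % 2 == 0:
            raise ConfigurationError(f"ECA kernel size must be odd, got {k}")
        if k > n_channels and padding == "circular":
            raise ConfigurationError(
                f"kernel {k} exceeds channel count {n_channels}"
            )
        self.n_channels = n_channels
        self.k = k
        self.padding = padding
        bound = 1.0 / np.sqrt(k)
        rng = rng or np.random.default_rng(0)
        self.weight = Parameter(rng.uniform(-bound, bound, size=k), name="eca.weight")
        self._cache: tuple | None = None

    def parameters(self) -> list[Parameter]:
        return [self.weight]

    def _pad(self, z: np.ndarray) -> np.ndarray:
        p = self.k // 2
        if p == 0:
            return z
        if self.padding == "circular":
            return np.concatenate([z[:, -p:], z, z[:, :p]], axis=1)
        return np.pad(z, ((0, 0), (p, p)))

    def attention_weights(self, x: np.ndarray) -> np.ndarray:
        """The per-channel sigmoid gates for a batch, without rescaling."""
        z = global_avg_pool(x)
        zp = self._pad(z)
        pre = np.zeros_like(z)
        for a in range(self.k):
            pre += self.weight.data[a] * zp[:, a : a + self.n_channels]
        return 1.0 / (1.0 + np.exp(-pre))

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.shape[1] != self.n_channels:
            raise DimensionError(
                f"expected {self.n_channels} channels, got {x.shape[1]}"
            )
        z = global_avg_pool(x)
        zp = self._pad(z)
        pre = np.zeros_like(z)
        for a in range(self.k):
            pre += self.weight.data[a] * zp[:, a : a + self.n_channels]
        s = 1.0 / (1.0 + np.exp(-pre))
        self._cache = (x, zp, s)
        return x * s[:, :, None, None]

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        x, zp, s = self._cache
        hw = x.shape[2] * x.shape[3]
        ds = (grad_out * x).sum(axis=(2, 3))
        dpre = ds * s * (1.0 - s)
        p = self.k // 2
        c = self.n_channels
        dzp = np.zeros_like(zp)
        for a in range(self.k):
            self.weight.grad[a] += float(np.sum(dpre * zp[:, a : a + c]))
            dzp[:, a : a + c] += self.weight.data[a] * dpre
        if p == 0:
            dz = dzp
        elif self.padding == "circular":
            dz = dzp[:, p : p + c].copy()
            dz[:, : p] += dzp[:, p + c :]
            dz[:, -p:] += dzp[:, :p]
        else:
            dz = dzp[:, p : p + c]
        dx = grad_out * s[:, :, None, None]
        dx += dz[:, :, None, None] / hw
        return dx


def _ms_block(cfg: ModelConfig, rng: np.random.Generator) -> Layer:
    """Three parallel temporal convolutions fused back to F1 channels."""
    if not cfg.use_multiscale:
        # single-kernel replacement: the middle (1, 16) branch alone
        k = cfg.ms_kernels[1]
        return nn.Sequential(
            nn.Conv2d(1, cfg.F1, (1, k), same_w=True, rng=rng),
            nn.BatchNorm2d(cfg.F1),
            nn.ELU(),
        )
    branches = [
        nn.Sequential(
            nn.Conv2d(1, cfg.F1, (1, k), same_w=True, rng=rng),
            nn.BatchNorm2d(cfg.F1),
            nn.ELU(),
        )
        for k in cfg.ms_kernels
    ]
    if cfg.ms_fusion == "sum":
        return _SumBranches(branches)
    return nn.Sequential(
        nn.Concat(*branches),
        nn.Conv2d(3 * cfg.F1, cfg.F1, (1, 1), rng=rng),
    )


class _SumBranches(Layer):
    def __init__(self, branches: list[Layer]) -> None:
        self.branches = branches

    def parameters(self) -> list[Parameter]:
        return [p for b in self.branches for p in b.parameters()]

    def set_training(self, mode: bool) -> None:
        self.training = mode
        for b in self.branches:
            b.set_training(mode)

    def astype(self, dtype) -> None:
        for b in self.branches:
            b.astype(dtype)

    def forward(self, x: np.ndarray) -> np.ndarray:
        out = None
        for b in self.branches:
            y = b.forward(x)
            out = y if out is None else out + y
        return out

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        dx = None
        for b in self.branches:
            g = b.backward(grad_out)
            dx = g if dx is None else dx + g
        return dx


def _st_block(cfg: ModelConfig, rng: np.random.Generator, drop_rng: np.random.Generator) -> Layer:
    f1d = cfg.F1 * cfg.D
    if not cfg.use_st_block:
        # parameter-free stand-in keeping the downstream shape contract:
        # duplicate channels F1 -> F1*D, collapse the spatial axis, pool x4
        return nn.Sequential(
            nn.ChannelRepeat(cfg.D),
            nn.SpatialCollapse(),
            nn.AvgPool2d((1, cfg.pool1)),
        )
    return nn.Sequential(
        nn.Conv2d(cfg.F1, f1d, (cfg.in_channels, 1), groups=cfg.F1, rng=rng),
        nn.BatchNorm2d(f1d),
        nn.ELU(),
        nn.Conv2d(f1d, f1d, (1, cfg.K1 // 4), same_w=True, rng=rng),
        nn.BatchNorm2d(f1d),
        nn.ELU(),
        nn.AvgPool2d((1, cfg.pool1)),
        nn.Dropout(cfg.dropout, rng=drop_rng),
    )


def _dsf_block(cfg: ModelConfig, rng: np.random.Generator, drop_rng: np.random.Generator) -> Layer:
    f1d = cfg.F1 * cfg.D
    if not cfg.use_dsf_block:
        return nn.AvgPool2d((1, cfg.pool2))
    return nn.Sequential(
        nn.Conv2d(f1d, f1d, (1, cfg.K2), groups=f1d, same_w=True, rng=rng),
        nn.Conv2d(f1d, cfg.F2, (1, 1), rng=rng),
        nn.BatchNorm2d(cfg.F2),
        nn.ELU(),
        nn.AvgPool2d((1, cfg.pool2)),
        nn.Dropout(cfg.dropout, rng=drop_rng),
    )


class AMANet:
    """The assembled network with explicit stage boundaries."""

    def __init__(self, cfg: ModelConfig) -> None:
        self.cfg = cfg
        self.shapes = stage_shapes(cfg)
        rng = np.random.default_rng(cfg.seed)
        self.dropout_rng = np.random.default_rng((cfg.seed, 0xD0))
        f1d = cfg.F1 * cfg.D
        self.ms = _ms_block(cfg, rng)
        self.st = _st_block(cfg, rng, self.dropout_rng)
        if cfg.use_eca:
            k = cfg.eca_k if cfg.eca_mode == "fixed" else eca_kernel_size(f1d, cfg.eca_gamma, cfg.eca_b)
            self.eca: Layer = ECA(f1d, k=k, padding=cfg.eca_padding, rng=rng)
        else:
            self.eca = nn.Identity()
        self.dsf = _dsf_block(cfg, rng, self.dropout_rng)
        self.classifier = nn.Sequential(
            nn.Flatten(),
            nn.Linear(self.shapes.flat, cfg.fc_width, rng=rng),
            nn.ELU(),
            nn.Dropout(cfg.dropout, rng=self.dropout_rng),
            nn.Linear(cfg.fc_width, cfg.n_classes, rng=rng),
        )
        self._stages = [self.ms, self.st, self.eca, self.dsf, self.classifier]
        self.dtype = np.dtype(cfg.dtype)
        if self.dtype != np.float64:
            for s in self._stages:
                s.astype(self.dtype)
        self.training = False

    # -- torch-like surface -------------------------------------------------
    def parameters(self) -> list[Parameter]:
        return [p for s in self._stages for p in s.parameters()]

    def train(self) -> "AMANet":
        self.training = True
        for s in self._stages:
            s.set_training(True)
        return self

    def eval(self) -> "AMANet":
        self.training = False
        for s in self._stages:
            s.set_training(False)
        return self

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=self.dtype)
        if x.ndim == 3:
            x = x[:, None, :, :]
        if x.ndim != 4 or x.shape[1] != 1:
            raise DimensionError(
                f"expected a (N, 1, C1, T1) batch, got shape {x.shape}"
            )
        if x.shape[2] != self.cfg.in_channels or x.shape[3] != self.cfg.in_samples:
            raise DimensionError(
                f"batch spatial shape {x.shape[2:]} does not match config "
                f"({self.cfg.in_channels}, {self.cfg.in_samples})"
            )
        for s in self._stages:
            x = s.forward(x)
        return x

    __call__ = forward

    def forward_stages(self, x: np.ndarray) -> dict[str, np.ndarray]:
        """Forward pass returning every intermediate activation (eval use)."""
        x = np.asarray(x, dtype=self.dtype)
        if x.ndim == 3:
            x = x[:, None, :, :]
        out = {}
        for name, s in zip(["ms", "st", "eca", "dsf", "logits"], self._stages):
            x = s.forward(x)
            out[name] = x
        return out

    def backward(self, grad_logits: np.ndarray) -> np.ndarray:
        g = grad_logits
        for s in reversed(self._stages):
            g = s.backward(g)
        return g

    def state_dict(self) -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}
        for i, p in enumerate(self.parameters()):
            state[f"p{i:03d}"] = p.data.copy()
        for j, s in enumerate(_iter_layers(self._stages)):
            if isinstance(s, nn.BatchNorm2d):
                state[f"bn{j:03d}.mean"] = s.running_mean.copy()
                state[f"bn{j:03d}.var"] = s.running_var.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.parameters()):
            p.data[...] = state[f"p{i:03d}"]
        for j, s in enumerate(_iter_layers(self._stages)):
            if isinstance(s, nn.BatchNorm2d):
                s.running_mean[...] = state[f"bn{j:03d}.mean"]
                s.running_var[...] = state[f"bn{j:03d}.var"]


def _iter_layers(layers) -> list[Layer]:
    flat: list[Layer] = []
    for l in layers:
        if isinstance(l, nn.Sequential):
            flat.extend(_iter_layers(l.layers))
        elif isinstance(l, nn.Concat):
            flat.extend(_iter_layers(l.branches))
        elif isinstance(l, _SumBranches):
            flat.extend(_iter_layers(l.branches))
        else:
            flat.append(l)
    return flat


def build_model(cfg: ModelConfig) -> AMANet:
    """Construct the network; weights are deterministic under ``cfg.seed``."""
    return AMANet(cfg)


def count_parameters(model: AMANet) -> tuple[int, dict[str, int]]:
    """Total trainable parameter count plus a per-stage breakdown."""
    names = ["ms", "st", "eca", "dsf", "classifier"]
    breakdown = {
        name: sum(p.size for p in stage.parameters())
        for name, stage in zip(names, model._stages)
    }
    return sum(breakdown.values()), breakdown


def config_for_ablation(cfg: ModelConfig, **flags: bool) -> ModelConfig:
    """Return a copy of ``cfg`` with ablation flags applied."""
    return replace(cfg, **flags)
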