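"""Layers operating on (N, C, H, W) arrays (float64 default, float32 optional).

Convolutions always use stride 1; "same" padding pads ``k // 2`` on both
sides of an axis and crops any trailing surplus sample, so even kernels
preserve the input length exactly.
"""

from __future__ import annotations

import numpy as np

from ..exceptions import ConfigurationError, DimensionError


class Parameter:
    """A trainable array with an accumulated gradient."""

    __slots__ = ("data", "grad", "name")

    def __init__(self, data: np.ndarray, name: str = "") -> None:
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = np.zeros_like(self.data)
        self.name = name

    def astype(self, dtype) -> None:
        self.data = self.data.astype(dtype)
        self.grad = self.grad.astype(dtype)

    @property
    def size(self) -> int:
        return self.data.size


class Layer:
    """Base class: stateless by default, caches activations for backward."""

    training: bool = False

    def parameters(self) -> list[Parameter]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, grad_out: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def set_training(self, mode: bool) -> None:
        self.training = mode

    def astype(self, dtype) -> None:
        for p in self.parameters():
            p.astype(dtype)

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)


class Identity(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        return x

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        return grad_out


class Sequential(Layer):
    def __init__(self, *layers: Layer) -> None:
        self.layers = [l for l in layers if l is not None]

    def parameters(self) -> list[Parameter]:
        return [p for l in self.layers for p in l.parameters()]

    def set_training(self, mode: bool) -> None:
        self.training = mode
        for l in self.layers:
            l.set_training(mode)

    def astype(self, dtype) -> None:
        for l in self.layers:
            l.astype(dtype)

    def forward(self, x: np.ndarray) -> np.ndarray:
        for l in self.layers:
            x = l.forward(x)
        return x

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        for l in reversed(self.layers):
            grad_out = l.backward(grad_out)
        return grad_out


class Concat(Layer):
    """Parallel branches concatenated along the channel axis."""

    def __init__(self, *branches: Layer) -> None:
        self.branches = list(branches)
        self._splits: list[int] = []

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
        outs = [b.forward(x) for b in self.branches]
        self._splits = [o.shape[1] for o in outs]
        return np.concatenate(outs, axis=1)

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        grads = np.split(grad_out, np.cumsum(self._splits)[:-1], axis=1)
        dx = None
        for b, g in zip(self.branches, grads):
            contrib = b.backward(g)
            dx = contrib if dx is None else dx + contrib
        return dx


class Conv2d(Layer):
    """Grouped 2-d convolution, stride 1.

    ``same_h`` / ``same_w`` request length-preserving padding on that axis;
    otherwise the axis is convolved "valid".
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel: tuple[int, int],
        groups: int = 1,
        bias: bool = True,
        same_h: bool = False,
        same_w: bool = False,
        rng: np.random.Generator | None = None,
    ) -> None:
        if in_channels % groups or out_channels % groups:
            raise ConfigurationError(
                f"channels ({in_channels}->{out_channels}) not divisible by "
                f"groups={groups}"
            )
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kh, self.kw = kernel
        self.groups = groups
        self.same_h = same_h
        self.same_w = same_w
        cin_g = in_channels // groups
        fan_in = cin_g * self.kh * self.kw
        bound = 1.0 / np.sqrt(fan_in)
        rng = rng or np.random.default_rng(0)
        self.weight = Parameter(
            rng.uniform(-bound, bound, size=(out_channels, cin_g, self.kh, self.kw)),
            name="conv.weight",
        )
        self.bias = Parameter(rng.uniform(-bound, bound, size=out_channels), name="conv.bias") if bias else None
        self._cols: np.ndarray | None = None
        self._in_shape: tuple[int, ...] | None = None

    def parameters(self) -> list[Parameter]:
        return [self.weight] + ([self.bias] if self.bias is not None else [])

    def _pads(self) -> tuple[int, int]:
        return (self.kh // 2 if self.same_h else 0, self.kw // 2 if self.same_w else 0)

    def out_shape(self, h: int, w: int) -> tuple[int, int]:
        if self.same_h:
            ho = h
        else:
            ho = h - self.kh + 1
        wo = w if self.same_w else w - self.kw + 1
        return ho, wo

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        if c != self.in_channels:
            raise DimensionError(
                f"expected {self.in_channels} input channels, got {c}"
            )
        ph, pw = self._pads()
        xp = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
        self._in_shape = x.shape
        ho, wo = self.out_shape(h, w)
        g = self.groups
        cin_g = self.in_channels // g
        cout_g = self.out_channels // g
        # im2col: (n, g, ho*wo, cin_g*kh*kw), then one matmul per group
        view = np.lib.stride_tricks.sliding_window_view(xp, (self.kh, self.kw), axis=(2, 3))
        view = view[:, :, : ho, : wo]  # crop any same-padding surplus
        cols = (
            view.reshape(n, g, cin_g, ho, wo, self.kh * self.kw)
            .transpose(0, 1, 3, 4, 2, 5)
            .reshape(n, g, ho * wo, cin_g * self.kh * self.kw)
        )
        self._cols = cols
        wmat = self.weight.data.reshape(g, cout_g, cin_g * self.kh * self.kw)
        y = cols @ wmat.transpose(0, 2, 1)[None]  # (n, g, ho*wo, cout_g)
        y = y.transpose(0, 1, 3, 2).reshape(n, self.out_channels, ho, wo)
        if self.bias is not None:
            y += self.bias.data[None, :, None, None]
        return y

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        n, c, h, w = self._in_shape
        ph, pw = self._pads()
        ho, wo = grad_out.shape[2], grad_out.shape[3]
        g = self.groups
        cin_g = self.in_channels // g
        cout_g = self.out_channels // g
        kk = self.kh * self.kw
        p_ = ho * wo
        dy = (
            grad_out.reshape(n, g, cout_g, p_).transpose(0, 1, 3, 2)
        )  # (n, g, P, cout_g)
        wmat = self.weight.data.reshape(g, cout_g, cin_g * kk)
        # weight gradient as one BLAS matmul per group: (K, n*P) @ (n*P, cout_g)
        cols_g = np.ascontiguousarray(self._cols.transpose(1, 3, 0, 2)).reshape(
            g, kk * cin_g, n * p_
        )
        dy_g = np.ascontiguousarray(dy.transpose(1, 0, 2, 3)).reshape(g, n * p_, cout_g)
        dw = (cols_g @ dy_g).transpose(0, 2, 1)  # (g, cout_g, cin_g*kk)
        self.weight.grad += dw.reshape(self.weight.data.shape)
        if self.bias is not None:
            self.bias.grad += grad_out.sum(axis=(0, 2, 3))
        # input gradient: col2im scatter-add of dy @ W
        dcols = (dy @ wmat[None]).reshape(n, g, ho, wo, cin_g, self.kh, self.kw)
        dxp = np.zeros((n, g, cin_g, h + 2 * ph, w + 2 * pw), dtype=dcols.dtype)
        for a in range(self.kh):
            for b in range(self.kw):
                dxp[:, :, :, a : a + ho, b : b + wo] += dcols[:, :, :, :, :, a, b].transpose(
                    0, 1, 4, 2, 3
                )
        dxp = dxp.reshape(n, self.in_channels, h + 2 * ph, w + 2 * pw)
        return dxp[:, :, ph : ph + h, pw : pw + w]


class BatchNorm2d(Layer):
    def __init__(self, num_features: int, eps: float = 1e-5, momentum: float = 0.1) -> None:
        self.num_features = num_features
        self.eps = eps
        self.momentum = momentum
        self.gamma = Parameter(np.ones(num_features), name="bn.gamma")
        self.beta = Parameter(np.zeros(num_features), name="bn.beta")
        self.running_mean = np.zeros(num_features)
        self.running_var = np.ones(num_features)
        self._cache: tuple | None = None

    def parameters(self) -> list[Parameter]:
        return [self.gamma, self.beta]

    def astype(self, dtype) -> None:
        super().astype(dtype)
        self.running_mean = self.running_mean.astype(dtype)
        self.running_var = self.running_var.astype(dtype)

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.shape[1] != self.num_features:
            raise DimensionError(
                f"expected {self.num_features} channels, got {x.shape[1]}"
            )
        if self.training:
            axes = (0, 2, 3)
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = x.shape[0] * x.shape[2] * x.shape[3]
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            unbiased = var * m / max(m - 1, 1)
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * unbiased
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv_std[None, :, None, None]
        self._cache = (xhat, inv_std)
        return self.gamma.data[None, :, None, None] * xhat + self.beta.data[None, :, None, None]

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        xhat, inv_std = self._cache
        axes = (0, 2, 3)
        self.gamma.grad += (grad_out * xhat).sum(axis=axes)
        self.beta.grad += grad_out.sum(axis=axes)
        dxhat = grad_out * self.gamma.data[None, :, None, None]
        if not self.training:
            return dxhat * inv_std[None, :, None, None]
        m = grad_out.shape[0] * grad_out.shape[2] * grad_out.shape[3]
        sum_dxhat = dxhat.sum(axis=axes)[None, :, None, None]
        sum_dxhat_xhat = (dxhat * xhat).sum(axis=axes)[None, :, None, None]
        return (inv_std[None, :, None, None] / m) * (m * dxhat - sum_dxhat - xhat * sum_dxhat_xhat)


class ELU(Layer):
    def __init__(self, alpha: float = 1.0) -> None:
        self.alpha = alpha
        self._y: np.ndarray | None = None
        self._pos: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        pos = x > 0
        y = np.where(pos, x, self.alpha * np.expm1(np.minimum(x, 0.0)))
        self._y, self._pos = y, pos
        return y

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        return grad_out * np.where(self._pos, 1.0, self._y + self.alpha)


class AvgPool2d(Layer):
    """Non-overlapping average pooling with floor semantics.

    A trailing remainder shorter than the pool is dropped (gradient zero
    there), so lengths follow ``floor(L / pool)``.
    """

    def __init__(self, pool: tuple[int, int]) -> None:
        self.ph, self.pw = pool
        self._in_shape: tuple[int, ...] | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        ho, wo = h // self.ph, w // self.pw
        if ho < 1 or wo < 1:
            raise DimensionError(
                f"input ({h}, {w}) too small for pooling ({self.ph}, {self.pw})"
            )
        self._in_shape = x.shape
        trimmed = x[:, :, : ho * self.ph, : wo * self.pw]
        return trimmed.reshape(n, c, ho, self.ph, wo, self.pw).mean(axis=(3, 5))

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        n, c, h, w = self._in_shape
        ho, wo = grad_out.shape[2], grad_out.shape[3]
        dx = np.zeros(self._in_shape, dtype=grad_out.dtype)
        expanded = np.repeat(np.repeat(grad_out, self.ph, axis=2), self.pw, axis=3)
        dx[:, :, : ho * self.ph, : wo * self.pw] = expanded / (self.ph * self.pw)
        return dx


class Dropout(Layer):
    """Inverted dropout; draws masks from the generator supplied at build."""

    def __init__(self, p: float, rng: np.random.Generator | None = None) -> None:
        if not 0.0 <= p < 1.0:
            raise ConfigurationError(f"dropout rate must be in [0, 1), got {p}")
        self.p = p
        self.rng = rng or np.random.default_rng(0)
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        if not self.training or self.p == 0.0:
            self._mask = None
            return x
        keep = self.rng.random(x.shape) >= self.p
        self._mask = keep.astype(x.dtype) / x.dtype.type(1.0 - self.p)
        return x * self._mask

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return grad_out
        return grad_out * self._mask


class Flatten(Layer):
    def __init__(self) -> None:
        self._in_shape: tuple[int, ...] | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        return grad_out.reshape(self._in_shape)


class Linear(Layer):
    def __init__(
        self,
        in_features: int,
        out_features: int,
        bias: bool = True,
        rng: np.random.Generator | None = None,
    ) -> None:
        self.in_features = in_features
        self.out_features = out_features
        bound = 1.0 / np.sqrt(in_features)
        rng = rng or np.random.default_rng(0)
        self.weight = Parameter(
            rng.uniform(-bound, bound, size=(out_features, in_features)), name="linear.weight"
        )
        self.bias = Parameter(rng.uniform(-bound, bound, size=out_features), name="linear.bias") if bias else None
        self._x: np.ndarray | None = None

    def parameters(self) -> list[Parameter]:
        return [self.weight] + ([self.bias] if self.bias is not None else [])

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.shape[1] != self.in_features:
            raise DimensionError(
                f"expected {self.in_features} features, got {x.shape[1]}"
            )
        self._x = x
        y = x @ self.weight.data.T
        if self.bias is not None:
            y += self.bias.data
        return y

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        self.weight.grad += grad_out.T @ self._x
        if self.bias is not None:
            self.bias.grad += grad_out.sum(axis=0)
        return grad_out @ self.weight.data


class ChannelRepeat(Layer):
    """Tile each channel ``factor`` times (parameter-free channel expansion)."""

    def __init__(self, factor: int) -> None:
        self.factor = factor

    def forward(self, x: np.ndarray) -> np.ndarray:
        return np.repeat(x, self.factor, axis=1)

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        n, cf, h, w = grad_out.shape
        return grad_out.reshape(n, cf // self.factor, self.factor, h, w).sum(axis=2)


class SpatialCollapse(Layer):
    """Average over the spatial (H) axis, keeping a singleton dimension."""

    def __init__(self) -> None:
        self._h: int | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._h = x.shape[2]
        return x.mean(axis=2, keepdims=True)

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        return np.repeat(grad_out, self._h, axis=2) / self._h
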