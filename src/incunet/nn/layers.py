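"""Neural-network layers on top of the autodiff engine.

All spatial layers use NCHW layout and stride-1 same-padded convolutions
(the U-Net family here preserves spatial size within a stage; resolution
changes only through 2x2 max-pooling and 2x transposed convolution).
Convolution forward/backward is an im2col matmul, which keeps everything
inside BLAS.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, from_op

__all__ = [
    "Module",
    "Sequential",
    "Conv2d",
    "DepthwiseConv2d",
    "SeparableConv2d",
    "ConvTranspose2d",
    "MaxPool2d",
    "BatchNorm2d",
    "Dense",
    "Flatten",
    "ReLU",
    "Sigmoid",
]


class Module:
    """Base class: parameter discovery, train/eval mode propagation."""

    def __init__(self):
        self.training = True

    def forward(self, x: Tensor) -> Tensor:  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, x: Tensor) -> Tensor:
        return self.forward(x)

    def _children(self):
        for name, value in vars(self).items():
            if isinstance(value, Module):
                yield value
            elif isinstance(value, (list, tuple)):
                for v in value:
                    if isinstance(v, Module):
                        yield v

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for value in vars(self).values():
            if isinstance(value, Tensor) and value.requires_grad:
                params.append(value)
        for child in self._children():
            params.extend(child.parameters())
        return params

    def modules(self):
        yield self
        for child in self._children():
            yield from child.modules()

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


def _param(shape, requires_grad=True, weight=False) -> Tensor:
    t = Tensor(np.zeros(shape), requires_grad=requires_grad)
    t.is_weight = weight
    return t


def _im2col(x: np.ndarray, kh: int, kw: int) -> np.ndarray:
    """(N,C,H,W) -> (N, C*kh*kw, H*W) columns for a same-padded stride-1 conv."""
    n, c, h, w = x.shape
    ph, pw = kh // 2, kw // 2
    xp = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    # win: (N, C, H, W, kh, kw) -> (N, C, kh, kw, H*W)
    cols = win.transpose(0, 1, 4, 5, 2, 3).reshape(n, c * kh * kw, h * w)
    return np.ascontiguousarray(cols)


def _col2im(gcols: np.ndarray, x_shape, kh: int, kw: int) -> np.ndarray:
    """Adjoint of :func:`_im2col`: scatter-add column gradients back."""
    n, c, h, w = x_shape
    ph, pw = kh // 2, kw // 2
    gx = np.zeros((n, c, h + 2 * ph, w + 2 * pw))
    g = gcols.reshape(n, c, kh, kw, h, w)
    for i in range(kh):
        for j in range(kw):
            gx[:, :, i : i + h, j : j + w] += g[:, :, i, j]
    return gx[:, :, ph : ph + h, pw : pw + w]


class Conv2d(Module):
    """Same-padded stride-1 convolution, odd square or rectangular kernels."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size, bias: bool = True):
        super().__init__()
        if isinstance(kernel_size, int):
            kernel_size = (kernel_size, kernel_size)
        kh, kw = kernel_size
        if kh % 2 == 0 or kw % 2 == 0:
            raise ValueError("same-padding requires odd kernel sizes")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = (kh, kw)
        self.weight = _param((out_channels, in_channels, kh, kw), weight=True)
        self.bias = _param((out_channels,)) if bias else None
        self.last_input_hw: tuple[int, int] | None = None

    def forward(self, x: Tensor) -> Tensor:
        kh, kw = self.kernel_size
        n, c, h, w = x.data.shape
        self.last_input_hw = (h, w)
        cols = _im2col(x.data, kh, kw)  # (N, C*kh*kw, H*W)
        w2 = self.weight.data.reshape(self.out_channels, -1)
        out_data = np.matmul(w2, cols).reshape(n, self.out_channels, h, w)
        if self.bias is not None:
            out_data = out_data + self.bias.data[None, :, None, None]
        parents = (x, self.weight) + ((self.bias,) if self.bias is not None else ())
        out = from_op(out_data, parents)
        weight, bias = self.weight, self.bias

        def bwd(g):
            gflat = g.reshape(n, self.out_channels, h * w)
            # one big GEMM: (D, N*P) @ (N*P, K)
            gw = gflat.transpose(1, 0, 2).reshape(self.out_channels, -1) @ (
                cols.transpose(0, 2, 1).reshape(-1, cols.shape[1])
            )
            weight._accumulate(gw.reshape(weight.data.shape))
            if bias is not None:
                bias._accumulate(g.sum(axis=(0, 2, 3)))
            gcols = np.matmul(w2.T, gflat)
            x._accumulate(_col2im(gcols, (n, c, h, w), kh, kw))

        out._backward = bwd
        return out


class DepthwiseConv2d(Module):
    """Per-channel spatial convolution (the depthwise half of a separable conv)."""

    def __init__(self, channels: int, kernel_size, bias: bool = False):
        super().__init__()
        if isinstance(kernel_size, int):
            kernel_size = (kernel_size, kernel_size)
        kh, kw = kernel_size
        if kh % 2 == 0 or kw % 2 == 0:
            raise ValueError("same-padding requires odd kernel sizes")
        self.channels = channels
        self.kernel_size = (kh, kw)
        self.weight = _param((channels, kh, kw), weight=True)
        self.bias = _param((channels,)) if bias else None
        self.last_input_hw: tuple[int, int] | None = None

    def forward(self, x: Tensor) -> Tensor:
        kh, kw = self.kernel_size
        n, c, h, w = x.data.shape
        self.last_input_hw = (h, w)
        cols = _im2col(x.data, kh, kw).reshape(n, c, kh * kw, h * w)
        wflat = self.weight.data.reshape(c, kh * kw)
        # batched matmul over (N, C): (1, K) @ (K, P) -> (1, P)
        out_data = np.matmul(wflat[:, None, :], cols)[:, :, 0, :].reshape(n, c, h, w)
        if self.bias is not None:
            out_data = out_data + self.bias.data[None, :, None, None]
        parents = (x, self.weight) + ((self.bias,) if self.bias is not None else ())
        out = from_op(out_data, parents)
        weight, bias = self.weight, self.bias

        def bwd(g):
            gflat = g.reshape(n, c, 1, h * w)
            gw = np.matmul(cols, gflat.transpose(0, 1, 3, 2))[..., 0].sum(axis=0)
            weight._accumulate(gw.reshape(weight.data.shape))
            if bias is not None:
                bias._accumulate(g.sum(axis=(0, 2, 3)))
            gcols = np.matmul(wflat[:, :, None], gflat).reshape(n, c * kh * kw, h * w)
            x._accumulate(_col2im(gcols, (n, c, h, w), kh, kw))

        out._backward = bwd
        return out


class SeparableConv2d(Module):
    """Depthwise k x k followed by pointwise 1x1 — the factored convolution
    whose multiply count is Uw*Uh*C*P^2 + C*D*P^2 instead of Uw*Uh*C*D*P^2."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size, bias: bool = True):
        super().__init__()
        self.depthwise = DepthwiseConv2d(in_channels, kernel_size, bias=False)
        self.pointwise = Conv2d(in_channels, out_channels, 1, bias=bias)

    def forward(self, x: Tensor) -> Tensor:
        return self.pointwise(self.depthwise(x))


class ConvTranspose2d(Module):
    """2x upsampling transposed convolution with a 2x2 kernel (no overlap)."""

    def __init__(self, in_channels: int, out_channels: int, bias: bool = True):
        super().__init__()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.weight = _param((in_channels, out_channels, 2, 2), weight=True)
        self.bias = _param((out_channels,)) if bias else None
        self.last_input_hw: tuple[int, int] | None = None

    def forward(self, x: Tensor) -> Tensor:
        n, c, h, w = x.data.shape
        self.last_input_hw = (h, w)
        out_data = np.zeros((n, self.out_channels, 2 * h, 2 * w))
        xt = x.data.transpose(0, 2, 3, 1)  # (N, H, W, C)
        for i in range(2):
            for j in range(2):
                out_data[:, :, i::2, j::2] = (xt @ self.weight.data[:, :, i, j]).transpose(
                    0, 3, 1, 2
                )
        if self.bias is not None:
            out_data += self.bias.data[None, :, None, None]
        parents = (x, self.weight) + ((self.bias,) if self.bias is not None else ())
        out = from_op(out_data, parents)
        weight, bias = self.weight, self.bias

        def bwd(g):
            gx = np.zeros_like(x.data)
            gw = np.zeros_like(weight.data)
            xt = x.data.transpose(0, 2, 3, 1).reshape(-1, weight.data.shape[0])
            for i in range(2):
                for j in range(2):
                    gij = g[:, :, i::2, j::2]
                    gt = gij.transpose(0, 2, 3, 1)
                    gx += (gt @ weight.data[:, :, i, j].T).transpose(0, 3, 1, 2)
                    gw[:, :, i, j] = xt.T @ gt.reshape(-1, weight.data.shape[1])
            weight._accumulate(gw)
            if bias is not None:
                bias._accumulate(g.sum(axis=(0, 2, 3)))
            x._accumulate(gx)

        out._backward = bwd
        return out


class MaxPool2d(Module):
    """2x2 max pooling; odd trailing rows/columns are dropped."""

    def __init__(self):
        super().__init__()

    def forward(self, x: Tensor) -> Tensor:
        n, c, h, w = x.data.shape
        ho, wo = h // 2, w // 2
        xv = x.data[:, :, : 2 * ho, : 2 * wo]
        blocks = xv.reshape(n, c, ho, 2, wo, 2).transpose(0, 1, 2, 4, 3, 5).reshape(
            n, c, ho, wo, 4
        )
        idx = blocks.argmax(axis=-1)
        out = from_op(np.take_along_axis(blocks, idx[..., None], axis=-1)[..., 0], (x,))

        def bwd(g):
            gb = np.zeros((n, c, ho, wo, 4))
            np.put_along_axis(gb, idx[..., None], g[..., None], axis=-1)
            gx = np.zeros_like(x.data)
            gx[:, :, : 2 * ho, : 2 * wo] = (
                gb.reshape(n, c, ho, wo, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(
                    n, c, 2 * ho, 2 * wo
                )
            )
            x._accumulate(gx)

        out._backward = bwd
        return out


class BatchNorm2d(Module):
    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.channels = channels
        self.eps = eps
        self.momentum = momentum
        self.gamma = _param((channels,))
        self.gamma.data[:] = 1.0
        self.beta = _param((channels,))
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mean = x.data.mean(axis=(0, 2, 3))
            var = x.data.var(axis=(0, 2, 3))
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mean
            self.running_var = (1 - m) * self.running_var + m * var
        else:
            mean, var = self.running_mean, self.running_var
        std = np.sqrt(var + self.eps)
        xhat = (x.data - mean[None, :, None, None]) / std[None, :, None, None]
        out_data = self.gamma.data[None, :, None, None] * xhat + self.beta.data[
            None, :, None, None
        ]
        out = from_op(out_data, (x, self.gamma, self.beta))
        gamma, beta, training = self.gamma, self.beta, self.training

        def bwd(g):
            gamma._accumulate((g * xhat).sum(axis=(0, 2, 3)))
            beta._accumulate(g.sum(axis=(0, 2, 3)))
            gs = g * gamma.data[None, :, None, None]
            if training:
                # gradient through the batch statistics
                mdim = (0, 2, 3)
                mean_gs = gs.mean(axis=mdim, keepdims=True)
                mean_gs_xhat = (gs * xhat).mean(axis=mdim, keepdims=True)
                gx = (gs - mean_gs - xhat * mean_gs_xhat) / std[None, :, None, None]
            else:
                gx = gs / std[None, :, None, None]
            x._accumulate(gx)

        out._backward = bwd
        return out


class Dense(Module):
    def __init__(self, in_features: int, out_features: int, bias: bool = True):
        super().__init__()
        self.in_features = in_features
        self.out_features = out_features
        self.weight = _param((in_features, out_features), weight=True)
        self.bias = _param((out_features,)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class Flatten(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.reshape(x.data.shape[0], -1)


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class Sigmoid(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.sigmoid()
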