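"""A compact numpy CNN engine tailored to the multi-branch EEG network.

Layers carry explicit ``forward``/``backward`` passes with hand-derived
gradients; no autograd. Temporal convolutions (kernel 100 on 125-sample
epochs) dominate the arithmetic, so they run in the frequency domain via
:mod:`scipy.fft`; the short separable-convolution kernels use direct
sliding-window products. Everything computes in float32.

Shape convention inside a branch: ``(N, F, C, T)`` — batch, feature maps,
spatial channels, time. Branch input is ``(N, 1, C, T)``.

Convolutions follow the deep-learning cross-correlation convention with
"same" zero padding: ``y[t] = sum_k w[k] * x[t + k - (K-1)//2]``.
"""

from __future__ import annotations

import copy
from typing import Dict, List, Sequence

import numpy as np
from scipy import fft as sfft

DTYPE = np.float32


class Param:
    """A trainable tensor and its gradient accumulator."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = np.ascontiguousarray(value, dtype=DTYPE)
        self.grad = np.zeros_like(self.value)
        self.name = name

    @property
    def size(self) -> int:
        return self.value.size


def glorot_uniform(rng: np.random.Generator, shape, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(DTYPE)


class Layer:
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def params(self) -> List[Param]:
        return []


class TemporalConv(Layer):
    """1 x K temporal convolution, single input map -> F output maps, no bias.

    (N, 1, C, T) -> (N, F, C, T), "same" padding, FFT-based. When the layer
    sits first in a stack (its input is raw data) set
    ``needs_input_grad=False`` to skip the input-gradient transform.
    """

    def __init__(self, n_filters: int, kernel: int, rng: np.random.Generator,
                 needs_input_grad: bool = False):
        self.K = int(kernel)
        self.F = int(n_filters)
        self.w = Param(glorot_uniform(rng, (self.F, self.K), self.K, self.K), "temporal_conv.w")
        self.pl = (self.K - 1) // 2
        self.pr = self.K - 1 - self.pl
        self.needs_input_grad = needs_input_grad

    def params(self) -> List[Param]:
        return [self.w]

    def _fft_len(self, T: int) -> int:
        # Smallest circular length whose wrap-around stays outside every
        # window we slice ("same" forward output, dW window, dx window).
        K, pl, pr = self.K, self.pl, self.pr
        j0 = T - 1 - pl
        need = max(pr + T, T + K - 1 - pr,       # forward slice [pr, pr+T)
                   j0 + K, 2 * T - 1 - j0,       # dW slice [j0, j0+K)
                   pl + T, T + K - 1 - pl)       # dx slice [pl, pl+T)
        return sfft.next_fast_len(need, real=True)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        assert x.shape[1] == 1, "temporal conv expects a single input feature map"
        N, _, C, T = x.shape
        L = self._fft_len(T)
        self._L, self._T = L, T
        xf = sfft.rfft(x[:, 0], n=L, axis=-1)          # (N, C, Lf)
        self._xf = xf
        wrf = sfft.rfft(self.w.value[:, ::-1], n=L, axis=-1)  # (F, Lf)
        yf = xf[:, None, :, :] * wrf[None, :, None, :]
        y = sfft.irfft(yf, n=L, axis=-1, overwrite_x=True)[..., self.pr:self.pr + T]
        return np.ascontiguousarray(y, dtype=DTYPE)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        N, F, C, T = dy.shape
        L = self._L
        dyf = sfft.rfft(dy, n=L, axis=-1)              # (N, F, C, Lf)
        # dW[f, k] = sum_{n,c,t} dy[n,f,c,t] * x[n,c,t + k - pl].
        # rfft of the time-reversed dy follows from dyf by conjugation:
        # rev over [0, T) then zero-pad  <=>  conj(dyf) * exp(-2i*pi*k*(T-1)/L)
        k = np.arange(dyf.shape[-1])
        phase = np.exp(-2j * np.pi * k * (T - 1) / L).astype(np.complex64)
        dyr = np.conj(dyf) * phase
        gf = np.einsum("ncl,nfcl->fl", self._xf, dyr)
        g = sfft.irfft(gf, n=L, axis=-1)               # (F, L)
        j0 = T - 1 - self.pl
        self.w.grad += g[:, j0:j0 + self.K].astype(DTYPE)
        if not self.needs_input_grad:
            return np.zeros((N, 1, C, T), dtype=DTYPE)
        wf = sfft.rfft(self.w.value, n=L, axis=-1)     # (F, Lf)
        # dx: true convolution of dy with w, summed over output maps
        dxf = np.einsum("nfcl,fl->ncl", dyf, wf)
        dx = sfft.irfft(dxf, n=L, axis=-1, overwrite_x=True)[..., self.pl:self.pl + T]
        return np.ascontiguousarray(dx[:, None], dtype=DTYPE)


class SpatialDepthwiseConv(Layer):
    """Depthwise C x 1 spatial convolution with depth multiplier D.

    (N, F1, C, T) -> (N, F1*D, 1, T): each kernel spans all C channels, so
    the spatial axis collapses to 1. No bias.
    """

    def __init__(self, f1: int, depth_multiplier: int, n_channels: int,
                 rng: np.random.Generator):
        self.f1, self.D, self.C = f1, depth_multiplier, n_channels
        self.w = Param(glorot_uniform(rng, (f1, depth_multiplier, n_channels),
                                      n_channels, depth_multiplier), "depthwise_spatial.w")

    def params(self) -> List[Param]:
        return [self.w]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        N, F1, C, T = x.shape
        # batch the contraction over feature maps: (F1, D, C) @ (F1, C, N*T)
        xt = np.ascontiguousarray(x.transpose(1, 2, 0, 3)).reshape(F1, C, N * T)
        self._xt, self._NT = xt, (N, T)
        y = self.w.value @ xt                            # (F1, D, N*T)
        y = y.reshape(F1 * self.D, N, T).transpose(1, 0, 2)
        return np.ascontiguousarray(y, dtype=DTYPE)[:, :, None, :]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        N, T = self._NT
        dyt = np.ascontiguousarray(dy[:, :, 0, :].transpose(1, 0, 2))
        dyt = dyt.reshape(self.f1, self.D, N * T)        # (F1, D, N*T)
        self.w.grad += dyt @ self._xt.transpose(0, 2, 1)
        dx = self.w.value.transpose(0, 2, 1) @ dyt       # (F1, C, N*T)
        dx = dx.reshape(self.f1, -1, N, T).transpose(2, 0, 1, 3)
        return np.ascontiguousarray(dx, dtype=DTYPE)


class SeparableConvTime(Layer):
    """1 x K depthwise-temporal conv followed by a 1 x 1 pointwise mix.

    (N, F, C, T) -> (N, F_out, C, T), "same" padding, no biases.
    """

    def __init__(self, n_maps: int, kernel: int, rng: np.random.Generator,
                 n_out: int | None = None):
        self.F = n_maps
        self.K = int(kernel)
        self.Fo = n_out if n_out is not None else n_maps
        self.pl = (self.K - 1) // 2
        self.pr = self.K - 1 - self.pl
        self.wd = Param(glorot_uniform(rng, (self.F, self.K), self.K, self.K),
                        "separable.depthwise.w")
        self.wp = Param(glorot_uniform(rng, (self.Fo, self.F), self.F, self.Fo),
                        "separable.pointwise.w")

    def params(self) -> List[Param]:
        return [self.wd, self.wp]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        N, F, C, T = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (0, 0), (self.pl, self.pr)))
        patches = np.lib.stride_tricks.sliding_window_view(xp, self.K, axis=3)
        self._patches, self._shape = patches, x.shape
        z = np.einsum("nfctk,fk->nfct", patches, self.wd.value, optimize=True)
        self._z = z
        y = np.einsum("nfct,gf->ngct", z, self.wp.value, optimize=True)
        return np.ascontiguousarray(y, dtype=DTYPE)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        N, F, C, T = self._shape
        self.wp.grad += np.einsum("ngct,nfct->gf", dy, self._z, optimize=True)
        dz = np.einsum("ngct,gf->nfct", dy, self.wp.value, optimize=True)
        self.wd.grad += np.einsum("nfctk,nfct->fk", self._patches, dz, optimize=True)
        dxp = np.zeros((N, F, C, T + self.K - 1), dtype=DTYPE)
        w = self.wd.value
        for k in range(self.K):
            dxp[..., k:k + T] += dz * w[:, k][None, :, None, None]
        return np.ascontiguousarray(dxp[..., self.pl:self.pl + T], dtype=DTYPE)


class BatchNorm(Layer):
    """Batch normalization over feature maps (axis 1), affine."""

    def __init__(self, n_features: int, eps: float = 1e-5, momentum: float = 0.1):
        self.eps, self.momentum = eps, momentum
        self.gamma = Param(np.ones(n_features, dtype=DTYPE), "bn.gamma")
        self.beta = Param(np.zeros(n_features, dtype=DTYPE), "bn.beta")
        self.running_mean = np.zeros(n_features, dtype=DTYPE)
        self.running_var = np.ones(n_features, dtype=DTYPE)

    def params(self) -> List[Param]:
        return [self.gamma, self.beta]

    def _bshape(self, x):
        return (1, -1) + (1,) * (x.ndim - 2)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        sh = self._bshape(x)
        axes = (0,) + tuple(range(2, x.ndim))
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            # in-place so external references to the stats stay valid
            self.running_mean *= 1 - self.momentum
            self.running_mean += (self.momentum * mean).astype(DTYPE)
            self.running_var *= 1 - self.momentum
            self.running_var += (self.momentum * var).astype(DTYPE)
        else:
            mean, var = self.running_mean, self.running_var
        ivar = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean.reshape(sh)) * ivar.reshape(sh)
        self._cache = (xhat, ivar, axes, sh, train)
        return (self.gamma.value.reshape(sh) * xhat + self.beta.value.reshape(sh)).astype(DTYPE)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, ivar, axes, sh, train = self._cache
        self.gamma.grad += np.sum(dy * xhat, axis=axes)
        self.beta.grad += np.sum(dy, axis=axes)
        g = self.gamma.value.reshape(sh)
        if not train:
            return (dy * (g * ivar.reshape(sh))).astype(DTYPE)
        # dx = g*ivar * (dy - mean(dy) - xhat * mean(dy*xhat)), means over batch
        m1 = dy.mean(axis=axes, keepdims=True)
        tmp = dy * xhat
        m2 = tmp.mean(axis=axes, keepdims=True)
        np.multiply(xhat, m2, out=tmp)
        tmp += m1
        np.subtract(dy, tmp, out=tmp)
        tmp *= g * ivar.reshape(sh)
        return tmp.astype(DTYPE, copy=False)


class ELU(Layer):
    def __init__(self, alpha: float = 1.0):
        self.alpha = alpha

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        pos = x > 0
        neg = np.minimum(x, 0, dtype=DTYPE)
        np.expm1(neg, out=neg)                      # alpha * (e^x - 1) on x<=0
        if self.alpha != 1.0:
            neg *= self.alpha
        y = np.where(pos, x, neg)
        self._cache = (pos, y)
        return y.astype(DTYPE, copy=False)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        pos, y = self._cache
        dneg = dy * (y + self.alpha)
        return np.where(pos, dy, dneg).astype(DTYPE, copy=False)


class Dropout(Layer):
    """Inverted dropout; identity in eval mode. Draws masks from ``rng``."""

    def __init__(self, p: float, rng: np.random.Generator):
        if not (0 <= p < 1):
            raise ValueError(f"dropout p must be in [0, 1), got {p}")
        self.p, self.rng = p, rng

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if not train or self.p == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape, dtype=np.float32) >= self.p
                      ).astype(DTYPE) / DTYPE(1 - self.p)
        return (x * self._mask).astype(DTYPE)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dy
        return (dy * self._mask).astype(DTYPE)


class AvgPoolTime(Layer):
    """Average pooling 1 x p along the time axis, stride p, floor division."""

    def __init__(self, p: int):
        self.p = int(p)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        N, F, C, T = x.shape
        To = T // self.p
        if To < 1:
            raise ValueError(f"time axis {T} shorter than pool size {self.p}")
        self._T = T
        y = x[..., :To * self.p].reshape(N, F, C, To, self.p).mean(axis=-1)
        return np.ascontiguousarray(y, dtype=DTYPE)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        N, F, C, To = dy.shape
        dx = np.zeros((N, F, C, self._T), dtype=DTYPE)
        dx[..., :To * self.p] = np.repeat(dy / self.p, self.p, axis=-1)
        return dx


class Flatten(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy.reshape(self._shape)


class Linear(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, name: str = "linear"):
        self.w = Param(glorot_uniform(rng, (n_out, n_in), n_in, n_out), f"{name}.w")
        self.b = Param(np.zeros(n_out, dtype=DTYPE), f"{name}.b")

    def params(self) -> List[Param]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x
        return (x @ self.w.value.T + self.b.value).astype(DTYPE)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.w.grad += dy.T @ self._x
        self.b.grad += dy.sum(axis=0)
        return (dy @ self.w.value).astype(DTYPE)


class Sequential(Layer):
    def __init__(self, layers: Sequence[Layer]):
        self.layers = list(layers)

    def params(self) -> List[Param]:
        return [p for l in self.layers for p in l.params()]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        for l in self.layers:
            x = l.forward(x, train)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for l in reversed(self.layers):
            dy = l.backward(dy)
        return dy


# ---------------------------------------------------------------------------
# Losses and optimizer
# ---------------------------------------------------------------------------

def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(probs: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy and the gradient w.r.t. the logits.

    ``labels`` are integer class indices. Returns (loss, dlogits) where the
    gradient already folds in the softmax Jacobian.
    """
    n = probs.shape[0]
    p = np.clip(probs[np.arange(n), labels], 1e-12, None)
    loss = float(-np.mean(np.log(p)))
    dlogits = probs.copy()
    dlogits[np.arange(n), labels] -= 1.0
    return loss, (dlogits / n).astype(DTYPE)


def mse_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean squared error and the gradient w.r.t. the predictions."""
    r = pred - target
    return float(np.mean(r ** 2)), (2.0 * r / r.size).astype(DTYPE)


class Adam:
    def __init__(self, params: Sequence[Param], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def collect_stateful(obj) -> List[np.ndarray]:
    """Flat list of references to every mutable array (params + BN stats)."""
    out: List[np.ndarray] = []

    def visit(l: Layer):
        if isinstance(l, Sequential):
            for sub in l.layers:
                visit(sub)
            return
        for p in l.params():
            out.append(p.value)
        if isinstance(l, BatchNorm):
            out.append(l.running_mean)
            out.append(l.running_var)

    visit(obj)
    return out


def snapshot(layers: Sequence[Layer]) -> List[np.ndarray]:
    out = []
    for l in layers:
        out.extend(a.copy() for a in collect_stateful(l))
    return out


def restore(layers: Sequence[Layer], state: List[np.ndarray]) -> None:
    refs = []
    for l in layers:
        refs.extend(collect_stateful(l))
    if len(refs) != len(state):
        raise ValueError("snapshot does not match the layer stack")
    for r, s in zip(refs, state):
        r[...] = s
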