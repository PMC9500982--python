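"""Numpy execution backend for :class:`~eegcube.architectures.ModelSpec`.

Instantiates a declarative spec as a trainable numpy model: 3D convolution
(stride 1, the only stride the specs use), batch normalization, max pooling
with kernel == stride, dense, ReLU/tanh, inverted dropout, and a
forward-only LSTM.  Backpropagation is hand-written per layer; the suite
checks the gradients against finite differences.

Convolutions run as im2col + GEMM over batch chunks sized to a fixed
memory budget, so large activations never materialise a full patch matrix.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np

from .architectures import LayerSpec, ModelSpec


@dataclass
class Param:
    name: str
    value: np.ndarray
    grad: np.ndarray

    @classmethod
    def zeros_like(cls, name: str, value: np.ndarray) -> "Param":
        return cls(name, value, np.zeros_like(value))


def _kaiming(rng: np.random.Generator, shape: tuple, fan_in: int) -> np.ndarray:
    return rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)


def _orthogonal(rng: np.random.Generator, rows: int, cols: int) -> np.ndarray:
    a = rng.standard_normal((max(rows, cols), min(rows, cols)))
    q, r = np.linalg.qr(a)
    q *= np.sign(np.diag(r))
    return q[:rows, :cols] if q.shape[0] >= rows else q.T[:rows, :cols]


class _Layer:
    params: list[Param]

    def __init__(self):
        self.params = []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


_COLS_BUDGET_BYTES = 128 * 1024 * 1024  # cap on the materialised im2col buffer


class Conv3D(_Layer):
    """Stride-1 3D convolution via chunked im2col + GEMM.

    Patches are materialised for a slice of the batch at a time so the
    column buffer stays within a fixed memory budget regardless of the
    activation size.
    """

    def __init__(self, spec: LayerSpec, rng: np.random.Generator, dtype=np.float64):
        super().__init__()
        if spec.kernel.stride != (1, 1, 1):
            raise NotImplementedError("backend supports stride-1 convolutions only")
        d, kh, kw = spec.kernel.size
        self.pad = spec.kernel.padding
        fan_in = spec.in_channels * d * kh * kw
        self.W = Param.zeros_like(
            "weight",
            _kaiming(rng, (spec.out_channels, spec.in_channels, d, kh, kw), fan_in).astype(dtype),
        )
        self.params = [self.W]
        self.bias = spec.bias
        if self.bias:
            self.b = Param.zeros_like("bias", np.zeros(spec.out_channels, dtype=dtype))
            self.params.append(self.b)
        self.ksize = (d, kh, kw)

    def _offsets(self):
        d, kh, kw = self.ksize
        for dz in range(d):
            for dy in range(kh):
                for dx in range(kw):
                    yield dz, dy, dx

    def _chunk_cols(self, xp: np.ndarray, start: int, stop: int,
                    out_shape: tuple) -> np.ndarray:
        """(C*K, nb*V) patch matrix for a batch slice, channel-major rows.

        Built with one large slab copy per kernel offset; single flat 2D
        GEMMs on this layout are far faster than batched matmuls with tiny
        channel dimensions.
        """
        Do, Ho, Wo = out_shape
        nb = stop - start
        C = xp.shape[1]
        K = self.ksize[0] * self.ksize[1] * self.ksize[2]
        V = Do * Ho * Wo
        cols = np.empty((C, K, nb, V), dtype=xp.dtype)
        for k, (dz, dy, dx) in enumerate(self._offsets()):
            sl = xp[start:stop, :, dz:dz + Do, dy:dy + Ho, dx:dx + Wo]
            cols[:, k] = sl.reshape(nb, C, V).transpose(1, 0, 2)
        return cols.reshape(C * K, nb * V)

    def _chunk_size(self, xp: np.ndarray, out_shape: tuple) -> int:
        Do, Ho, Wo = out_shape
        ck = self.W.value[0].size
        bytes_per_sample = Do * Ho * Wo * ck * xp.dtype.itemsize
        return max(1, _COLS_BUDGET_BYTES // max(1, bytes_per_sample))

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        dtype = self.W.value.dtype
        pd, ph, pw = self.pad
        xp = np.pad(x.astype(dtype, copy=False),
                    ((0, 0), (0, 0), (pd, pd), (ph, ph), (pw, pw)))
        self._xp = xp
        B, C, D, H, W = xp.shape
        d, kh, kw = self.ksize
        Do, Ho, Wo = D - d + 1, H - kh + 1, W - kw + 1
        O = self.W.value.shape[0]
        V = Do * Ho * Wo
        Wmat = self.W.value.reshape(O, -1)
        out = np.empty((B, O, Do, Ho, Wo), dtype=dtype)
        step = self._chunk_size(xp, (Do, Ho, Wo))
        for start in range(0, B, step):
            stop = min(start + step, B)
            nb = stop - start
            cols = self._chunk_cols(xp, start, stop, (Do, Ho, Wo))
            res = Wmat @ cols  # (O, nb*V)
            out[start:stop] = res.reshape(O, nb, Do, Ho, Wo).transpose(1, 0, 2, 3, 4)
        if self.bias:
            out += self.b.value[None, :, None, None, None]
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xp = self._xp
        d, kh, kw = self.ksize
        Do, Ho, Wo = dout.shape[2:]
        B, C = xp.shape[:2]
        O = self.W.value.shape[0]
        K = d * kh * kw
        V = Do * Ho * Wo
        Wmat = self.W.value.reshape(O, C * K)
        dWmat = np.zeros_like(Wmat)
        dxp = np.zeros_like(xp)
        step = self._chunk_size(xp, (Do, Ho, Wo))
        for start in range(0, B, step):
            stop = min(start + step, B)
            nb = stop - start
            cols = self._chunk_cols(xp, start, stop, (Do, Ho, Wo))
            dmat = np.ascontiguousarray(
                dout[start:stop].transpose(1, 0, 2, 3, 4)
            ).reshape(O, nb * V)
            dWmat += dmat @ cols.T
            dcols = (Wmat.T @ dmat).reshape(C, K, nb, V)
            for k, (dz, dy, dx) in enumerate(self._offsets()):
                dxp[start:stop, :, dz:dz + Do, dy:dy + Ho, dx:dx + Wo] += (
                    dcols[:, k].transpose(1, 0, 2).reshape(nb, C, Do, Ho, Wo)
                )
        self.W.grad += dWmat.reshape(self.W.grad.shape)
        if self.bias:
            self.b.grad += dout.sum(axis=(0, 2, 3, 4))
        pd, ph, pw = self.pad
        D, H, W = dxp.shape[2:]
        return dxp[:, :, pd:D - pd or None, ph:H - ph or None, pw:W - pw or None]


class BatchNorm3D(_Layer):
    def __init__(self, spec: LayerSpec, dtype=np.float64, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        c = spec.in_channels
        self.gamma = Param.zeros_like("weight", np.ones(c, dtype=dtype))
        self.beta = Param.zeros_like("bias", np.zeros(c, dtype=dtype))
        self.params = [self.gamma, self.beta]
        self.running_mean = np.zeros(c, dtype=dtype)
        self.running_var = np.ones(c, dtype=dtype)
        self.eps = eps
        self.momentum = momentum

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        axes = (0, 2, 3, 4)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        shape = (1, -1, 1, 1, 1)
        self._inv_std = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mean.reshape(shape)) * self._inv_std.reshape(shape)
        return self.gamma.value.reshape(shape) * self._xhat + self.beta.value.reshape(shape)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        axes = (0, 2, 3, 4)
        shape = (1, -1, 1, 1, 1)
        n = dout.size / dout.shape[1]
        self.gamma.grad += (dout * self._xhat).sum(axis=axes)
        self.beta.grad += dout.sum(axis=axes)
        dxhat = dout * self.gamma.value.reshape(shape)
        dx = (
            dxhat
            - dxhat.mean(axis=axes).reshape(shape)
            - self._xhat * (dxhat * self._xhat).mean(axis=axes).reshape(shape)
        ) * self._inv_std.reshape(shape)
        return dx


class ReLU(_Layer):
    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class Tanh(_Layer):
    def forward(self, x, train):
        self._y = np.tanh(x)
        return self._y

    def backward(self, dout):
        return dout * (1 - self._y ** 2)


class MaxPool3D(_Layer):
    def __init__(self, spec: LayerSpec):
        super().__init__()
        if spec.kernel.size != spec.kernel.stride:
            raise NotImplementedError("backend pools require kernel == stride")
        self.k = spec.kernel.size

    def forward(self, x, train):
        B, C, D, H, W = x.shape
        kd, kh, kw = self.k
        if D % kd or H % kh or W % kw:
            raise ValueError(f"input {x.shape} not divisible by pool {self.k}")
        xr = x.reshape(B, C, D // kd, kd, H // kh, kh, W // kw, kw)
        out = xr.max(axis=(3, 5, 7))
        self._xr = xr
        self._out = out
        return out

    def backward(self, dout):
        xr = self._xr
        mask = xr == self._out[:, :, :, None, :, None, :, None]
        counts = mask.sum(axis=(3, 5, 7), keepdims=True)
        dxr = mask * (dout[:, :, :, None, :, None, :, None] / counts)
        B, C, Dn, kd, Hn, kh, Wn, kw = xr.shape
        return dxr.reshape(B, C, Dn * kd, Hn * kh, Wn * kw)


class Flatten(_Layer):
    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Dense(_Layer):
    def __init__(self, spec: LayerSpec, rng: np.random.Generator, dtype=np.float64):
        super().__init__()
        self.W = Param.zeros_like(
            "weight",
            _kaiming(rng, (spec.out_features, spec.in_features), spec.in_features).astype(dtype),
        )
        self.b = Param.zeros_like("bias", np.zeros(spec.out_features, dtype=dtype))
        self.params = [self.W, self.b]

    def forward(self, x, train):
        self._x = x
        return x @ self.W.value.T + self.b.value

    def backward(self, dout):
        self.W.grad += dout.T @ self._x
        self.b.grad += dout.sum(axis=0)
        return dout @ self.W.value


class Dropout(_Layer):
    def __init__(self, spec: LayerSpec, rng: np.random.Generator):
        super().__init__()
        self.rate = spec.rate
        self.rng = rng

    def forward(self, x, train):
        if not train or self.rate == 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class TakeLast(_Layer):
    def forward(self, x, train):
        self._shape = x.shape
        return x[:, -1, :]

    def backward(self, dout):
        dx = np.zeros(self._shape)
        dx[:, -1, :] = dout
        return dx


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


class LSTM(_Layer):
    """Standard LSTM layer returning the full hidden sequence (forward only)."""

    def __init__(self, spec: LayerSpec, rng: np.random.Generator, dtype=np.float64):
        super().__init__()
        h, n_in = spec.hidden_size, spec.input_size
        self.h = h
        self.W_ih = Param.zeros_like("weight_ih", _kaiming(rng, (4 * h, n_in), n_in).astype(dtype))
        self.W_hh = Param.zeros_like("weight_hh", _orthogonal(rng, 4 * h, h).astype(dtype))
        b_ih = np.zeros(4 * h, dtype=dtype)
        b_ih[h:2 * h] = 1.0  # forget-gate bias
        self.b_ih = Param.zeros_like("bias_ih", b_ih)
        self.b_hh = Param.zeros_like("bias_hh", np.zeros(4 * h, dtype=dtype))
        self.params = [self.W_ih, self.W_hh, self.b_ih, self.b_hh]

    def forward(self, x, train):
        B, T, _ = x.shape
        h = self.h
        ht = np.zeros((B, h))
        ct = np.zeros((B, h))
        out = np.empty((B, T, h))
        for t in range(T):
            gates = x[:, t] @ self.W_ih.value.T + ht @ self.W_hh.value.T
            gates += self.b_ih.value + self.b_hh.value
            i = _sigmoid(gates[:, :h])
            f = _sigmoid(gates[:, h:2 * h])
            g = np.tanh(gates[:, 2 * h:3 * h])
            o = _sigmoid(gates[:, 3 * h:])
            ct = f * ct + i * g
            ht = o * np.tanh(ct)
            out[:, t] = ht
        return out

    def backward(self, dout):
        raise NotImplementedError(
            "LSTM backward is not implemented; the recurrent baseline is "
            "inference/profiling-only in this backend"
        )


_LAYER_FACTORY = {
    "conv3d": lambda spec, rng, dtype: Conv3D(spec, rng, dtype),
    "batchnorm": lambda spec, rng, dtype: BatchNorm3D(spec, dtype),
    "relu": lambda spec, rng, dtype: ReLU(),
    "tanh": lambda spec, rng, dtype: Tanh(),
    "maxpool3d": lambda spec, rng, dtype: MaxPool3D(spec),
    "flatten": lambda spec, rng, dtype: Flatten(),
    "dense": lambda spec, rng, dtype: Dense(spec, rng, dtype),
    "dropout": lambda spec, rng, dtype: Dropout(spec, rng),
    "lstm": lambda spec, rng, dtype: LSTM(spec, rng, dtype),
    "take_last": lambda spec, rng, dtype: TakeLast(),
}


class NumpyModel:
    """A spec instantiated with concrete parameters."""

    def __init__(self, spec: ModelSpec, layers: list[_Layer]):
        self.spec = spec
        self.layers = layers

    @classmethod
    def from_spec(cls, spec: ModelSpec, seed: int = 0, dtype=np.float64) -> "NumpyModel":
        rng = np.random.default_rng(seed)
        layers = [_LAYER_FACTORY[l.kind](l, rng, np.dtype(dtype)) for l in spec.layers]
        return cls(spec, layers)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        d = dlogits
        for layer in reversed(self.layers):
            d = layer.backward(d)
        return d

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0.0

    def parameters(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params]

    def parameter_count(self) -> int:
        return int(sum(p.value.size for p in self.parameters()))

    def checksum(self) -> str:
        h = hashlib.sha256()
        for p in self.parameters():
            h.update(np.ascontiguousarray(p.value).tobytes())
        return h.hexdigest()


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over a batch and its gradient wrt the logits."""
    probs = softmax(logits)
    n = len(labels)
    eps = 1e-12
    loss = -np.log(probs[np.arange(n), labels] + eps).mean()
    dlogits = probs.copy()
    dlogits[np.arange(n), labels] -= 1.0
    return float(loss), dlogits / n


class SGD:
    """Plain SGD with optional momentum and weight decay."""

    def __init__(self, params: list[Param], lr: float, momentum: float = 0.0,
                 weight_decay: float = 0.0):
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self._velocity = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        for p, v in zip(self.params, self._velocity):
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.value
            if self.momentum:
                v *= self.momentum
                v += g
                g = v
            p.value -= self.lr * g
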