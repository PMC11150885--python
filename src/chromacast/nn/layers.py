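"""Neural-network layers with explicit forward/backward passes (numpy, float64).

Convolutional layers act on ``(batch, channels, length)`` arrays, recurrent
layers on ``(batch, time, features)``. Strided convolutions use asymmetric
zero padding of ``kernel − stride`` total so a length-``L`` input maps to
exactly ``L/stride``, and the mirrored transposed convolution maps it back to
exactly ``L`` — no cropping heuristics, the geometry is exact by construction.
"""

from __future__ import annotations

import numpy as np

from chromacast.errors import ConfigError


def conv_padding(kernel: int, stride: int) -> tuple[int, int]:
    """Left/right zero padding for exact ``L → L/stride`` length mapping.

    Total padding is ``kernel − stride``; no valid integer padding exists for
    ``kernel < stride``.
    """
    total = kernel - stride
    if total < 0:
        raise ConfigError(
            f"no integer padding maps length L to L/{stride} with kernel "
            f"{kernel}; choose kernel ≥ step"
        )
    left = total // 2
    return left, total - left


def _glorot(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Layer:
    """Base class: parameters and their gradients live in name-keyed dicts."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv1d(Layer):
    """Strided 1D convolution mapping length ``L`` to ``L/stride`` exactly."""

    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int = 1,
                 rng: np.random.Generator | None = None) -> None:
        super().__init__()
        rng = rng or np.random.default_rng()
        self.c_in, self.c_out, self.kernel, self.stride = c_in, c_out, kernel, stride
        self.pad = conv_padding(kernel, stride)
        fan_in, fan_out = c_in * kernel, c_out * kernel
        self.params["W"] = _glorot(rng, (c_out, c_in, kernel), fan_in, fan_out)
        self.params["b"] = np.zeros(c_out)

    def forward(self, x, train=False, rng=None):
        if x.shape[2] % self.stride:
            raise ConfigError(
                f"input length {x.shape[2]} not divisible by stride {self.stride}"
            )
        pl, pr = self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (pl, pr)))
        # (B, C, Lo, k) windows at multiples of the stride
        cols = np.lib.stride_tricks.sliding_window_view(xp, self.kernel, axis=2)[:, :, ::self.stride, :]
        self._cache = (x.shape, cols)
        out = np.tensordot(cols, self.params["W"], axes=([1, 3], [1, 2]))  # (B, Lo, Cout)
        return out.transpose(0, 2, 1) + self.params["b"][None, :, None]

    def backward(self, dout):
        x_shape, cols = self._cache
        W = self.params["W"]
        self.grads["W"] = np.einsum("bot,bctk->ock", dout, cols)
        self.grads["b"] = dout.sum(axis=(0, 2))
        dcols = np.einsum("bot,ock->bctk", dout, W)
        pl, pr = self.pad
        B, C, L = x_shape
        dxp = np.zeros((B, C, L + pl + pr))
        Lo = dout.shape[2]
        for k in range(self.kernel):
            dxp[:, :, k: k + self.stride * Lo: self.stride] += dcols[:, :, :, k]
        return dxp[:, :, pl: pl + L]


class ConvTranspose1d(Layer):
    """Strided 1D transposed convolution mapping ``L`` to ``L·stride`` exactly."""

    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int = 1,
                 rng: np.random.Generator | None = None) -> None:
        super().__init__()
        rng = rng or np.random.default_rng()
        self.c_in, self.c_out, self.kernel, self.stride = c_in, c_out, kernel, stride
        self.pad = conv_padding(kernel, stride)
        fan_in, fan_out = c_in * kernel, c_out * kernel
        self.params["W"] = _glorot(rng, (c_in, c_out, kernel), fan_in, fan_out)
        self.params["b"] = np.zeros(c_out)

    def forward(self, x, train=False, rng=None):
        B, C, Li = x.shape
        pl, pr = self.pad
        Lfull = (Li - 1) * self.stride + self.kernel
        y = np.einsum("bct,cok->botk", x, self.params["W"])
        outp = np.zeros((B, self.c_out, Lfull))
        for k in range(self.kernel):
            outp[:, :, k: k + self.stride * Li: self.stride] += y[:, :, :, k]
        self._cache = x
        return outp[:, :, pl: Lfull - pr if pr else Lfull] + self.params["b"][None, :, None]

    def backward(self, dout):
        x = self._cache
        B, C, Li = x.shape
        pl, pr = self.pad
        Lfull = (Li - 1) * self.stride + self.kernel
        dfull = np.zeros((B, self.c_out, Lfull))
        dfull[:, :, pl: Lfull - pr if pr else Lfull] = dout
        cols = np.lib.stride_tricks.sliding_window_view(dfull, self.kernel, axis=2)[:, :, ::self.stride, :]
        self.grads["W"] = np.einsum("bct,botk->cok", x, cols)
        self.grads["b"] = dout.sum(axis=(0, 2))
        return np.einsum("botk,cok->bct", cols, self.params["W"])


class ReLU(Layer):
    def forward(self, x, train=False, rng=None):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dout):
        return dout * self._mask


class BatchNorm1d(Layer):
    """Per-channel batch normalisation over batch and length axes."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5) -> None:
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.params["gamma"] = np.ones(channels)
        self.params["beta"] = np.zeros(channels)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)

    def forward(self, x, train=False, rng=None):
        if train:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        std = np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None]) / std[None, :, None]
        self._cache = (xhat, std, train)
        return self.params["gamma"][None, :, None] * xhat + self.params["beta"][None, :, None]

    def backward(self, dout):
        xhat, std, trained = self._cache
        self.grads["gamma"] = np.sum(dout * xhat, axis=(0, 2))
        self.grads["beta"] = dout.sum(axis=(0, 2))
        g_over_std = (self.params["gamma"] / std)[None, :, None]
        if not trained:
            return dout * g_over_std
        n = dout.shape[0] * dout.shape[2]
        mean_dout = dout.mean(axis=(0, 2))[None, :, None]
        mean_dx = np.mean(dout * xhat, axis=(0, 2))[None, :, None]
        return g_over_std * (dout - mean_dout - xhat * mean_dx)


class Dropout(Layer):
    """Inverted dropout; identity in evaluation mode."""

    def __init__(self, p: float) -> None:
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ConfigError(f"dropout probability must be in [0, 1), got {p}")
        self.p = p

    def forward(self, x, train=False, rng=None):
        if not train or self.p == 0.0:
            self._mask = None
            return x
        if rng is None:
            raise ConfigError("dropout in training mode requires an RNG")
        self._mask = (rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class LSTM(Layer):
    """Single-direction LSTM over ``(batch, time, features)``.

    Gate order i, f, g, o; forget-gate bias initialised to 1.
    """

    def __init__(self, d_in: int, hidden: int, rng: np.random.Generator | None = None) -> None:
        super().__init__()
        rng = rng or np.random.default_rng()
        self.d_in, self.hidden = d_in, hidden
        self.params["Wx"] = _glorot(rng, (d_in, 4 * hidden), d_in, hidden)
        self.params["Wh"] = _glorot(rng, (hidden, 4 * hidden), hidden, hidden)
        b = np.zeros(4 * hidden)
        b[hidden: 2 * hidden] = 1.0
        self.params["b"] = b

    def forward(self, x, train=False, rng=None):
        B, T, D = x.shape
        H = self.hidden
        Wx, Wh, b = self.params["Wx"], self.params["Wh"], self.params["b"]
        xW = x @ Wx
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        out = np.empty((B, T, H))
        cache = []
        for t in range(T):
            a = xW[:, t] + h @ Wh + b
            i = _sigmoid(a[:, :H])
            f = _sigmoid(a[:, H: 2 * H])
            g = np.tanh(a[:, 2 * H: 3 * H])
            o = _sigmoid(a[:, 3 * H:])
            c_new = f * c + i * g
            tc = np.tanh(c_new)
            h_new = o * tc
            cache.append((h, c, i, f, g, o, tc))
            h, c = h_new, c_new
            out[:, t] = h
        self._cache = (x, cache)
        return out

    def backward(self, dout):
        x, cache = self._cache
        B, T, D = x.shape
        H = self.hidden
        Wx, Wh = self.params["Wx"], self.params["Wh"]
        dWx = np.zeros_like(Wx)
        dWh = np.zeros_like(Wh)
        db = np.zeros(4 * H)
        dx = np.empty_like(x)
        dh_next = np.zeros((B, H))
        dc_next = np.zeros((B, H))
        for t in range(T - 1, -1, -1):
            h_prev, c_prev, i, f, g, o, tc = cache[t]
            dh = dout[:, t] + dh_next
            do = dh * tc
            dc = dc_next + dh * o * (1.0 - tc * tc)
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            da = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f), dg * (1 - g * g), do * o * (1 - o)],
                axis=1,
            )
            dx[:, t] = da @ Wx.T
            dh_next = da @ Wh.T
            dc_next = dc * f
            dWx += x[:, t].T @ da
            dWh += h_prev.T @ da
            db += da.sum(axis=0)
        self.grads["Wx"], self.grads["Wh"], self.grads["b"] = dWx, dWh, db
        return dx


class BiLSTM(Layer):
    """Bidirectional LSTM: forward and time-reversed passes, features concatenated."""

    def __init__(self, d_in: int, hidden: int, rng: np.random.Generator | None = None) -> None:
        super().__init__()
        rng = rng or np.random.default_rng()
        self.fwd = LSTM(d_in, hidden, rng)
        self.bwd = LSTM(d_in, hidden, rng)
        self.hidden = hidden

    @property
    def sublayers(self):
        return [self.fwd, self.bwd]

    def forward(self, x, train=False, rng=None):
        hf = self.fwd.forward(x, train, rng)
        hb = self.bwd.forward(x[:, ::-1], train, rng)[:, ::-1]
        return np.concatenate([hf, hb], axis=2)

    def backward(self, dout):
        H = self.hidden
        dxf = self.fwd.backward(dout[:, :, :H])
        dxb = self.bwd.backward(dout[:, ::-1, H:])[:, ::-1]
        return dxf + dxb
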