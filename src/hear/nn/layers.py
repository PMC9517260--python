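"""Trainable layers with explicit forward/backward passes.

All layers operate on NumPy arrays and cache what their backward pass
needs. "Grouped" layers hold an independent weight set per group — here a
group is one sensor channel, so the 2 sensors x 9 channels of a recording
get 18 independent per-channel extractors evaluated in a single batched
matmul.

Conventions: parameters live in ``self.params`` (dict name -> array),
gradients accumulate into ``self.grads`` with matching keys; batch-norm
running statistics live in ``self.buffers``. Arrays are updated in place
by the optimizer.
"""

from __future__ import annotations

import numpy as np


def _sigmoid(x: np.ndarray) -> np.ndarray:
    # tanh form: same function, noticeably faster than 1/(1+exp(-x)) here
    return 0.5 * (1.0 + np.tanh(0.5 * x))


def glorot_uniform(rng: np.random.Generator, shape, fan_in, fan_out, dtype):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


def orthogonal(rng: np.random.Generator, n: int, dtype) -> np.ndarray:
    q, r = np.linalg.qr(rng.normal(size=(n, n)))
    return (q * np.sign(np.diag(r))).astype(dtype)


class Layer:
    """Base: parameter/gradient bookkeeping shared by all layers."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self.buffers: dict[str, np.ndarray] = {}

    def zero_grad(self) -> None:
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def param_count(self, include_buffers: bool = True) -> int:
        n = sum(v.size for v in self.params.values())
        if include_buffers:
            n += sum(v.size for v in self.buffers.values())
        return n


class GroupedLSTM(Layer):
    """Per-group LSTM over univariate (or low-dim) sequences.

    Input ``(B, T, G, D)`` -> hidden sequence ``(B, T, G, H)``. Gate order
    i, f, o, g (the three sigmoid gates first, so one vectorized sigmoid
    covers them); forget-gate bias initialized to 1. Each of the G groups
    has its own kernel ``Wx (D, 4H)``, recurrent kernel ``Wh (H, 4H)`` and
    bias.
    """

    def __init__(self, groups: int, in_dim: int, units: int,
                 rng: np.random.Generator, dtype=np.float32) -> None:
        super().__init__()
        self.G, self.D, self.H = groups, in_dim, units
        H = units
        Wx = np.stack([
            glorot_uniform(rng, (in_dim, 4 * H), in_dim, 4 * H, dtype)
            for _ in range(groups)
        ])
        Wh = np.stack([
            np.concatenate([orthogonal(rng, H, dtype) for _ in range(4)], axis=1)
            for _ in range(groups)
        ])
        b = np.zeros((groups, 4 * H), dtype=dtype)
        b[:, H:2 * H] = 1.0  # forget-gate bias
        self.params = {"Wx": Wx, "Wh": Wh, "b": b}
        self.zero_grad()
        self._cache = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        B, T, G, D = x.shape
        H = self.H
        xs = np.ascontiguousarray(x.transpose(1, 2, 0, 3))  # (T, G, B, D)
        Wx, Wh, b = self.params["Wx"], self.params["Wh"], self.params["b"]
        # input contribution for all timesteps at once; only the recurrent
        # part is inherently sequential. matmul with inner dim 1 is a
        # degenerate (slow) GEMM, so the univariate case broadcasts instead.
        if self.D == 1:
            zx = xs * Wx[:, 0, :][:, None, :]  # (T, G, B, 4H)
        else:
            zx = np.matmul(xs, Wx)
        zx += b[None, :, None, :]
        h = np.zeros((G, B, H), dtype=x.dtype)
        c = np.zeros((G, B, H), dtype=x.dtype)
        hs = np.empty((T, G, B, H), dtype=x.dtype)
        cache = []
        for t in range(T):
            z = zx[t] + np.matmul(h, Wh)
            sig = _sigmoid(z[..., :3 * H])
            i = sig[..., :H]
            f = sig[..., H:2 * H]
            o = sig[..., 2 * H:]
            g = np.tanh(z[..., 3 * H:])
            c_prev = c
            c = f * c_prev + i * g
            hc = np.tanh(c)
            h_prev = h
            h = o * hc
            hs[t] = h
            cache.append((xs[t], h_prev, c_prev, i, f, g, o, hc))
        self._cache = cache
        # non-contiguous view; the consumer copies into its own layout
        return hs.transpose(2, 0, 1, 3)  # (B, T, G, H)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        B, T, G, H = dout.shape
        douts = dout.transpose(1, 2, 0, 3)  # (T, G, B, H)
        Wx, Wh = self.params["Wx"], self.params["Wh"]
        WhT = Wh.transpose(0, 2, 1).copy()
        dh_next = np.zeros((G, B, H), dtype=dout.dtype)
        dc_next = np.zeros((G, B, H), dtype=dout.dtype)
        # only dh/dc recurrences are sequential; weight-gradient GEMMs and
        # the input gradient run once over the stacked timesteps below
        dzs = np.empty((T, G, B, 4 * H), dtype=dout.dtype)
        for t in range(T - 1, -1, -1):
            _, _, c_prev, i, f, g, o, hc = self._cache[t]
            dh = douts[t] + dh_next
            do = dh * hc
            dc = dc_next + dh * o * (1.0 - hc * hc)
            dz = dzs[t]
            dz[..., :H] = (dc * g) * i * (1.0 - i)
            dz[..., H:2 * H] = (dc * c_prev) * f * (1.0 - f)
            dz[..., 2 * H:3 * H] = do * o * (1.0 - o)
            dz[..., 3 * H:] = (dc * i) * (1.0 - g * g)
            dh_next = np.matmul(dz, WhT)
            dc_next = dc * f
        xs = np.stack([c[0] for c in self._cache])  # (T, G, B, D)
        hs_prev = np.stack([c[1] for c in self._cache])
        dz_flat = dzs.transpose(1, 0, 2, 3).reshape(G, T * B, 4 * H)
        x_flat = xs.transpose(1, 0, 2, 3).reshape(G, T * B, self.D)
        h_flat = hs_prev.transpose(1, 0, 2, 3).reshape(G, T * B, H)
        self.grads["Wx"] += np.matmul(x_flat.transpose(0, 2, 1), dz_flat)
        self.grads["Wh"] += np.matmul(h_flat.transpose(0, 2, 1), dz_flat)
        self.grads["b"] += dzs.sum(axis=(0, 2))
        if self.D == 1:
            dx = (dzs * Wx[:, 0, :][None, :, None, :]).sum(axis=-1,
                                                           keepdims=True)
        else:
            dx = np.matmul(dzs, Wx.transpose(0, 2, 1))
        self._cache = None
        return np.ascontiguousarray(dx.transpose(2, 0, 1, 3))  # (B, T, G, D)


class GroupedConv1D(Layer):
    """Per-group temporal convolution, 'same' padding, no activation.

    Input ``(B, T, G, Fin)`` -> ``(B, T, G, Fout)`` with kernel ``(G, K,
    Fin, Fout)``; each group (sensor channel) has its own filters.
    """

    def __init__(self, groups: int, in_maps: int, filters: int, kernel: int,
                 rng: np.random.Generator, dtype=np.float32) -> None:
        super().__init__()
        if kernel % 2 != 1:
            raise ValueError("conv1d kernel must be odd for 'same' padding")
        self.G, self.Fin, self.Fout, self.K = groups, in_maps, filters, kernel
        fan_in, fan_out = kernel * in_maps, kernel * filters
        W = np.stack([
            glorot_uniform(rng, (kernel, in_maps, filters), fan_in, fan_out, dtype)
            for _ in range(groups)
        ])
        self.params = {"W": W, "b": np.zeros((groups, filters), dtype=dtype)}
        self.zero_grad()
        self._cache = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        B, T, G, Fin = x.shape
        K = self.K
        pad = K // 2
        xp = np.zeros((G, B, T + 2 * pad, Fin), dtype=x.dtype)
        xp[:, :, pad:pad + T, :] = x.transpose(2, 0, 1, 3)
        W, b = self.params["W"], self.params["b"]
        y = np.zeros((G, B, T, self.Fout), dtype=x.dtype)
        for p in range(K):
            seg = xp[:, :, p:p + T, :].reshape(G, B * T, Fin)
            y += np.matmul(seg, W[:, p]).reshape(G, B, T, self.Fout)
        y += b[:, None, None, :]
        self._cache = (xp, (B, T))
        return np.ascontiguousarray(y.transpose(1, 2, 0, 3))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xp, (B, T) = self._cache
        G, K, Fin, Fout = self.G, self.K, self.Fin, self.Fout
        pad = K // 2
        dy = np.ascontiguousarray(dout.transpose(2, 0, 1, 3))  # (G, B, T, Fout)
        dyf = dy.reshape(G, B * T, Fout)
        W = self.params["W"]
        dW, db = self.grads["W"], self.grads["b"]
        dxp = np.zeros_like(xp)
        for p in range(K):
            seg = xp[:, :, p:p + T, :].reshape(G, B * T, Fin)
            dW[:, p] += np.matmul(seg.transpose(0, 2, 1), dyf)
            dxp[:, :, p:p + T, :] += np.matmul(dyf, W[:, p].transpose(0, 2, 1)
                                               ).reshape(G, B, T, Fin)
        db += dy.sum(axis=(1, 2))
        self._cache = None
        dx = dxp[:, :, pad:pad + T, :]
        return np.ascontiguousarray(dx.transpose(1, 2, 0, 3))


class Conv2D(Layer):
    """2-D convolution with 'same' padding over ``(B, H, W, Cin)`` maps."""

    def __init__(self, in_maps: int, filters: int, kernel: tuple[int, int],
                 rng: np.random.Generator, dtype=np.float32) -> None:
        super().__init__()
        kh, kw = kernel
        if kh % 2 != 1 or kw % 2 != 1:
            raise ValueError("conv2d kernel must be odd for 'same' padding")
        self.Cin, self.Cout, self.kh, self.kw = in_maps, filters, kh, kw
        fan_in, fan_out = kh * kw * in_maps, kh * kw * filters
        self.params = {
            "W": glorot_uniform(rng, (kh, kw, in_maps, filters), fan_in, fan_out, dtype),
            "b": np.zeros(filters, dtype=dtype),
        }
        self.zero_grad()
        self._cache = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        B, H, W_, Cin = x.shape
        ph, pw = self.kh // 2, self.kw // 2
        xp = np.zeros((B, H + 2 * ph, W_ + 2 * pw, Cin), dtype=x.dtype)
        xp[:, ph:ph + H, pw:pw + W_, :] = x
        Wk, b = self.params["W"], self.params["b"]
        y = np.zeros((B, H, W_, self.Cout), dtype=x.dtype)
        for i in range(self.kh):
            for j in range(self.kw):
                seg = xp[:, i:i + H, j:j + W_, :].reshape(-1, Cin)
                if Cin == 1:  # rank-1 GEMM is slow; broadcast instead
                    contrib = seg * Wk[i, j, 0]
                else:
                    contrib = seg @ Wk[i, j]
                y += contrib.reshape(B, H, W_, self.Cout)
        y += b
        self._cache = (xp, (B, H, W_))
        return y

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xp, (B, H, W_) = self._cache
        Cin, Cout = self.Cin, self.Cout
        ph, pw = self.kh // 2, self.kw // 2
        dyf = dout.reshape(-1, Cout)
        Wk = self.params["W"]
        dW, db = self.grads["W"], self.grads["b"]
        dxp = np.zeros_like(xp)
        for i in range(self.kh):
            for j in range(self.kw):
                seg = xp[:, i:i + H, j:j + W_, :].reshape(-1, Cin)
                dW[i, j] += seg.T @ dyf
                dxp[:, i:i + H, j:j + W_, :] += (dyf @ Wk[i, j].T).reshape(
                    B, H, W_, Cin)
        db += dout.sum(axis=(0, 1, 2))
        self._cache = None
        return dxp[:, ph:ph + H, pw:pw + W_, :]


class BatchNorm(Layer):
    """Batch normalization over the given reduction axes.

    ``channel_shape`` is the trailing shape of the per-feature statistics
    (e.g. ``(G, F)`` for grouped temporal maps, ``(C,)`` for 2-D maps);
    ``axes`` are the batch/spatial axes normalized over. Running statistics
    (momentum 0.9) are used in inference mode.
    """

    def __init__(self, channel_shape: tuple[int, ...], axes: tuple[int, ...],
                 dtype=np.float32, eps: float = 1e-3, momentum: float = 0.9) -> None:
        super().__init__()
        self.axes = axes
        self.eps = eps
        self.momentum = momentum
        self.params = {
            "gamma": np.ones(channel_shape, dtype=dtype),
            "beta": np.zeros(channel_shape, dtype=dtype),
        }
        self.buffers = {
            "running_mean": np.zeros(channel_shape, dtype=dtype),
            "running_var": np.ones(channel_shape, dtype=dtype),
        }
        self.zero_grad()
        self._cache = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        gamma, beta = self.params["gamma"], self.params["beta"]
        if training:
            mu = x.mean(axis=self.axes)
            var = x.var(axis=self.axes)
            m = self.momentum
            self.buffers["running_mean"] *= m
            self.buffers["running_mean"] += (1 - m) * mu.astype(
                self.buffers["running_mean"].dtype)
            self.buffers["running_var"] *= m
            self.buffers["running_var"] += (1 - m) * var.astype(
                self.buffers["running_var"].dtype)
        else:
            mu = self.buffers["running_mean"]
            var = self.buffers["running_var"]
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv_std
        if training:
            self._cache = (xhat, inv_std)
        return gamma * xhat + beta

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv_std = self._cache
        gamma = self.params["gamma"]
        n = int(np.prod([dout.shape[a] for a in self.axes]))
        self.grads["gamma"] += (dout * xhat).sum(axis=self.axes)
        self.grads["beta"] += dout.sum(axis=self.axes)
        dxhat = dout * gamma
        s1 = dxhat.sum(axis=self.axes, keepdims=True)
        s2 = (dxhat * xhat).sum(axis=self.axes, keepdims=True)
        self._cache = None
        return (inv_std / n) * (n * dxhat - s1 - xhat * s2)


class MaxPool1D(Layer):
    """Temporal max pooling (floor mode) over axis 1 of ``(B, T, G, F)``."""

    def __init__(self, size: int = 2) -> None:
        super().__init__()
        self.size = size
        self._cache = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        B, T, G, F = x.shape
        To = T // self.size
        if self.size == 2:
            a = x[:, 0 : To * 2 : 2]
            b = x[:, 1 : To * 2 : 2]
            out = np.maximum(a, b)
            self._cache = (a >= b, x.shape)
            return out
        xv = x[:, : To * self.size].reshape(B, To, self.size, G, F)
        idx = xv.argmax(axis=2)
        out = np.take_along_axis(xv, idx[:, :, None], axis=2)[:, :, 0]
        self._cache = (idx, x.shape)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cache, shape = self._cache
        B, T, G, F = shape
        To = dout.shape[1]
        dx = np.zeros(shape, dtype=dout.dtype)
        self._cache = None
        if self.size == 2:
            first = cache
            contrib = dout * first
            dx[:, 0 : To * 2 : 2] = contrib
            dx[:, 1 : To * 2 : 2] = dout - contrib
            return dx
        idx = cache
        dxv = np.zeros((B, To, self.size, G, F), dtype=dout.dtype)
        np.put_along_axis(dxv, idx[:, :, None], dout[:, :, None], axis=2)
        dx[:, : To * self.size] = dxv.reshape(B, To * self.size, G, F)
        return dx


class MaxPool2D(Layer):
    """2x2 spatial max pooling on ``(B, H, W, C)``; floor or ceil mode.

    Ceil mode pads odd extents with -inf so the last partial cell is kept
    (7 -> 4); floor mode truncates (14 -> 7 is exact). The winner of each
    cell is recovered in the backward pass by pairwise comparisons (ties
    break toward the earlier position).
    """

    def __init__(self, size: tuple[int, int] = (2, 2), ceil_mode: bool = False) -> None:
        super().__init__()
        if size != (2, 2):
            raise ValueError("only 2x2 pooling is supported")
        self.sh, self.sw = size
        self.ceil_mode = ceil_mode
        self._cache = None

    def _out_extent(self, n: int, s: int) -> int:
        return -(-n // s) if self.ceil_mode else n // s

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        B, H, W, C = x.shape
        Ho, Wo = self._out_extent(H, self.sh), self._out_extent(W, self.sw)
        Hp, Wp = Ho * self.sh, Wo * self.sw
        if (Hp, Wp) != (H, W):
            xp = np.full((B, Hp, Wp, C), -np.inf, dtype=x.dtype)
            xp[:, :H, :W] = x[:, :Hp, :Wp]
        else:
            xp = x
        a = xp[:, 0::2, 0::2, :]
        b = xp[:, 0::2, 1::2, :]
        c = xp[:, 1::2, 0::2, :]
        d = xp[:, 1::2, 1::2, :]
        m_ab = np.maximum(a, b)
        m_cd = np.maximum(c, d)
        out = np.maximum(m_ab, m_cd)
        self._cache = ((a, b, c, d, m_ab), x.shape, (Hp, Wp))
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        (a, b, c, d, m_ab), shape, (Hp, Wp) = self._cache
        B, H, W, C = shape
        top = m_ab >= np.maximum(c, d)  # winner in the top row?
        ab = a >= b
        cd = c >= d
        dxp = np.empty((B, Hp, Wp, C), dtype=dout.dtype)
        dtop = dout * top
        dbot = dout - dtop
        dxp[:, 0::2, 0::2, :] = dtop * ab
        dxp[:, 0::2, 1::2, :] = dtop * ~ab
        dxp[:, 1::2, 0::2, :] = dbot * cd
        dxp[:, 1::2, 1::2, :] = dbot * ~cd
        self._cache = None
        if (Hp, Wp) != (H, W):
            return dxp[:, :H, :W]
        return dxp


class Dense(Layer):
    """Fully connected layer ``(B, Din) -> (B, Dout)``."""

    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator,
                 dtype=np.float32) -> None:
        super().__init__()
        self.params = {
            "W": glorot_uniform(rng, (in_dim, out_dim), in_dim, out_dim, dtype),
            "b": np.zeros(out_dim, dtype=dtype),
        }
        self.zero_grad()
        self._cache = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._cache = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x = self._cache
        self.grads["W"] += x.T @ dout
        self.grads["b"] += dout.sum(axis=0)
        self._cache = None
        return dout @ self.params["W"].T


class ReLU(Layer):
    def __init__(self) -> None:
        super().__init__()
        self._cache = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._cache = x > 0
        return np.maximum(x, 0.0)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        mask = self._cache
        self._cache = None
        return dout * mask


class Dropout(Layer):
    """Inverted dropout; identity in inference mode."""

    def __init__(self, rate: float, rng: np.random.Generator) -> None:
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng
        self._cache = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if not training or self.rate == 0.0:
            self._cache = None
            return x
        keep = 1.0 - self.rate
        mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        self._cache = mask
        return x * mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self._cache is None:
            return dout
        mask = self._cache
        self._cache = None
        return dout * mask
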