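"""Minimal numpy neural-network core: layers with explicit backprop.

Layers operate on channels-first batches ``(N, C, L)`` for sequence layers and
``(N, F)`` after flattening.  Every layer exposes ``params``/``grads`` dicts
keyed by parameter name, a ``forward(x, train)`` and a ``backward(dy)``.
Weight initialization is Glorot-uniform from a caller-supplied
``numpy.random.Generator`` so model construction is fully seeded.

The layer set is exactly what the m6A backbones need: 1-D convolution, group
normalization, ELU, bidirectional LSTM, learned position embedding, a single
transformer encoder block (2-head self-attention + position-wise feed-forward
with residuals and layer norm), 1-D max pooling, dense, dropout.  Gradient
correctness is enforced by numeric-differentiation tests.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer",
    "Conv1D",
    "GroupNorm",
    "ELU",
    "BiLSTM",
    "MaxPool1D",
    "Flatten",
    "Dense",
    "Dropout",
    "PositionEmbedding",
    "TransformerBlock",
    "Sequential",
    "SGD",
    "glorot",
    "softmax",
]


def glorot(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Layer:
    """Base layer; stateless layers leave params empty."""

    def __init__(self, name: str):
        self.name = name
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def n_params(self) -> int:
        return sum(p.size for p in self.params.values())


class Conv1D(Layer):
    """Valid (no padding) 1-D convolution, channels-first."""

    def __init__(self, name: str, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator):
        super().__init__(name)
        fan_in, fan_out = in_ch * kernel, out_ch * kernel
        self.kernel = kernel
        self.params["W"] = glorot(rng, (out_ch, in_ch, kernel), fan_in, fan_out)
        self.params["b"] = np.zeros(out_ch)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        # x: (N, C, L) -> windows (N, C, L', K)
        self._win = np.lib.stride_tricks.sliding_window_view(x, self.kernel, axis=2)
        self._in_shape = x.shape
        y = np.einsum("nclk,ock->nol", self._win, self.params["W"], optimize=True)
        return y + self.params["b"][None, :, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        W = self.params["W"]
        K = self.kernel
        N, O, Lp = dy.shape
        _, C, L = self._in_shape
        self.grads["W"] = np.einsum("nclk,nol->ock", self._win, dy, optimize=True)
        self.grads["b"] = dy.sum(axis=(0, 2))
        # col2im: per-window input gradients, then scatter-add over offsets
        G = (dy.transpose(0, 2, 1).reshape(N * Lp, O) @ W.reshape(O, C * K))
        G = G.reshape(N, Lp, C, K).transpose(0, 2, 1, 3)  # (N, C, L', K)
        dx = np.zeros(self._in_shape)
        for k in range(K):
            dx[:, :, k : k + Lp] += G[:, :, :, k]
        return dx


class GroupNorm(Layer):
    """Group normalization over (channel-group x length) per sample."""

    def __init__(self, name: str, channels: int, groups: int, eps: float = 1e-5):
        super().__init__(name)
        if channels % groups != 0:
            raise ValueError(f"groups ({groups}) must divide channels ({channels})")
        self.groups = groups
        self.eps = eps
        self.params["gamma"] = np.ones(channels)
        self.params["beta"] = np.zeros(channels)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        N, C, L = x.shape
        g = self.groups
        xg = x.reshape(N, g, C // g, L)
        mu = xg.mean(axis=(2, 3), keepdims=True)
        var = xg.var(axis=(2, 3), keepdims=True)
        self._std = np.sqrt(var + self.eps)
        self._xhat = ((xg - mu) / self._std).reshape(N, C, L)
        return self._xhat * self.params["gamma"][None, :, None] + self.params["beta"][None, :, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        N, C, L = dy.shape
        g = self.groups
        self.grads["gamma"] = (dy * self._xhat).sum(axis=(0, 2))
        self.grads["beta"] = dy.sum(axis=(0, 2))
        dxhat = (dy * self.params["gamma"][None, :, None]).reshape(N, g, C // g, L)
        xhat = self._xhat.reshape(N, g, C // g, L)
        m1 = dxhat.mean(axis=(2, 3), keepdims=True)
        m2 = (dxhat * xhat).mean(axis=(2, 3), keepdims=True)
        dx = (dxhat - m1 - xhat * m2) / self._std
        return dx.reshape(N, C, L)


class ELU(Layer):
    def __init__(self, name: str = "elu", alpha: float = 1.0):
        super().__init__(name)
        self.alpha = alpha

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._y = np.where(x > 0, x, self.alpha * (np.expm1(x)))
        self._pos = x > 0
        return self._y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * np.where(self._pos, 1.0, self._y + self.alpha)


def _lstm_forward_py(xw: np.ndarray, Wh: np.ndarray):
    """Reference LSTM recurrence; gates ordered [input, forget, output, cell].

    xw is the precomputed input contribution x @ Wx + b of shape (N, L, 4H).
    Returns (post-activation gates (N,L,4H), cell states (N,L,H),
    hidden states incl. h0 (N,L+1,H)).
    """
    N, L, H4 = xw.shape
    H = H4 // 4
    gates = np.empty((N, L, H4))
    c_all = np.empty((N, L, H))
    h_all = np.zeros((N, L + 1, H))
    c = np.zeros((N, H))
    for t in range(L):
        z = xw[:, t] + h_all[:, t] @ Wh
        sig = _sigmoid(z[:, : 3 * H])
        i, f, o = sig[:, :H], sig[:, H : 2 * H], sig[:, 2 * H :]
        g = np.tanh(z[:, 3 * H :])
        c = f * c + i * g
        gates[:, t, : 3 * H] = sig
        gates[:, t, 3 * H :] = g
        c_all[:, t] = c
        h_all[:, t + 1] = o * np.tanh(c)
    return gates, c_all, h_all


def _lstm_backward_py(gates: np.ndarray, c_all: np.ndarray, Wh: np.ndarray,
                      dout: np.ndarray) -> np.ndarray:
    """Backprop through the recurrence; returns dZ (N, L, 4H) wrt pre-activation
    gate inputs."""
    N, L, H = dout.shape
    dZ = np.empty((N, L, 4 * H))
    dh = np.zeros((N, H))
    dc = np.zeros((N, H))
    WhT = np.ascontiguousarray(Wh.T)
    for t in range(L - 1, -1, -1):
        i = gates[:, t, :H]
        f = gates[:, t, H : 2 * H]
        o = gates[:, t, 2 * H : 3 * H]
        g = gates[:, t, 3 * H :]
        tc = np.tanh(c_all[:, t])
        dhv = dh + dout[:, t]
        dcv = dc + dhv * o * (1.0 - tc * tc)
        c_prev = c_all[:, t - 1] if t > 0 else 0.0
        dZ[:, t, :H] = dcv * g * i * (1.0 - i)
        dZ[:, t, H : 2 * H] = dcv * c_prev * f * (1.0 - f)
        dZ[:, t, 2 * H : 3 * H] = dhv * tc * o * (1.0 - o)
        dZ[:, t, 3 * H :] = dcv * i * (1.0 - g * g)
        dh = dZ[:, t] @ WhT
        dc = dcv * f
    return dZ


try:  # numba JIT of the recurrences (the only sequential hot loop)
    from numba import njit

    @njit(cache=True)
    def _lstm_forward_nb(xw, Wh):  # pragma: no cover - exercised via wrapper
        N, L, H4 = xw.shape
        H = H4 // 4
        gates = np.empty((N, L, H4))
        c_all = np.empty((N, L, H))
        h_all = np.zeros((N, L + 1, H))
        for t in range(L):
            z = xw[:, t].copy()
            z += np.dot(h_all[:, t].copy(), Wh)
            for n in range(N):
                for k in range(H):
                    i = 1.0 / (1.0 + np.exp(-z[n, k]))
                    f = 1.0 / (1.0 + np.exp(-z[n, H + k]))
                    o = 1.0 / (1.0 + np.exp(-z[n, 2 * H + k]))
                    g = np.tanh(z[n, 3 * H + k])
                    cp = c_all[n, t - 1, k] if t > 0 else 0.0
                    cc = f * cp + i * g
                    gates[n, t, k] = i
                    gates[n, t, H + k] = f
                    gates[n, t, 2 * H + k] = o
                    gates[n, t, 3 * H + k] = g
                    c_all[n, t, k] = cc
                    h_all[n, t + 1, k] = o * np.tanh(cc)
        return gates, c_all, h_all

    @njit(cache=True)
    def _lstm_backward_nb(gates, c_all, Wh, dout):  # pragma: no cover
        N, L, H = dout.shape
        dZ = np.empty((N, L, 4 * H))
        dh = np.zeros((N, H))
        dc = np.zeros((N, H))
        WhT = Wh.T.copy()
        for t in range(L - 1, -1, -1):
            for n in range(N):
                for k in range(H):
                    i = gates[n, t, k]
                    f = gates[n, t, H + k]
                    o = gates[n, t, 2 * H + k]
                    g = gates[n, t, 3 * H + k]
                    tc = np.tanh(c_all[n, t, k])
                    dhv = dh[n, k] + dout[n, t, k]
                    dcv = dc[n, k] + dhv * o * (1.0 - tc * tc)
                    cp = c_all[n, t - 1, k] if t > 0 else 0.0
                    dZ[n, t, k] = dcv * g * i * (1.0 - i)
                    dZ[n, t, H + k] = dcv * cp * f * (1.0 - f)
                    dZ[n, t, 2 * H + k] = dhv * tc * o * (1.0 - o)
                    dZ[n, t, 3 * H + k] = dcv * i * (1.0 - g * g)
                    dc[n, k] = dcv * f
            dh = np.dot(dZ[:, t].copy(), WhT)
        return dZ

    _lstm_forward = _lstm_forward_nb
    _lstm_backward = _lstm_backward_nb
except ImportError:  # pragma: no cover
    _lstm_forward = _lstm_forward_py
    _lstm_backward = _lstm_backward_py


class _LSTMDirection:
    """One direction of an LSTM; gates ordered [input, forget, output, cell]."""

    def __init__(self, in_ch: int, hidden: int, rng: np.random.Generator):
        self.H = hidden
        self.Wx = glorot(rng, (in_ch, 4 * hidden), in_ch, 4 * hidden)
        self.Wh = glorot(rng, (hidden, 4 * hidden), hidden, 4 * hidden)
        self.b = np.zeros(4 * hidden)
        self.b[hidden : 2 * hidden] = 1.0  # forget-gate bias

    def forward(self, x: np.ndarray) -> np.ndarray:
        # x: (N, L, C), time along axis 1 (already reversed for the backward
        # direction by the caller)
        self._x = x
        xw = x @ self.Wx + self.b  # (N, L, 4H)
        self._gates, self._c, self._h_all = _lstm_forward(
            np.ascontiguousarray(xw), self.Wh
        )
        return self._h_all[:, 1:]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dZ = _lstm_backward(self._gates, self._c, self.Wh,
                            np.ascontiguousarray(dout))
        self.dWx = np.einsum("nlc,nlz->cz", self._x, dZ, optimize=True)
        self.dWh = np.einsum("nlh,nlz->hz", self._h_all[:, :-1], dZ, optimize=True)
        self.db = dZ.sum(axis=(0, 1))
        return dZ @ self.Wx.T  # (N, L, C)


class BiLSTM(Layer):
    """Bidirectional LSTM returning the full output sequence.

    Input/output are channels-first: (N, C, L) -> (N, 2H, L), forward-direction
    channels first, then backward-direction channels.
    """

    def __init__(self, name: str, in_ch: int, hidden: int, rng: np.random.Generator):
        super().__init__(name)
        self.fwd = _LSTMDirection(in_ch, hidden, rng)
        self.bwd = _LSTMDirection(in_ch, hidden, rng)
        for tag, d in (("fwd", self.fwd), ("bwd", self.bwd)):
            self.params[f"{tag}_Wx"] = d.Wx
            self.params[f"{tag}_Wh"] = d.Wh
            self.params[f"{tag}_b"] = d.b

    def _sync_in(self) -> None:
        # params dict is the source of truth (optimizer/transfer mutate it)
        for tag, d in (("fwd", self.fwd), ("bwd", self.bwd)):
            d.Wx = self.params[f"{tag}_Wx"]
            d.Wh = self.params[f"{tag}_Wh"]
            d.b = self.params[f"{tag}_b"]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._sync_in()
        xt = np.ascontiguousarray(x.transpose(0, 2, 1))  # (N, L, C)
        hf = self.fwd.forward(xt)
        hb = self.bwd.forward(xt[:, ::-1])[:, ::-1]
        return np.concatenate([hf, hb], axis=2).transpose(0, 2, 1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        H = self.fwd.H
        dyt = dy.transpose(0, 2, 1)  # (N, L, 2H)
        dxf = self.fwd.backward(np.ascontiguousarray(dyt[:, :, :H]))
        dxb = self.bwd.backward(np.ascontiguousarray(dyt[:, ::-1, H:]))[:, ::-1]
        for tag, d in (("fwd", self.fwd), ("bwd", self.bwd)):
            self.grads[f"{tag}_Wx"] = d.dWx
            self.grads[f"{tag}_Wh"] = d.dWh
            self.grads[f"{tag}_b"] = d.db
        return (dxf + dxb).transpose(0, 2, 1)


class MaxPool1D(Layer):
    """Non-overlapping max pooling along the length axis; remainder dropped."""

    def __init__(self, name: str, pool: int):
        super().__init__(name)
        if pool < 1:
            raise ValueError("pool size must be >= 1")
        self.pool = pool

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        N, C, L = x.shape
        P = self.pool
        Lp = L // P
        if Lp == 0:
            raise ValueError(f"length {L} shorter than pool size {P}")
        xr = x[:, :, : Lp * P].reshape(N, C, Lp, P)
        self._arg = xr.argmax(axis=3)
        self._in_shape = x.shape
        return xr.max(axis=3)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        N, C, Lp = dy.shape
        P = self.pool
        dx = np.zeros(self._in_shape)
        dxr = dx[:, :, : Lp * P].reshape(N, C, Lp, P)
        n, c, l = np.ogrid[:N, :C, :Lp]
        dxr[n, c, l, self._arg] = dy
        return dx


class Flatten(Layer):
    def __init__(self, name: str = "flatten"):
        super().__init__(name)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy.reshape(self._shape)


class Dense(Layer):
    def __init__(self, name: str, in_f: int, out_f: int, rng: np.random.Generator):
        super().__init__(name)
        self.params["W"] = glorot(rng, (in_f, out_f), in_f, out_f)
        self.params["b"] = np.zeros(out_f)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.grads["W"] = self._x.T @ dy
        self.grads["b"] = dy.sum(axis=0)
        return dy @ self.params["W"].T


class Dropout(Layer):
    """Inverted dropout; identity at inference. Owns a seeded RNG stream."""

    def __init__(self, name: str, rate: float, seed: int):
        super().__init__(name)
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = np.random.default_rng(seed)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy if self._mask is None else dy * self._mask


class PositionEmbedding(Layer):
    """Learned additive position embedding for a fixed sequence length."""

    def __init__(self, name: str, channels: int, length: int, rng: np.random.Generator):
        super().__init__(name)
        self.params["E"] = rng.normal(0.0, 0.02, size=(channels, length))

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if x.shape[1:] != self.params["E"].shape:
            raise ValueError(
                f"position embedding shape {self.params['E'].shape} does not match input {x.shape[1:]}"
            )
        return x + self.params["E"][None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.grads["E"] = dy.sum(axis=0)
        return dy


class _LayerNormOp:
    """Channel-wise layer norm used inside the transformer block (not a
    standalone Layer; parameters live on the owning block)."""

    def __init__(self, channels: int, eps: float = 1e-5):
        self.gamma = np.ones(channels)
        self.beta = np.zeros(channels)
        self.eps = eps

    def forward(self, x: np.ndarray) -> np.ndarray:
        mu = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mu) / self._std
        return self._xhat * self.gamma + self.beta

    def backward(self, dy: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        dgamma = (dy * self._xhat).sum(axis=tuple(range(dy.ndim - 1)))
        dbeta = dy.sum(axis=tuple(range(dy.ndim - 1)))
        dxhat = dy * self.gamma
        m1 = dxhat.mean(axis=-1, keepdims=True)
        m2 = (dxhat * self._xhat).mean(axis=-1, keepdims=True)
        dx = (dxhat - m1 - self._xhat * m2) / self._std
        return dx, dgamma, dbeta


class TransformerBlock(Layer):
    """One transformer encoder block: multi-head self-attention + position-wise
    feed-forward, each with residual connection and layer normalization.

    Channels-first interface (N, C, L); internally (N, L, C).
    """

    def __init__(self, name: str, channels: int, heads: int, ff_dim: int, rng: np.random.Generator):
        super().__init__(name)
        if channels % heads != 0:
            raise ValueError("heads must divide channels")
        self.heads = heads
        self.dh = channels // heads
        C = channels
        for w in ("Wq", "Wk", "Wv", "Wo"):
            self.params[w] = glorot(rng, (C, C), C, C)
            self.params[w.replace("W", "b")] = np.zeros(C)
        self.params["Wf1"] = glorot(rng, (C, ff_dim), C, ff_dim)
        self.params["bf1"] = np.zeros(ff_dim)
        self.params["Wf2"] = glorot(rng, (ff_dim, C), ff_dim, C)
        self.params["bf2"] = np.zeros(C)
        self.ln1 = _LayerNormOp(C)
        self.ln2 = _LayerNormOp(C)
        self.params["ln1_gamma"] = self.ln1.gamma
        self.params["ln1_beta"] = self.ln1.beta
        self.params["ln2_gamma"] = self.ln2.gamma
        self.params["ln2_beta"] = self.ln2.beta
        self._elu = ELU()

    def _split(self, x: np.ndarray) -> np.ndarray:
        N, L, C = x.shape
        return x.reshape(N, L, self.heads, self.dh).transpose(0, 2, 1, 3)  # (N,h,L,dh)

    def _merge(self, x: np.ndarray) -> np.ndarray:
        N, h, L, dh = x.shape
        return x.transpose(0, 2, 1, 3).reshape(N, L, h * dh)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self.ln1.gamma = self.params["ln1_gamma"]
        self.ln1.beta = self.params["ln1_beta"]
        self.ln2.gamma = self.params["ln2_gamma"]
        self.ln2.beta = self.params["ln2_beta"]
        p = self.params
        xt = x.transpose(0, 2, 1)  # (N, L, C)
        self._xt = xt
        Q = xt @ p["Wq"] + p["bq"]
        K = xt @ p["Wk"] + p["bk"]
        V = xt @ p["Wv"] + p["bv"]
        Qh, Kh, Vh = self._split(Q), self._split(K), self._split(V)
        scores = Qh @ Kh.transpose(0, 1, 3, 2) / np.sqrt(self.dh)
        A = softmax(scores, axis=-1)  # (N,h,L,L)
        ctx = A @ Vh
        merged = self._merge(ctx)
        att = merged @ p["Wo"] + p["bo"]
        self._cache_att = (Qh, Kh, Vh, A, merged)
        y1 = self.ln1.forward(xt + att)
        self._y1 = y1
        f1 = y1 @ p["Wf1"] + p["bf1"]
        f1a = self._elu.forward(f1)
        self._f1a = f1a
        ff = f1a @ p["Wf2"] + p["bf2"]
        y2 = self.ln2.forward(y1 + ff)
        return y2.transpose(0, 2, 1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        p = self.params
        dyt = dy.transpose(0, 2, 1)  # (N, L, C)
        dz2, dg2, db2 = self.ln2.backward(dyt)
        self.grads["ln2_gamma"] = dg2
        self.grads["ln2_beta"] = db2
        # feed-forward branch
        dff = dz2
        self.grads["Wf2"] = np.einsum("nlf,nlc->fc", self._f1a, dff, optimize=True)
        self.grads["bf2"] = dff.sum(axis=(0, 1))
        df1a = dff @ p["Wf2"].T
        df1 = self._elu.backward(df1a)
        self.grads["Wf1"] = np.einsum("nlc,nlf->cf", self._y1, df1, optimize=True)
        self.grads["bf1"] = df1.sum(axis=(0, 1))
        dy1 = dz2 + df1 @ p["Wf1"].T
        dz1, dg1, db1 = self.ln1.backward(dy1)
        self.grads["ln1_gamma"] = dg1
        self.grads["ln1_beta"] = db1
        # attention branch
        datt = dz1
        Qh, Kh, Vh, A, merged = self._cache_att
        self.grads["Wo"] = np.einsum("nlc,nld->cd", merged, datt, optimize=True)
        self.grads["bo"] = datt.sum(axis=(0, 1))
        dmerged = datt @ p["Wo"].T
        dctx = self._split(dmerged)
        dA = dctx @ Vh.transpose(0, 1, 3, 2)
        dVh = A.transpose(0, 1, 3, 2) @ dctx
        dscores = A * (dA - (dA * A).sum(axis=-1, keepdims=True))
        dscores /= np.sqrt(self.dh)
        dQh = dscores @ Kh
        dKh = dscores.transpose(0, 1, 3, 2) @ Qh
        dQ, dK, dV = self._merge(dQh), self._merge(dKh), self._merge(dVh)
        xt = self._xt
        dxt = dz1.copy()  # residual
        for W, b, dmat in (("Wq", "bq", dQ), ("Wk", "bk", dK), ("Wv", "bv", dV)):
            self.grads[W] = np.einsum("nlc,nld->cd", xt, dmat, optimize=True)
            self.grads[b] = dmat.sum(axis=(0, 1))
            dxt += dmat @ p[W].T
        return dxt.transpose(0, 2, 1)


class Sequential:
    """A simple stack of layers with a shared parameter namespace."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def named_params(self) -> dict[str, np.ndarray]:
        out = {}
        for layer in self.layers:
            for k, v in layer.params.items():
                out[f"{layer.name}.{k}"] = v
        return out

    def named_grads(self) -> dict[str, np.ndarray]:
        out = {}
        for layer in self.layers:
            for k, v in layer.grads.items():
                out[f"{layer.name}.{k}"] = v
        return out


class SGD:
    """Stochastic gradient descent with classical momentum."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 0.01, momentum: float = 0.9):
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self.velocity = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, grads: dict[str, np.ndarray]) -> None:
        for k, p in self.params.items():
            g = grads.get(k)
            if g is None:
                continue
            v = self.velocity[k]
            v *= self.momentum
            v -= self.lr * g
            p += v
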