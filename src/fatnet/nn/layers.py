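"""Neural network building blocks on top of the autodiff engine.

Shapes follow the time-last-feature convention used throughout the
package: sequence inputs are ``(batch, T, channels)`` and vector inputs
``(batch, features)``.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, _sigmoid, gelu, softmax

DTYPE = np.float32


class RNGRef:
    """Shared mutable reference to a numpy Generator (for dropout masks)."""

    def __init__(self, rng: np.random.Generator | None = None):
        self.rng = rng if rng is not None else np.random.default_rng(0)


class Module:
    """Tiny nn.Module analogue: parameter discovery + train/eval mode."""

    def __init__(self):
        self.training = True

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        seen: set[int] = set()
        for v in self.__dict__.values():
            self._collect(v, params, seen)
        return params

    @staticmethod
    def _collect(v, params, seen):
        if isinstance(v, Tensor) and v.requires_grad and id(v) not in seen:
            seen.add(id(v))
            params.append(v)
        elif isinstance(v, Module):
            for p in v.parameters():
                if id(p) not in seen:
                    seen.add(id(p))
                    params.append(p)
        elif isinstance(v, (list, tuple)):
            for item in v:
                Module._collect(item, params, seen)

    def modules(self):
        yield self
        for v in self.__dict__.values():
            items = v if isinstance(v, (list, tuple)) else [v]
            for item in items:
                if isinstance(item, Module):
                    yield from item.modules()

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def _buffer_modules(self):
        return [m for m in self.modules() if hasattr(m, "running_mean")]

    def state_dict(self) -> list[np.ndarray]:
        arrays = [p.data.copy() for p in self.parameters()]
        for m in self._buffer_modules():  # BatchNorm running statistics
            arrays += [m.running_mean.copy(), m.running_var.copy()]
        return arrays

    def load_state_dict(self, state: list[np.ndarray]) -> None:
        params = self.parameters()
        bufmods = self._buffer_modules()
        if len(params) + 2 * len(bufmods) != len(state):
            raise ValueError("state size mismatch")
        for p, s in zip(params, state):
            p.data = s.copy().astype(p.data.dtype)
        for i, m in enumerate(bufmods):
            m.running_mean = state[len(params) + 2 * i].copy()
            m.running_var = state[len(params) + 2 * i + 1].copy()


def _glorot(rng, fan_in, fan_out, shape=None, dtype=DTYPE):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    shape = (fan_in, fan_out) if shape is None else shape
    return Tensor(rng.uniform(-limit, limit, size=shape).astype(dtype),
                  requires_grad=True)


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        super().__init__()
        self.W = _glorot(rng, d_in, d_out)
        self.b = Tensor(np.zeros(d_out, dtype=DTYPE), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b


class Dropout(Module):
    def __init__(self, p: float, rng_ref: RNGRef):
        super().__init__()
        self.p = float(p)
        self.rng_ref = rng_ref

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.p <= 0.0:
            return x
        keep = 1.0 - self.p
        mask = (self.rng_ref.rng.random(x.shape) < keep).astype(x.data.dtype) / keep
        return x * Tensor(mask)


class LayerNorm(Module):
    """Layer normalization over the trailing axis (fused forward/backward)."""

    def __init__(self, d: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones(d, dtype=DTYPE), requires_grad=True)
        self.beta = Tensor(np.zeros(d, dtype=DTYPE), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        xd = x.data
        mu = xd.mean(axis=-1, keepdims=True)
        xc = xd - mu
        var = (xc ** 2).mean(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = xc * inv
        out_data = xhat * self.gamma.data + self.beta.data
        gamma, beta = self.gamma, self.beta
        d = xd.shape[-1]

        def bwd(g):
            if gamma.requires_grad:
                red = tuple(range(g.ndim - 1))
                gamma._accum((g * xhat).sum(axis=red))
                beta._accum(g.sum(axis=red))
            if x.requires_grad:
                gx = g * gamma.data
                term = gx - gx.mean(axis=-1, keepdims=True) \
                    - xhat * (gx * xhat).mean(axis=-1, keepdims=True)
                x._accum(term * inv)

        return x._make(out_data, (x, gamma, beta), bwd)


class BatchNorm1d(Module):
    """Batch normalization for (batch, features) inputs with running stats."""

    def __init__(self, d: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones(d, dtype=DTYPE), requires_grad=True)
        self.beta = Tensor(np.zeros(d, dtype=DTYPE), requires_grad=True)
        self.running_mean = np.zeros(d, dtype=np.float64)
        self.running_var = np.ones(d, dtype=np.float64)
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        xd = x.data
        if self.training:
            mu = xd.mean(axis=0)
            var = xd.var(axis=0)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mu
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mu = self.running_mean.astype(xd.dtype)
            var = self.running_var.astype(xd.dtype)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (xd - mu) * inv
        out_data = xhat * self.gamma.data + self.beta.data
        gamma, beta, training = self.gamma, self.beta, self.training
        n = xd.shape[0]

        def bwd(g):
            if gamma.requires_grad:
                gamma._accum((g * xhat).sum(axis=0))
                beta._accum(g.sum(axis=0))
            if x.requires_grad:
                gx = g * gamma.data
                if training:
                    term = gx - gx.mean(axis=0) - xhat * (gx * xhat).mean(axis=0)
                    x._accum(term * inv)
                else:
                    x._accum(gx * inv)

        return x._make(out_data, (x, gamma, beta), bwd)


class Conv1d(Module):
    """1-D convolution over (batch, T, C_in), stride 1, length-preserving.

    'Same' symmetric padding by default; with ``causal=True`` all
    padding goes to the left so output t only sees inputs ≤ t.
    Supports dilation.  Implemented as im2col + GEMM; odd kernel sizes
    only (as used here).
    """

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator,
                 dilation: int = 1, causal: bool = False):
        super().__init__()
        if kernel % 2 != 1:
            raise ValueError("Conv1d supports odd kernel sizes")
        self.kernel = kernel
        self.c_in = c_in
        self.c_out = c_out
        self.dilation = int(dilation)
        self.causal = causal
        self.W = _glorot(rng, c_in * kernel, c_out)
        self.b = Tensor(np.zeros(c_out, dtype=DTYPE), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        B, T, C = x.shape
        if T < self.kernel:
            raise ValueError(f"sequence length {T} shorter than kernel {self.kernel}")
        k, dil = self.kernel, self.dilation
        span = (k - 1) * dil
        if self.causal:
            pad_l, pad_r = span, 0
        else:
            pad_l = pad_r = span // 2
        xd = np.pad(x.data, ((0, 0), (pad_l, pad_r), (0, 0)))
        # im2col: (B, T, k*C)
        col = np.stack([xd[:, j * dil:j * dil + T, :] for j in range(k)],
                       axis=2).reshape(B, T, k * C)
        out_data = col @ self.W.data.reshape(k * C, self.c_out) + self.b.data
        W, b = self.W, self.b

        def bwd(g):
            g2 = g.reshape(B * T, self.c_out)
            if W.requires_grad:
                W._accum(col.reshape(B * T, k * C).T @ g2)
                b._accum(g2.sum(axis=0))
            if x.requires_grad:
                dcol = (g2 @ W.data.reshape(k * C, self.c_out).T).reshape(B, T, k, C)
                dxp = np.zeros_like(xd)
                for j in range(k):
                    dxp[:, j * dil:j * dil + T, :] += dcol[:, :, j, :]
                x._accum(dxp[:, pad_l:pad_l + T, :])

        return x._make(out_data, (x, W, b), bwd)


class LSTM(Module):
    """Unidirectional LSTM returning the full hidden sequence (B, T, H).

    The whole time loop is a single fused autodiff node; gate
    activations are cached for the standard reverse-time backward pass.
    """

    def __init__(self, d_in: int, hidden: int, rng: np.random.Generator,
                 reverse: bool = False):
        super().__init__()
        self.hidden = hidden
        self.reverse = reverse
        s = 1.0 / np.sqrt(hidden)
        self.Wx = Tensor(rng.uniform(-s, s, size=(d_in, 4 * hidden)).astype(DTYPE),
                         requires_grad=True)
        self.Wh = Tensor(rng.uniform(-s, s, size=(hidden, 4 * hidden)).astype(DTYPE),
                         requires_grad=True)
        self.b = Tensor(np.zeros(4 * hidden, dtype=DTYPE), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        B, T, _ = x.shape
        H = self.hidden
        xd = x.data[:, ::-1, :] if self.reverse else x.data
        Wx, Wh, b = self.Wx, self.Wh, self.b
        pre_x = xd @ Wx.data + b.data  # (B, T, 4H) input part, precomputed
        gates = np.empty((B, T, 4 * H), dtype=xd.dtype)
        cs = np.empty((B, T, H), dtype=xd.dtype)
        tanhc = np.empty((B, T, H), dtype=xd.dtype)
        hs = np.empty((B, T, H), dtype=xd.dtype)
        h = np.zeros((B, H), dtype=xd.dtype)
        c = np.zeros((B, H), dtype=xd.dtype)
        for t in range(T):
            pre = pre_x[:, t, :] + h @ Wh.data
            i = _sigmoid(pre[:, :H])
            f = _sigmoid(pre[:, H:2 * H])
            gg = np.tanh(pre[:, 2 * H:3 * H])
            o = _sigmoid(pre[:, 3 * H:])
            c = f * c + i * gg
            tc = np.tanh(c)
            h = o * tc
            gates[:, t, :H] = i
            gates[:, t, H:2 * H] = f
            gates[:, t, 2 * H:3 * H] = gg
            gates[:, t, 3 * H:] = o
            cs[:, t] = c
            tanhc[:, t] = tc
            hs[:, t] = h
        out_data = hs[:, ::-1, :] if self.reverse else hs
        reverse = self.reverse

        def bwd(g):
            gh = g[:, ::-1, :] if reverse else g
            dWx = np.zeros_like(Wx.data)
            dWh = np.zeros_like(Wh.data)
            db = np.zeros_like(b.data)
            dx = np.zeros_like(xd) if x.requires_grad else None
            dh_next = np.zeros((B, H), dtype=xd.dtype)
            dc_next = np.zeros((B, H), dtype=xd.dtype)
            dpre = np.empty((B, 4 * H), dtype=xd.dtype)
            for t in range(T - 1, -1, -1):
                i = gates[:, t, :H]
                f = gates[:, t, H:2 * H]
                gg = gates[:, t, 2 * H:3 * H]
                o = gates[:, t, 3 * H:]
                tc = tanhc[:, t]
                c_prev = cs[:, t - 1] if t > 0 else np.zeros((B, H), dtype=xd.dtype)
                h_prev = hs[:, t - 1] if t > 0 else np.zeros((B, H), dtype=xd.dtype)
                dh = gh[:, t] + dh_next
                dc = dc_next + dh * o * (1.0 - tc ** 2)
                dpre[:, :H] = dc * gg * i * (1 - i)
                dpre[:, H:2 * H] = dc * c_prev * f * (1 - f)
                dpre[:, 2 * H:3 * H] = dc * i * (1 - gg ** 2)
                dpre[:, 3 * H:] = dh * tc * o * (1 - o)
                dWx += xd[:, t].T @ dpre
                dWh += h_prev.T @ dpre
                db += dpre.sum(axis=0)
                dh_next = dpre @ Wh.data.T
                dc_next = dc * f
                if dx is not None:
                    dx[:, t] = dpre @ Wx.data.T
            Wx._accum(dWx)
            Wh._accum(dWh)
            b._accum(db)
            if dx is not None:
                x._accum(dx[:, ::-1, :] if reverse else dx)

        return x._make(out_data, (x, Wx, Wh, b), bwd)


class BiLSTM(Module):
    """Bidirectional LSTM with hidden size h/2 per direction → (B, T, h)."""

    def __init__(self, d_in: int, h: int, rng: np.random.Generator):
        super().__init__()
        if h % 2 != 0:
            raise ValueError("BiLSTM output width h must be even")
        self.fwd = LSTM(d_in, h // 2, rng)
        self.bwd = LSTM(d_in, h // 2, rng, reverse=True)

    def __call__(self, x: Tensor) -> Tensor:
        from .autodiff import concat
        return concat([self.fwd(x), self.bwd(x)], axis=-1)


def _sdpa(q: Tensor, k: Tensor, v: Tensor, n_heads: int,
          weights_sink: list | None = None) -> Tensor:
    """Fused multi-head scaled-dot-product attention core.

    Inputs are post-projection (B, T, h) tensors; the head split,
    softmax, context and merge run as one autodiff node with a
    hand-derived backward pass (checked against finite differences).
    """
    B, Tq, h = q.shape
    Tk = k.shape[1]
    dh = h // n_heads

    def split(x):  # (B, T, h) -> (B, nh, T, dh), contiguous
        return np.ascontiguousarray(
            x.reshape(B, -1, n_heads, dh).transpose(0, 2, 1, 3))

    qh, kh, vh = split(q.data), split(k.data), split(v.data)
    scale = 1.0 / np.sqrt(dh)
    scores = np.matmul(qh, kh.swapaxes(-1, -2))
    scores *= scale
    scores -= scores.max(axis=-1, keepdims=True)
    np.exp(scores, out=scores)
    scores /= scores.sum(axis=-1, keepdims=True)
    attn = scores                                     # (B, nh, Tq, Tk)
    if weights_sink is not None:
        weights_sink.append(attn.copy())
    ctx = np.matmul(attn, vh)                         # (B, nh, Tq, dh)
    out_data = np.ascontiguousarray(ctx.transpose(0, 2, 1, 3)).reshape(B, Tq, h)

    def bwd(g):
        dctx = np.ascontiguousarray(
            g.reshape(B, Tq, n_heads, dh).transpose(0, 2, 1, 3))
        if v.requires_grad:
            dvh = np.matmul(attn.swapaxes(-1, -2), dctx)
            v._accum(np.ascontiguousarray(dvh.transpose(0, 2, 1, 3))
                     .reshape(B, Tk, h))
        dattn = np.matmul(dctx, vh.swapaxes(-1, -2))
        dscore = attn * (dattn - (dattn * attn).sum(axis=-1, keepdims=True))
        dscore *= scale
        if q.requires_grad:
            dqh = np.matmul(dscore, kh)
            q._accum(np.ascontiguousarray(dqh.transpose(0, 2, 1, 3))
                     .reshape(B, Tq, h))
        if k.requires_grad:
            dkh = np.matmul(dscore.swapaxes(-1, -2), qh)
            k._accum(np.ascontiguousarray(dkh.transpose(0, 2, 1, 3))
                     .reshape(B, Tk, h))

    req = q.requires_grad or k.requires_grad or v.requires_grad
    return Tensor(out_data, requires_grad=req,
                  parents=[t for t in (q, k, v) if t.requires_grad],
                  backward=bwd if req else None)


class MultiHeadAttention(Module):
    """Scaled dot-product multi-head attention.

    Query/key/value inputs are (B, Tq, h)/(B, Tk, h)/(B, Tk, h); the
    output is (B, Tq, h).  The (detached) attention weights of the last
    call are kept on ``last_weights`` with shape (B, n_heads, Tq, Tk).
    """

    def __init__(self, h: int, n_heads: int, rng: np.random.Generator):
        super().__init__()
        if h % n_heads != 0:
            raise ValueError("n_heads must divide the embedding width h")
        self.h = h
        self.n_heads = n_heads
        self.d_head = h // n_heads
        self.Wq = Linear(h, h, rng)
        self.Wk = Linear(h, h, rng)
        self.Wv = Linear(h, h, rng)
        self.Wo = Linear(h, h, rng)
        self.last_weights: np.ndarray | None = None

    def __call__(self, q: Tensor, k: Tensor, v: Tensor) -> Tensor:
        sink: list = []
        out = _sdpa(self.Wq(q), self.Wk(k), self.Wv(v), self.n_heads,
                    weights_sink=sink)
        self.last_weights = sink[0]
        return self.Wo(out)


__all__ = [
    "Module", "RNGRef", "Linear", "Dropout", "LayerNorm", "BatchNorm1d",
    "Conv1d", "LSTM", "BiLSTM", "MultiHeadAttention", "gelu", "softmax",
    "Tensor", "DTYPE",
]
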