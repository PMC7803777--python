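"""Convolutional recurrent network for segment classification.

The classifier scores a *segment* — 21 consecutive binarized motion images —
with a scratch probability.  Architecturally it is a time-distributed
convolutional encoder (three conv+maxpool blocks with shared weights applied
to every frame), a two-layer LSTM that integrates the 21 per-frame feature
vectors, and a five-layer fully connected head ending in a sigmoid.

All layers are implemented directly on numpy (float32) with hand-derived
backward passes; there is no external deep-learning framework behind this
module.  Convolutions are evaluated as im2col matrix products, chunked over
frames to bound peak memory.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "ModelSpec",
    "CRNN",
    "WeightState",
    "build_model",
    "shape_plan",
    "param_count",
    "save_weights",
    "load_weights",
]

_F32 = np.float32

# ---------------------------------------------------------------------------
# Model specification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelSpec:
    """Hyperparameters of the network.

    Defaults reproduce the full-scale detector: 21-frame segments of
    200x200 single-channel images, three conv blocks of 32 3x3 filters
    (stride 1, same padding, ReLU) each followed by 2x2/2x2 max pooling,
    two 256-unit LSTM layers, and a dense head of widths 128/128/32/8/1
    with 20% dropout on the first two dense layers.
    """

    input_px: int = 200
    seq_len: int = 21
    conv_filters: tuple[int, ...] = (32, 32, 32)
    conv_kernel: int = 3
    lstm_units: int = 256
    lstm_layers: int = 2
    lstm_activation: str = "relu"  # cell activation; "tanh" is the saturating escape hatch
    head_widths: tuple[int, ...] = (128, 128, 32, 8, 1)
    dropout: float = 0.2
    n_dropout_layers: int = 2  # dropout applied after the first k dense layers

    def validate(self) -> None:
        if self.input_px < 2 ** len(self.conv_filters):
            raise ValueError(
                f"input_px={self.input_px} too small for "
                f"{len(self.conv_filters)} pooling halvings"
            )
        if self.input_px % (2 ** len(self.conv_filters)) != 0:
            raise ValueError(
                f"input_px={self.input_px} must be divisible by "
                f"{2 ** len(self.conv_filters)} so pooling halves exactly"
            )
        if self.seq_len < 1:
            raise ValueError(f"seq_len={self.seq_len} must be >= 1")
        if self.head_widths[-1] != 1:
            raise ValueError(
                f"head_widths last entry must be 1, got {self.head_widths[-1]}"
            )
        if self.lstm_activation not in ("relu", "tanh"):
            raise ValueError(f"lstm_activation must be 'relu' or 'tanh', got {self.lstm_activation!r}")
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError(f"dropout={self.dropout} must be in [0, 1)")
        if self.conv_kernel % 2 != 1:
            raise ValueError(f"conv_kernel={self.conv_kernel} must be odd (same padding)")
        if self.lstm_layers < 1:
            raise ValueError(f"lstm_layers={self.lstm_layers} must be >= 1")

    # -- derived shapes ----------------------------------------------------

    def conv_output_px(self) -> int:
        return self.input_px // (2 ** len(self.conv_filters))

    def frame_feature_len(self) -> int:
        return self.conv_output_px() ** 2 * self.conv_filters[-1]

    def fingerprint(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def shape_plan(spec: ModelSpec) -> list[tuple[str, tuple[int, ...]]]:
    """Per-layer output shapes, input to output.

    Per-frame shapes are (H, W, C); post-flatten shapes are feature vectors.
    """
    spec.validate()
    plan: list[tuple[str, tuple[int, ...]]] = []
    px = spec.input_px
    plan.append(("input", (spec.seq_len, px, px, 1)))
    for i, f in enumerate(spec.conv_filters, start=1):
        plan.append((f"conv{i}", (px, px, f)))
        px //= 2
        plan.append((f"pool{i}", (px, px, f)))
    plan.append(("flatten", (px * px * spec.conv_filters[-1],)))
    for i in range(1, spec.lstm_layers + 1):
        shape = (spec.seq_len, spec.lstm_units) if i < spec.lstm_layers else (spec.lstm_units,)
        plan.append((f"lstm{i}", shape))
    for i, w in enumerate(spec.head_widths, start=1):
        plan.append((f"fc{i}", (w,)))
    return plan


def param_count(spec: ModelSpec) -> int:
    """Number of learnable scalars, computed from the spec alone."""
    spec.validate()
    total = 0
    c_in = 1
    for f in spec.conv_filters:
        total += spec.conv_kernel**2 * c_in * f + f
        c_in = f
    d = spec.frame_feature_len()
    h = spec.lstm_units
    for _ in range(spec.lstm_layers):
        total += (d * 4 * h) + (h * 4 * h) + 4 * h
        d = h
    w_in = spec.lstm_units
    for w in spec.head_widths:
        total += w_in * w + w
        w_in = w
    return total


# ---------------------------------------------------------------------------
# Initializers
# ---------------------------------------------------------------------------


def _glorot_uniform(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(_F32)


def _orthogonal(rng: np.random.Generator, rows: int, cols: int) -> np.ndarray:
    a = rng.standard_normal((max(rows, cols), min(rows, cols)))
    q, r = np.linalg.qr(a)
    q *= np.sign(np.diag(r))
    if rows < cols:
        q = q.T
    return np.ascontiguousarray(q[:rows, :cols], dtype=_F32)


# ---------------------------------------------------------------------------
# Layers (NHWC, float32, explicit backward)
# ---------------------------------------------------------------------------

_CONV_CHUNK = 128  # frames per im2col block; bounds peak memory


class _Param:
    __slots__ = ("value", "grad", "m", "v")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)
        self.m = None  # Adam state, lazily allocated
        self.v = None


class _Workspace:
    """Reusable named buffers; avoids re-allocating large arrays per step."""

    def __init__(self):
        self._bufs: dict[str, np.ndarray] = {}

    def get(self, name: str, shape: tuple[int, ...], dtype=None) -> np.ndarray:
        if dtype is None:
            dtype = _F32
        buf = self._bufs.get(name)
        if buf is None or buf.shape != shape or buf.dtype != dtype:
            buf = np.empty(shape, dtype=dtype)
            self._bufs[name] = buf
        return buf


def _im2col(x: np.ndarray, k: int, out: np.ndarray) -> np.ndarray:
    """Gather kxk same-padded patches of (n, H, W, C) into out (n*H*W, k*k*C)."""
    n, h, w, c = x.shape
    p = k // 2
    xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
    v = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(1, 2))
    # v: (n, H, W, C, ky, kx) -> (n, H, W, ky, kx, C)
    dst = out.reshape(n, h, w, k, k, c)
    np.copyto(dst, v.transpose(0, 1, 2, 4, 5, 3))
    return out


class _ConvPoolReLU:
    """Fused block: 3x3 same conv -> 2x2/2 max pool -> ReLU.

    Pooling before the rectifier is exactly equivalent to the conventional
    conv-relu-pool order because max commutes with a monotone function;
    fusing them keeps the cached activations at pooled resolution.
    Convolution runs as chunked im2col matrix products on persistent
    workspace buffers.  Pool-gradient ties split evenly among tied inputs.
    """

    def __init__(self, rng, c_in: int, c_out: int, k: int, first: bool):
        self.k, self.c_in, self.c_out = k, c_in, c_out
        self.first = first  # first block skips the input gradient
        fan_in = k * k * c_in
        self.W = _Param(_glorot_uniform(rng, fan_in, k * k * c_out, (k * k * c_in, c_out)))
        self.b = _Param(np.zeros(c_out, dtype=_F32))
        self.ws = _Workspace()
        self._x = None
        self._conv = None
        self._out = None

    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, h, w, _ = x.shape
        k = self.k
        conv = self.ws.get("conv", (n, h, w, self.c_out))
        for s in range(0, n, _CONV_CHUNK):
            blk = x[s : s + _CONV_CHUNK]
            m = blk.shape[0]
            cols = self.ws.get("cols", (_CONV_CHUNK * h * w, k * k * self.c_in))
            cols_m = _im2col(blk, k, cols[: m * h * w])
            np.matmul(cols_m, self.W.value, out=conv[s : s + _CONV_CHUNK].reshape(m * h * w, self.c_out))
        conv += self.b.value
        h2, w2 = h // 2, w // 2
        out = self.ws.get("out", (n, h2, w2, self.c_out))
        v5 = conv.reshape(n, h2, 2, w2, 2, self.c_out)
        np.max(v5, axis=(2, 4), out=out)
        np.maximum(out, 0.0, out=out)  # relu, in place
        if train:
            self._x = x
            self._conv = conv
            self._out = out
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray | None:
        x, conv, out = self._x, self._conv, self._out
        n, h, w, _ = x.shape
        h2, w2 = h // 2, w // 2
        k = self.k
        co = self.c_out
        # relu gradient at pooled resolution (out is post-relu)
        g = self.ws.get("g", (n, h2, w2, co))
        np.multiply(dout, out > 0, out=g)
        # unpool with tie-splitting
        v5 = conv.reshape(n, h2, 2, w2, 2, co)
        ob = out.reshape(n, h2, 1, w2, 1, co)
        mask = self.ws.get("mask", (n, h2, 2, w2, 2, co), dtype=bool)
        np.equal(v5, ob, out=mask)
        cnt = mask.sum(axis=(2, 4), dtype=_F32)
        np.maximum(cnt, 1.0, out=cnt)  # negative pooled max -> no tie, g is 0 there anyway
        np.divide(g, cnt, out=g)
        dconv = self.ws.get("dconv", (n, h, w, co))
        dc5 = dconv.reshape(n, h2, 2, w2, 2, co)
        np.multiply(mask, g.reshape(n, h2, 1, w2, 1, co), out=dc5)

        self.b.grad += dconv.sum(axis=(0, 1, 2))
        dW = np.zeros_like(self.W.value)
        if not self.first:
            dx = self.ws.get("dx", x.shape)
            Wr = np.ascontiguousarray(
                self.W.value.reshape(k, k, self.c_in, co)[::-1, ::-1]
                .transpose(0, 1, 3, 2)
                .reshape(k * k * co, self.c_in)
            )
        for s in range(0, n, _CONV_CHUNK):
            blk_x = x[s : s + _CONV_CHUNK]
            blk_d = dconv[s : s + _CONV_CHUNK]
            m = blk_x.shape[0]
            cols = self.ws.get("cols", (_CONV_CHUNK * h * w, k * k * self.c_in))
            cols_m = _im2col(blk_x, k, cols[: m * h * w])
            dW += cols_m.T @ blk_d.reshape(m * h * w, co)
            if not self.first:
                dcols = self.ws.get("dcols", (_CONV_CHUNK * h * w, k * k * co))
                dcols_m = _im2col(blk_d, k, dcols[: m * h * w])
                np.matmul(dcols_m, Wr, out=dx[s : s + _CONV_CHUNK].reshape(m * h * w, self.c_in))
        self.W.grad += dW
        self._x = self._conv = self._out = None
        return None if self.first else dx


class _ReLU:
    """Plain rectifier for the dense head."""

    def __init__(self):
        self._mask = None

    def params(self):
        return []

    def forward(self, x, train):
        out = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, dout):
        dx = dout * self._mask
        self._mask = None
        return dx


class _Dense:
    def __init__(self, rng, d_in: int, d_out: int):
        self.W = _Param(_glorot_uniform(rng, d_in, d_out, (d_in, d_out)))
        self.b = _Param(np.zeros(d_out, dtype=_F32))
        self._x = None

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train):
        if train:
            self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, dout):
        self.W.grad += self._x.T @ dout
        self.b.grad += dout.sum(axis=0)
        dx = dout @ self.W.value.T
        self._x = None
        return dx


class _Dropout:
    """Inverted dropout; identity outside training."""

    def __init__(self, rate: float):
        self.rate = rate
        self._mask = None
        self.rng: np.random.Generator | None = None

    def params(self):
        return []

    def forward(self, x, train):
        if not train or self.rate == 0.0:
            return x
        if self.rng is None:
            self.rng = np.random.default_rng()
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(_F32) / _F32(keep)
        return x * self._mask

    def backward(self, dout):
        if self._mask is None:
            return dout
        dx = dout * self._mask
        self._mask = None
        return dx


def _sigmoid(z):
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class _LSTM:
    """Single LSTM layer over (N, T, D) inputs; gate order i, f, g, o.

    The cell activation (applied to the candidate g and to the cell state
    before the output gate) is configurable: ReLU or tanh.  Recurrent
    weights are orthogonally initialized, the forget-gate bias starts at 1.
    """

    def __init__(self, rng, d_in: int, units: int, activation: str, return_sequences: bool):
        h = units
        self.units = h
        self.activation = activation
        self.return_sequences = return_sequences
        self.Wx = _Param(_glorot_uniform(rng, d_in, 4 * h, (d_in, 4 * h)))
        self.Wh = _Param(_orthogonal(rng, h, 4 * h))
        b = np.zeros(4 * h, dtype=_F32)
        b[h : 2 * h] = 1.0  # forget bias
        self.b = _Param(b)
        self._cache = None

    def params(self):
        return [self.Wx, self.Wh, self.b]

    def _act(self, z):
        return np.maximum(z, 0.0) if self.activation == "relu" else np.tanh(z)

    def _act_grad(self, z, a):
        # a = act(z)
        return (z > 0).astype(_F32) if self.activation == "relu" else 1.0 - a * a

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, T, d = x.shape
        h = self.units
        hs = np.zeros((T, n, h), dtype=_F32)
        cs = np.zeros((T, n, h), dtype=_F32)
        gates = np.empty((T, n, 4 * h), dtype=_F32) if train else None
        zg_all = np.empty((T, n, h), dtype=_F32) if train else None
        h_t = np.zeros((n, h), dtype=_F32)
        c_t = np.zeros((n, h), dtype=_F32)
        xW = x.reshape(n * T, d) @ self.Wx.value + self.b.value
        xW = xW.reshape(n, T, 4 * h)
        for t in range(T):
            z = xW[:, t] + h_t @ self.Wh.value
            i = _sigmoid(z[:, :h])
            f = _sigmoid(z[:, h : 2 * h])
            zg = z[:, 2 * h : 3 * h]
            g = self._act(zg)
            o = _sigmoid(z[:, 3 * h :])
            c_t = f * c_t + i * g
            h_t = o * self._act(c_t)
            hs[t] = h_t
            cs[t] = c_t
            if train:
                gates[t, :, :h] = i
                gates[t, :, h : 2 * h] = f
                gates[t, :, 2 * h : 3 * h] = g
                gates[t, :, 3 * h :] = o
                zg_all[t] = zg
        if train:
            self._cache = (x, hs, cs, gates, zg_all)
        if self.return_sequences:
            return hs.transpose(1, 0, 2).copy()
        return hs[-1].copy()

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x, hs, cs, gates, zg_all = self._cache
        n, T, d = x.shape
        h = self.units
        if self.return_sequences:
            dh_seq = dout.transpose(1, 0, 2)
        else:
            dh_seq = None
        dWx, dWh, db = (
            np.zeros_like(self.Wx.value),
            np.zeros_like(self.Wh.value),
            np.zeros_like(self.b.value),
        )
        dz_all = np.empty((T, n, 4 * h), dtype=_F32)
        dh = np.zeros((n, h), dtype=_F32)
        dc = np.zeros((n, h), dtype=_F32)
        if not self.return_sequences:
            dh = dout.astype(_F32).copy()
        for t in range(T - 1, -1, -1):
            if self.return_sequences:
                dh = dh + dh_seq[t]
            i = gates[t, :, :h]
            f = gates[t, :, h : 2 * h]
            g = gates[t, :, 2 * h : 3 * h]
            o = gates[t, :, 3 * h :]
            c_t = cs[t]
            ac = self._act(c_t)
            dc = dc + dh * o * self._act_grad(c_t, ac)
            c_prev = cs[t - 1] if t > 0 else np.zeros_like(c_t)
            do = dh * ac * o * (1.0 - o)
            di = dc * g * i * (1.0 - i)
            df = dc * c_prev * f * (1.0 - f)
            dg = dc * i * self._act_grad(zg_all[t], g)
            dz = dz_all[t]
            dz[:, :h] = di
            dz[:, h : 2 * h] = df
            dz[:, 2 * h : 3 * h] = dg
            dz[:, 3 * h :] = do
            dh = dz @ self.Wh.value.T
            if t > 0:
                dWh += hs[t - 1].T @ dz
            dc = dc * f
        dz_flat = dz_all.transpose(1, 0, 2).reshape(n * T, 4 * h)
        dWx = x.reshape(n * T, d).T @ dz_flat
        db = dz_flat.sum(axis=0)
        dx = (dz_flat @ self.Wx.value.T).reshape(n, T, d)
        self.Wx.grad += dWx
        self.Wh.grad += dWh
        self.b.grad += db
        self._cache = None
        return dx


# ---------------------------------------------------------------------------
# The model
# ---------------------------------------------------------------------------

_PROB_EPS = _F32(1e-6)


class CRNN:
    """Segment classifier: shared conv encoder -> stacked LSTM -> dense head.

    Inputs are float32 arrays of shape (batch, seq_len, px, px) with values
    in [0, 1].  ``forward`` returns one probability per segment, strictly
    inside (0, 1).
    """

    def __init__(self, spec: ModelSpec, seed: int):
        spec.validate()
        self.spec = spec
        self.seed = seed
        rng = np.random.default_rng(seed)
        self.conv_layers: list = []
        c_in = 1
        for bi, f in enumerate(spec.conv_filters):
            self.conv_layers.append(
                _ConvPoolReLU(rng, c_in, f, spec.conv_kernel, first=(bi == 0))
            )
            c_in = f
        d = spec.frame_feature_len()
        self.lstm_layers: list[_LSTM] = []
        for li in range(spec.lstm_layers):
            last = li == spec.lstm_layers - 1
            self.lstm_layers.append(
                _LSTM(rng, d, spec.lstm_units, spec.lstm_activation, return_sequences=not last)
            )
            d = spec.lstm_units
        self.head: list = []
        w_in = spec.lstm_units
        for i, w in enumerate(spec.head_widths):
            self.head.append(_Dense(rng, w_in, w))
            if i < len(spec.head_widths) - 1:
                self.head.append(_ReLU())
                if i < spec.n_dropout_layers and spec.dropout > 0:
                    self.head.append(_Dropout(spec.dropout))
            w_in = w
        self._layers = self.conv_layers + self.lstm_layers + self.head
        self._logits = None

    # -- plumbing ----------------------------------------------------------

    def params(self) -> list[_Param]:
        return [p for layer in self._layers for p in layer.params()]

    def n_params(self) -> int:
        return int(sum(p.value.size for p in self.params()))

    def set_dropout_rng(self, rng: np.random.Generator) -> None:
        for layer in self.head:
            if isinstance(layer, _Dropout):
                layer.rng = rng

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0

    # -- computation -------------------------------------------------------

    def _check_input(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x)
        if x.ndim != 4 or x.shape[1] != self.spec.seq_len or x.shape[2:] != (
            self.spec.input_px,
            self.spec.input_px,
        ):
            raise ValueError(
                f"expected input (batch, {self.spec.seq_len}, "
                f"{self.spec.input_px}, {self.spec.input_px}), got {x.shape}"
            )
        return x.astype(_F32, copy=False)

    def encode_frames(self, frames: np.ndarray, train: bool = False) -> np.ndarray:
        """Apply the shared conv encoder to (N, px, px) frames -> (N, feat)."""
        z = np.asarray(frames, dtype=_F32)[..., None]
        for layer in self.conv_layers:
            z = layer.forward(z, train)
        return z.reshape(z.shape[0], -1)

    def _head_forward(self, z: np.ndarray, train: bool) -> np.ndarray:
        for layer in self.head:
            z = layer.forward(z, train)
        return z[:, 0]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        x = self._check_input(x)
        n, T = x.shape[:2]
        feats = self.encode_frames(x.reshape(n * T, *x.shape[2:]), train)
        z = feats.reshape(n, T, -1)
        for layer in self.lstm_layers:
            z = layer.forward(z, train)
        logits = self._head_forward(z, train)
        if train:
            self._logits = logits
        p = _sigmoid(logits)
        return np.clip(p, _PROB_EPS, 1.0 - _PROB_EPS)

    def forward_from_features(self, feats: np.ndarray) -> np.ndarray:
        """Inference from precomputed per-frame features (B, T, feat)."""
        z = np.asarray(feats, dtype=_F32)
        for layer in self.lstm_layers:
            z = layer.forward(z, False)
        p = _sigmoid(self._head_forward(z, False))
        return np.clip(p, _PROB_EPS, 1.0 - _PROB_EPS)

    def backward_bce(self, probs: np.ndarray, labels: np.ndarray) -> None:
        """Backprop of mean binary cross-entropy from the last train forward."""
        n = probs.shape[0]
        dlogit = ((probs - labels.astype(_F32)) / _F32(n)).astype(_F32)
        z = dlogit[:, None]
        for layer in reversed(self.head):
            z = layer.backward(z)
        for layer in reversed(self.lstm_layers):
            z = layer.backward(z)
        T = self.spec.seq_len
        n_frames = z.shape[0] * T
        z = z.reshape(n_frames, self.spec.conv_output_px(), self.spec.conv_output_px(), -1)
        # undo the flatten of the conv output
        for layer in reversed(self.conv_layers):
            z = layer.backward(z)


def bce_loss(probs: np.ndarray, labels: np.ndarray) -> float:
    y = labels.astype(np.float64)
    p = probs.astype(np.float64)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def build_model(spec: ModelSpec, seed: int) -> CRNN:
    """Construct a CRNN with reproducibly seeded initial weights."""
    return CRNN(spec, seed)


# ---------------------------------------------------------------------------
# Weight persistence
# ---------------------------------------------------------------------------


@dataclass
class WeightState:
    """All learnable parameters plus reproducibility metadata."""

    spec: ModelSpec
    arrays: list[np.ndarray]
    seed: int
    epochs_run: int = 0
    init_scheme: str = "glorot_uniform/orthogonal(recurrent)"

    @classmethod
    def capture(cls, model: CRNN, epochs_run: int = 0) -> "WeightState":
        return cls(
            spec=model.spec,
            arrays=[p.value.copy() for p in model.params()],
            seed=model.seed,
            epochs_run=epochs_run,
        )

    def restore(self, model: CRNN) -> None:
        if model.spec.fingerprint() != self.spec.fingerprint():
            raise ValueError(
                f"spec fingerprint mismatch: model {model.spec.fingerprint()} "
                f"vs weights {self.spec.fingerprint()}"
            )
        for p, a in zip(model.params(), self.arrays, strict=True):
            p.value[...] = a


def save_weights(state: WeightState, path: str | Path) -> None:
    """Write a checkpoint: .npz arrays + sidecar .json spec fingerprint."""
    path = Path(path)
    np.savez_compressed(path.with_suffix(".npz"), *state.arrays)
    meta = {
        "spec": asdict(state.spec),
        "fingerprint": state.spec.fingerprint(),
        "seed": state.seed,
        "epochs_run": state.epochs_run,
        "init_scheme": state.init_scheme,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_weights(path: str | Path) -> WeightState:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    spec_d = meta["spec"]
    for key in ("conv_filters", "head_widths"):
        spec_d[key] = tuple(spec_d[key])
    spec = ModelSpec(**spec_d)
    if spec.fingerprint() != meta["fingerprint"]:
        raise ValueError("checkpoint fingerprint does not match its spec")
    with np.load(path.with_suffix(".npz")) as z:
        arrays = [z[k] for k in z.files]
    state = WeightState(
        spec=spec,
        arrays=arrays,
        seed=int(meta["seed"]),
        epochs_run=int(meta["epochs_run"]),
    )
    state.init_scheme = meta.get("init_scheme", state.init_scheme)
    return state
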