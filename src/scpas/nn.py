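"""NumPy neural-network engine for the PAS sequence classifier.

Implements exactly the layer stack used by the classifier —

    softmax . dense(ReLU, dropout) . BiLSTM . maxpool . conv(ReLU) . conv(ReLU)

— with explicit forward/backward passes and Adam updates.  Input is a batch
of one-hot encoded 200-nt windows of shape (B, 200, 4).  The architecture is
width-configurable so that a reduced model can be trained at desk scale
while the default matches the full published-scale design (128x12 and 64x6
convolutions, pool stride 4, 128 BiLSTM units per direction, 1024 dense
units, dropout 0.3).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


@dataclass(frozen=True)
class ModelSpec:
    """Widths of every layer; defaults are the full-scale architecture."""

    seq_len: int = 200
    conv1_filters: int = 128
    conv1_width: int = 12
    conv2_filters: int = 64
    conv2_width: int = 6
    pool: int = 4  # window == stride
    lstm_units: int = 128  # per direction
    dense_units: int = 1024
    dropout: float = 0.3
    n_classes: int = 2

    def scaled(self, factor: float) -> "ModelSpec":
        """Shrink filter/unit counts by ``factor`` (motif widths unchanged)."""
        f = lambda n: max(4, int(round(n * factor)))
        return ModelSpec(
            seq_len=self.seq_len,
            conv1_filters=f(self.conv1_filters),
            conv1_width=self.conv1_width,
            conv2_filters=f(self.conv2_filters),
            conv2_width=self.conv2_width,
            pool=self.pool,
            lstm_units=f(self.lstm_units),
            dense_units=f(self.dense_units),
            dropout=self.dropout,
            n_classes=self.n_classes,
        )


def _glorot(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    fan_in = int(np.prod(shape[:-1]))
    fan_out = shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


# ---------------------------------------------------------------------------
# layer primitives (functional: forward returns output + cache)


def conv1d_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray):
    """Valid 1-D convolution. x:(B,L,C), w:(k,C,F), b:(F) -> (B,L-k+1,F)."""
    k, c, f = w.shape
    cols = sliding_window_view(x, k, axis=1)  # (B, Lout, C, k)
    cols = np.ascontiguousarray(cols.transpose(0, 1, 3, 2))  # (B, Lout, k, C)
    bsz, lout = cols.shape[:2]
    flat = cols.reshape(bsz, lout, k * c)
    z = flat @ w.reshape(k * c, f) + b
    return z, (flat, x.shape, w.shape)


def conv1d_backward(dz: np.ndarray, w: np.ndarray, cache):
    flat, x_shape, w_shape = cache
    k, c, f = w_shape
    bsz, lout = dz.shape[:2]
    wf = w.reshape(k * c, f)
    dw = (flat.reshape(-1, k * c).T @ dz.reshape(-1, f)).reshape(k, c, f)
    db = dz.sum(axis=(0, 1))
    dflat = dz @ wf.T  # (B, Lout, k*C)
    dcols = dflat.reshape(bsz, lout, k, c)
    dx = np.zeros(x_shape)
    for j in range(k):
        dx[:, j : j + lout, :] += dcols[:, :, j, :]
    return dx, dw, db


def relu_forward(x: np.ndarray):
    return np.maximum(x, 0.0), x > 0


def relu_backward(d: np.ndarray, mask: np.ndarray) -> np.ndarray:
    return d * mask


def maxpool_forward(x: np.ndarray, s: int):
    """Non-overlapping max pool along axis 1 (remainder positions dropped)."""
    bsz, length, c = x.shape
    lp = length // s
    xt = x[:, : lp * s].reshape(bsz, lp, s, c)
    idx = xt.argmax(axis=2)
    out = np.take_along_axis(xt, idx[:, :, None, :], axis=2)[:, :, 0, :]
    return out, (idx, x.shape, s)


def maxpool_backward(d: np.ndarray, cache) -> np.ndarray:
    idx, x_shape, s = cache
    bsz, length, c = x_shape
    lp = length // s
    dxt = np.zeros((bsz, lp, s, c))
    np.put_along_axis(dxt, idx[:, :, None, :], d[:, :, None, :], axis=2)
    return dxt.reshape(bsz, lp * s, c) if lp * s == length else np.concatenate(
        [dxt.reshape(bsz, lp * s, c), np.zeros((bsz, length - lp * s, c))], axis=1
    )


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30, 30)))


def lstm_forward(x: np.ndarray, wx: np.ndarray, wh: np.ndarray, b: np.ndarray):
    """Single-direction LSTM; returns final hidden state (B, H) and cache.

    Gate order in the fused weight matrices is (input, forget, cell, output).
    """
    bsz, steps, _ = x.shape
    h_dim = wh.shape[0]
    h = np.zeros((bsz, h_dim))
    c = np.zeros((bsz, h_dim))
    caches = []
    for t in range(steps):
        z = x[:, t] @ wx + h @ wh + b
        i = _sigmoid(z[:, :h_dim])
        f = _sigmoid(z[:, h_dim : 2 * h_dim])
        g = np.tanh(z[:, 2 * h_dim : 3 * h_dim])
        o = _sigmoid(z[:, 3 * h_dim :])
        c_next = f * c + i * g
        h_next = o * np.tanh(c_next)
        caches.append((x[:, t], h, c, i, f, g, o, c_next))
        h, c = h_next, c_next
    return h, caches


def lstm_backward(dh_final: np.ndarray, wx: np.ndarray, wh: np.ndarray, caches):
    h_dim = wh.shape[0]
    steps = len(caches)
    bsz = dh_final.shape[0]
    in_dim = wx.shape[0]
    dwx = np.zeros_like(wx)
    dwh = np.zeros_like(wh)
    db = np.zeros(4 * h_dim)
    dx = np.zeros((bsz, steps, in_dim))
    dh = dh_final.copy()
    dc = np.zeros((bsz, h_dim))
    for t in range(steps - 1, -1, -1):
        x_t, h_prev, c_prev, i, f, g, o, c_next = caches[t]
        tanh_c = np.tanh(c_next)
        do = dh * tanh_c
        dc = dc + dh * o * (1 - tanh_c**2)
        di = dc * g
        df = dc * c_prev
        dg = dc * i
        dz = np.concatenate(
            [di * i * (1 - i), df * f * (1 - f), dg * (1 - g**2), do * o * (1 - o)],
            axis=1,
        )
        dwx += x_t.T @ dz
        dwh += h_prev.T @ dz
        db += dz.sum(axis=0)
        dx[:, t] = dz @ wx.T
        dh = dz @ wh.T
        dc = dc * f
    return dx, dwx, dwh, db


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        for k, g in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g**2
            mhat = self.m[k] / (1 - self.beta1**self.t)
            vhat = self.v[k] / (1 - self.beta2**self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class SequenceClassifier:
    """The CNN+BiLSTM two-class sequence model with explicit backprop."""

    def __init__(self, spec: ModelSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        s = spec
        h = s.lstm_units
        lstm_in = s.conv2_filters
        self.params: dict[str, np.ndarray] = {
            "conv1_w": _glorot(rng, (s.conv1_width, 4, s.conv1_filters)),
            "conv1_b": np.zeros(s.conv1_filters),
            "conv2_w": _glorot(rng, (s.conv2_width, s.conv1_filters, s.conv2_filters)),
            "conv2_b": np.zeros(s.conv2_filters),
            "lstm_fw_wx": _glorot(rng, (lstm_in, 4 * h)),
            "lstm_fw_wh": _glorot(rng, (h, 4 * h)),
            "lstm_fw_b": np.zeros(4 * h),
            "lstm_bw_wx": _glorot(rng, (lstm_in, 4 * h)),
            "lstm_bw_wh": _glorot(rng, (h, 4 * h)),
            "lstm_bw_b": np.zeros(4 * h),
            "dense_w": _glorot(rng, (2 * h, s.dense_units)),
            "dense_b": np.zeros(s.dense_units),
            "out_w": _glorot(rng, (s.dense_units, s.n_classes)),
            "out_b": np.zeros(s.n_classes),
        }
        # forget-gate bias 1 stabilises early training
        for k in ("lstm_fw_b", "lstm_bw_b"):
            self.params[k][h : 2 * h] = 1.0

    # -- forward -----------------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None):
        p = self.params
        z1, c1 = conv1d_forward(x, p["conv1_w"], p["conv1_b"])
        a1, m1 = relu_forward(z1)
        z2, c2 = conv1d_forward(a1, p["conv2_w"], p["conv2_b"])
        a2, m2 = relu_forward(z2)
        pool, cp = maxpool_forward(a2, self.spec.pool)
        h_fw, cf = lstm_forward(pool, p["lstm_fw_wx"], p["lstm_fw_wh"], p["lstm_fw_b"])
        h_bw, cb = lstm_forward(pool[:, ::-1], p["lstm_bw_wx"], p["lstm_bw_wh"], p["lstm_bw_b"])
        h = np.concatenate([h_fw, h_bw], axis=1)
        zd = h @ p["dense_w"] + p["dense_b"]
        ad, md = relu_forward(zd)
        if train and self.spec.dropout > 0:
            assert rng is not None
            keep = 1.0 - self.spec.dropout
            drop_mask = (rng.uniform(size=ad.shape) < keep) / keep
            ad = ad * drop_mask
        else:
            drop_mask = None
        logits = ad @ p["out_w"] + p["out_b"]
        probs = softmax(logits)
        cache = (x, c1, m1, c2, m2, cp, cf, cb, h, md, drop_mask, ad)
        return probs, cache

    # -- backward ----------------------------------------------------------
    def backward(self, probs: np.ndarray, y: np.ndarray, cache) -> dict[str, np.ndarray]:
        p = self.params
        x, c1, m1, c2, m2, cp, cf, cb, h, md, drop_mask, ad = cache
        bsz = len(y)
        dlogits = probs.copy()
        dlogits[np.arange(bsz), y] -= 1.0
        dlogits /= bsz
        grads: dict[str, np.ndarray] = {}
        grads["out_w"] = ad.T @ dlogits
        grads["out_b"] = dlogits.sum(axis=0)
        dad = dlogits @ p["out_w"].T
        if drop_mask is not None:
            dad = dad * drop_mask
        dzd = relu_backward(dad, md)
        grads["dense_w"] = h.T @ dzd
        grads["dense_b"] = dzd.sum(axis=0)
        dh = dzd @ p["dense_w"].T
        h_dim = self.spec.lstm_units
        dpool_f, grads["lstm_fw_wx"], grads["lstm_fw_wh"], grads["lstm_fw_b"] = lstm_backward(
            dh[:, :h_dim], p["lstm_fw_wx"], p["lstm_fw_wh"], cf
        )
        dpool_b, grads["lstm_bw_wx"], grads["lstm_bw_wh"], grads["lstm_bw_b"] = lstm_backward(
            dh[:, h_dim:], p["lstm_bw_wx"], p["lstm_bw_wh"], cb
        )
        dpool = dpool_f + dpool_b[:, ::-1]
        da2 = maxpool_backward(dpool, cp)
        dz2 = relu_backward(da2, m2)
        da1, grads["conv2_w"], grads["conv2_b"] = conv1d_backward(dz2, p["conv2_w"], c2)
        dz1 = relu_backward(da1, m1)
        _, grads["conv1_w"], grads["conv1_b"] = conv1d_backward(dz1, p["conv1_w"], c1)
        return grads

    # -- inference / persistence -------------------------------------------
    def predict_proba(self, x: np.ndarray, batch_size: int = 1024) -> np.ndarray:
        out = []
        for i in range(0, len(x), batch_size):
            probs, _ = self.forward(x[i : i + batch_size], train=False)
            out.append(probs[:, 1])
        return np.concatenate(out) if out else np.zeros(0)

    def conv1_activations(self, x: np.ndarray) -> np.ndarray:
        """Pre-ReLU first-layer filter activations (B, Lout, F)."""
        z1, _ = conv1d_forward(x, self.params["conv1_w"], self.params["conv1_b"])
        return z1

    def save(self, path: str) -> None:
        meta = json.dumps(asdict(self.spec))
        np.savez_compressed(path, __spec__=np.array(meta), **self.params)

    @classmethod
    def load(cls, path: str) -> "SequenceClassifier":
        data = np.load(path, allow_pickle=False)
        spec = ModelSpec(**json.loads(str(data["__spec__"])))
        model = cls(spec, seed=0)
        for k in model.params:
            model.params[k] = data[k]
        return model

    def copy_params(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def set_params(self, params: dict[str, np.ndarray]) -> None:
        self.params = {k: v.copy() for k, v in params.items()}


def cross_entropy(probs: np.ndarray, y: np.ndarray) -> float:
    eps = 1e-12
    return float(-np.mean(np.log(probs[np.arange(len(y)), y] + eps)))
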