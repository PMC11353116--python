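"""The MLS-Net sequence classifier and its two variants.

The primary model ("mls") reads the per-epoch 10-feature vectors as a
temporal sequence through a bidirectional LSTM (16 units per direction,
32 total), whose per-epoch outputs feed a small MLP and a softmax over the
three vigilance states. Sleep states come in bouts, so the recurrent
context on both sides of an epoch carries real information — this is the
reason the sequence model beats per-epoch classifiers on REM.

Variants:

* ``smls`` (spatial): the expert features are dropped; a two-layer 1-D CNN
  reads the raw per-epoch signal channels, followed by the MLP and softmax.
  No recurrent layer — each epoch is classified independently.
* ``stmls`` (spatio-temporal): the CNN embedding is concatenated with the
  10 expert features and the combined sequence goes through the bi-LSTM.

Everything is implemented directly on numpy with hand-derived gradients
and an Adam optimizer; all randomness (initialization, shuffling, dropout)
flows from ``ModelConfig.seed``, so runs are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json
import logging
from pathlib import Path

import numpy as np

from .io_poly import STATES, ConfigurationError

__all__ = [
    "ModelConfig",
    "EpochPrediction",
    "SequenceClassifier",
    "build_model",
    "predict",
    "train",
    "save_model",
    "load_model",
]

logger = logging.getLogger(__name__)


@dataclass
class ModelConfig:
    """Architecture and training hyperparameters.

    The recurrent width (16 per direction) is the model's defining
    constant; sequence length, optimizer settings and MLP shape are
    configurable because the method does not pin them.
    """

    variant: str = "mls"  # {mls, smls, stmls}
    lstm_units_per_direction: int = 16
    mlp_hidden_sizes: tuple[int, ...] = (32,)
    n_classes: int = 3
    sequence_length: int = 64
    dropout: float = 0.0
    cnn_channels: tuple[int, ...] = (8, 16)
    cnn_kernel: int = 7
    cnn_stride: int = 2
    n_features: int = 10
    n_signal_channels: int = 3
    learning_rate: float = 1e-3
    batch_size: int = 32
    class_weights: tuple[float, float, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.variant not in ("mls", "smls", "stmls"):
            raise ConfigurationError(f"unknown model variant {self.variant!r}")
        if self.lstm_units_per_direction < 1:
            raise ConfigurationError("lstm_units_per_direction must be >= 1")
        if self.n_classes != 3:
            raise ConfigurationError("the classifier is three-state (WAKE/NREM/REM)")
        if not (0 <= self.dropout < 1):
            raise ConfigurationError("dropout must be in [0, 1)")


@dataclass
class EpochPrediction:
    """Softmax probabilities and argmax label for one epoch."""

    probabilities: np.ndarray  # (3,), sums to 1
    label: str = field(init=False)

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        if abs(p.sum() - 1.0) > 1e-6 or (p < -1e-12).any():
            raise ValueError("probabilities must be a simplex point")
        self.probabilities = p
        self.label = STATES[int(np.argmax(p))]


# ---------------------------------------------------------------------------
# Layers (numpy, manual gradients)


def _uniform_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int):
    k = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-k, k, size=shape)


class _Dense:
    """Affine layer applied over the last axis; optional ReLU."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, relu=False):
        self.W = _uniform_init(rng, (n_in, n_out), n_in)
        self.b = np.zeros(n_out)
        self.relu = relu
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        y = x @ self.W + self.b
        if self.relu:
            self._mask = y > 0
            y = y * self._mask
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self.relu:
            dy = dy * self._mask
        x2 = self._x.reshape(-1, self._x.shape[-1])
        dy2 = dy.reshape(-1, dy.shape[-1])
        self.dW += x2.T @ dy2
        self.db += dy2.sum(axis=0)
        return dy @ self.W.T


class _LSTM:
    """Single-direction LSTM over (batch, time, features). Gate order i,f,g,o."""

    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator):
        H = n_hidden
        self.H = H
        self.Wx = _uniform_init(rng, (n_in, 4 * H), n_in)
        self.Wh = _uniform_init(rng, (H, 4 * H), H)
        self.b = np.zeros(4 * H)
        self.b[H : 2 * H] = 1.0  # forget-gate bias: remember by default
        self.dWx = np.zeros_like(self.Wx)
        self.dWh = np.zeros_like(self.Wh)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [(self.Wx, self.dWx), (self.Wh, self.dWh), (self.b, self.db)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, T, _ = x.shape
        H = self.H
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        self._cache = []
        self._x = x
        out = np.empty((B, T, H))
        for t in range(T):
            a = x[:, t] @ self.Wx + h @ self.Wh + self.b
            i = _sigmoid(a[:, :H])
            f = _sigmoid(a[:, H : 2 * H])
            g = np.tanh(a[:, 2 * H : 3 * H])
            o = _sigmoid(a[:, 3 * H :])
            c_prev = c
            c = f * c_prev + i * g
            hc = np.tanh(c)
            h_prev = h
            h = o * hc
            out[:, t] = h
            self._cache.append((i, f, g, o, hc, c_prev, h_prev))
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x = self._x
        B, T, _ = x.shape
        H = self.H
        dx = np.zeros_like(x)
        dh_next = np.zeros((B, H))
        dc_next = np.zeros((B, H))
        for t in reversed(range(T)):
            i, f, g, o, hc, c_prev, h_prev = self._cache[t]
            dh = dout[:, t] + dh_next
            dc = dc_next + dh * o * (1 - hc**2)
            da = np.empty((B, 4 * H))
            da[:, :H] = dc * g * i * (1 - i)
            da[:, H : 2 * H] = dc * c_prev * f * (1 - f)
            da[:, 2 * H : 3 * H] = dc * i * (1 - g**2)
            da[:, 3 * H :] = dh * hc * o * (1 - o)
            self.dWx += x[:, t].T @ da
            self.dWh += h_prev.T @ da
            self.db += da.sum(axis=0)
            dx[:, t] = da @ self.Wx.T
            dh_next = da @ self.Wh.T
            dc_next = dc * f
        return dx


class _BiLSTM:
    """Concatenated forward and time-reversed LSTM passes."""

    def __init__(self, n_in: int, n_per_dir: int, rng: np.random.Generator):
        self.fwd = _LSTM(n_in, n_per_dir, rng)
        self.bwd = _LSTM(n_in, n_per_dir, rng)

    def params(self):
        return self.fwd.params() + self.bwd.params()

    def forward(self, x: np.ndarray) -> np.ndarray:
        yf = self.fwd.forward(x)
        yb = self.bwd.forward(x[:, ::-1])[:, ::-1]
        return np.concatenate([yf, yb], axis=2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        H = self.fwd.H
        dxf = self.fwd.backward(dy[:, :, :H])
        dxb = self.bwd.backward(dy[:, ::-1, H:])[:, ::-1]
        return dxf + dxb


class _Conv1d:
    """Strided 1-D convolution over (batch, channels, samples), with ReLU."""

    def __init__(self, c_in, c_out, kernel, stride, rng: np.random.Generator):
        self.W = _uniform_init(rng, (c_out, c_in, kernel), c_in * kernel)
        self.b = np.zeros(c_out)
        self.stride = stride
        self.kernel = kernel
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        K, s = self.kernel, self.stride
        cols = np.lib.stride_tricks.sliding_window_view(x, K, axis=2)[:, :, ::s]
        self._cols = cols  # (B, C_in, L, K)
        y = np.einsum("bclk,ock->bol", cols, self.W) + self.b[None, :, None]
        self._mask = y > 0
        self._xshape = x.shape
        return y * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dy = dy * self._mask
        self.dW += np.einsum("bol,bclk->ock", dy, self._cols)
        self.db += dy.sum(axis=(0, 2))
        dcols = np.einsum("bol,ock->bclk", dy, self.W)
        dx = np.zeros(self._xshape)
        L = dcols.shape[2]
        s = self.stride
        for k in range(self.kernel):
            dx[:, :, k : k + L * s : s][:, :, :L] += dcols[:, :, :, k]
        return dx


class _MaxPool1d:
    def __init__(self, pool: int = 2):
        self.pool = pool

    def params(self):
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        p = self.pool
        B, C, L = x.shape
        Lp = L // p
        xr = x[:, :, : Lp * p].reshape(B, C, Lp, p)
        self._arg = xr.argmax(axis=3)
        self._shape = x.shape
        return xr.max(axis=3)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        p = self.pool
        B, C, Lp = dy.shape
        dxr = np.zeros((B, C, Lp, p))
        np.put_along_axis(dxr, self._arg[..., None], dy[..., None], axis=3)
        dx = np.zeros(self._shape)
        dx[:, :, : Lp * p] = dxr.reshape(B, C, Lp * p)
        return dx


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    e = np.exp(x[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class _Adam:
    def __init__(self, param_pairs, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.pairs = param_pairs
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in param_pairs]
        self.v = [np.zeros_like(p) for p, _ in param_pairs]
        self.t = 0

    def step(self):
        self.t += 1
        for (p, g), m, v in zip(self.pairs, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g**2
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for _, g in self.pairs:
            g[...] = 0.0


# ---------------------------------------------------------------------------
# The classifier


class SequenceClassifier:
    """bi-LSTM (or CNN) epoch classifier; built via :func:`build_model`."""

    def __init__(self, cfg: ModelConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        H = cfg.lstm_units_per_direction
        self._conv_layers: list = []
        conv_out = 0
        if cfg.variant in ("smls", "stmls"):
            c_in = cfg.n_signal_channels
            for c_out in cfg.cnn_channels:
                self._conv_layers.append(
                    _Conv1d(c_in, c_out, cfg.cnn_kernel, cfg.cnn_stride, rng)
                )
                self._conv_layers.append(_MaxPool1d(2))
                c_in = c_out
            conv_out = c_in
        if cfg.variant == "mls":
            mlp_in_src = 2 * H
            self.bilstm: _BiLSTM | None = _BiLSTM(cfg.n_features, H, rng)
        elif cfg.variant == "stmls":
            mlp_in_src = 2 * H
            self.bilstm = _BiLSTM(cfg.n_features + conv_out, H, rng)
        else:  # smls: no recurrent layer
            mlp_in_src = conv_out
            self.bilstm = None
        self._mlp: list[_Dense] = []
        n_in = mlp_in_src
        for h in cfg.mlp_hidden_sizes:
            self._mlp.append(_Dense(n_in, h, rng, relu=True))
            n_in = h
        self._mlp.append(_Dense(n_in, cfg.n_classes, rng, relu=False))
        self._train_rng = np.random.default_rng(cfg.seed + 1)

    # -- plumbing

    @property
    def has_recurrent_layer(self) -> bool:
        return self.bilstm is not None

    @property
    def recurrent_state_width(self) -> int:
        """Total recurrent units (both directions); 0 for smls."""
        if self.bilstm is None:
            return 0
        return 2 * self.bilstm.fwd.H

    def _all_params(self):
        pairs = []
        for layer in self._conv_layers:
            pairs += layer.params()
        if self.bilstm is not None:
            pairs += self.bilstm.params()
        for layer in self._mlp:
            pairs += layer.params()
        return pairs

    def parameter_count(self) -> int:
        return sum(p.size for p, _ in self._all_params())

    def parameter_vector(self) -> np.ndarray:
        return np.concatenate([p.ravel() for p, _ in self._all_params()])

    # -- forward passes

    def _conv_embed(self, signals: np.ndarray) -> np.ndarray:
        """(N, C, S) raw epochs -> (N, conv_out) embeddings (global avg pool)."""
        y = signals
        for layer in self._conv_layers:
            y = layer.forward(y)
        self._conv_len = y.shape[2]
        return y.mean(axis=2)

    def _conv_embed_backward(self, demb: np.ndarray) -> None:
        dy = np.repeat(demb[:, :, None], self._conv_len, axis=2) / self._conv_len
        for layer in reversed(self._conv_layers):
            dy = layer.backward(dy)

    def _forward(self, inputs, training: bool = False) -> np.ndarray:
        """inputs -> logits.

        mls: (B, T, n_features) -> (B, T, 3)
        smls: (N, C, S) -> (N, 3)
        stmls: (features (B, T, n_features), signals (B, T, C, S)) -> (B, T, 3)
        """
        cfg = self.cfg
        if cfg.variant == "mls":
            h = self.bilstm.forward(np.asarray(inputs, dtype=float))
        elif cfg.variant == "smls":
            h = self._conv_embed(np.asarray(inputs, dtype=float))
        else:
            feats, signals = inputs
            feats = np.asarray(feats, dtype=float)
            signals = np.asarray(signals, dtype=float)
            B, T, C, S = signals.shape
            emb = self._conv_embed(signals.reshape(B * T, C, S))
            emb = emb.reshape(B, T, -1)
            self._stmls_split = (feats.shape[-1], B, T)
            h = self.bilstm.forward(np.concatenate([feats, emb], axis=2))
        self._dropout_masks = []
        for layer in self._mlp[:-1]:
            h = layer.forward(h)
            if training and cfg.dropout > 0:
                keep = 1.0 - cfg.dropout
                mask = self._train_rng.random(h.shape) < keep
                h = h * mask / keep
                self._dropout_masks.append((mask, keep))
            else:
                self._dropout_masks.append(None)
        return self._mlp[-1].forward(h)

    def _backward(self, dlogits: np.ndarray) -> None:
        d = self._mlp[-1].backward(dlogits)
        for layer, mask in zip(reversed(self._mlp[:-1]), reversed(self._dropout_masks)):
            if mask is not None:
                m, keep = mask
                d = d * m / keep
            d = layer.backward(d)
        cfg = self.cfg
        if cfg.variant == "mls":
            self.bilstm.backward(d)
        elif cfg.variant == "smls":
            self._conv_embed_backward(d)
        else:
            dx = self.bilstm.backward(d)
            n_feat, B, T = self._stmls_split
            self._conv_embed_backward(dx[:, :, n_feat:].reshape(B * T, -1))

    # -- public prediction API

    def predict_proba(self, inputs) -> np.ndarray:
        """Per-epoch class probabilities, one row per epoch.

        mls: (n_epochs, n_features); smls: (n_epochs, C, S);
        stmls: tuple (features, signals).
        """
        cfg = self.cfg
        if cfg.variant == "smls":
            x = np.asarray(inputs, dtype=float)
            if x.ndim != 3 or x.shape[1] != cfg.n_signal_channels:
                raise ValueError(
                    f"smls expects (n_epochs, {cfg.n_signal_channels}, samples), "
                    f"got {x.shape}"
                )
            return _softmax(self._forward(x))
        if cfg.variant == "mls":
            F = np.asarray(inputs, dtype=float)
            if F.ndim != 2 or F.shape[1] != cfg.n_features:
                raise ValueError(
                    f"mls expects (n_epochs, {cfg.n_features}) features, got {F.shape}"
                )
            out = np.empty((F.shape[0], cfg.n_classes))
            for lo, hi in _chunks(F.shape[0], cfg.sequence_length):
                out[lo:hi] = _softmax(self._forward(F[None, lo:hi]))[0]
            return out
        feats, signals = inputs
        feats = np.asarray(feats, dtype=float)
        signals = np.asarray(signals, dtype=float)
        out = np.empty((feats.shape[0], cfg.n_classes))
        for lo, hi in _chunks(feats.shape[0], cfg.sequence_length):
            logits = self._forward((feats[None, lo:hi], signals[None, lo:hi]))
            out[lo:hi] = _softmax(logits)[0]
        return out


def _chunks(n: int, size: int):
    for lo in range(0, n, size):
        yield lo, min(lo + size, n)


def build_model(cfg: ModelConfig) -> SequenceClassifier:
    """Instantiate a classifier with seeded, reproducible initialization."""
    return SequenceClassifier(cfg)


def predict(model: SequenceClassifier, inputs) -> list[EpochPrediction]:
    """One EpochPrediction (probabilities + argmax label) per epoch."""
    proba = model.predict_proba(inputs)
    return [EpochPrediction(p) for p in proba]


# ---------------------------------------------------------------------------
# Training


def _encode_labels(labels) -> np.ndarray:
    index = {s: i for i, s in enumerate(STATES)}
    try:
        return np.array([index[l] for l in labels], dtype=int)
    except KeyError as exc:
        raise ValueError(f"label outside {STATES}: {exc}") from exc


def _make_sequences(X: np.ndarray, y: np.ndarray, seq_len: int):
    """Contiguous non-overlapping windows; a trailing partial window is kept."""
    seqs = []
    for lo, hi in _chunks(len(y), seq_len):
        seqs.append((X[lo:hi], y[lo:hi]))
    return seqs


def train(
    model: SequenceClassifier,
    train_features,
    train_labels,
    iterations: int = 120,
    signals=None,
):
    """Train with Adam on cross-entropy; returns (model, curves).

    ``iterations`` are full passes over the training set (the curves have
    one accuracy and one loss entry per pass). For ``smls`` pass raw epoch
    ``signals`` instead of features; for ``stmls`` pass both.

    A single-class training set is accepted (with a warning) — the model
    then simply learns the majority prior.
    """
    cfg = model.cfg
    y = _encode_labels(train_labels)
    if len(np.unique(y)) < 2:
        logger.warning("training labels contain a single class; model will be trivial")
    curves = {"loss": [], "accuracy": []}
    if iterations == 0:
        return model, curves

    weights = np.ones(cfg.n_classes)
    if cfg.class_weights is not None:
        weights = np.asarray(cfg.class_weights, dtype=float)

    opt = _Adam(model._all_params(), lr=cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed + 17)

    if cfg.variant == "smls":
        X = np.asarray(signals, dtype=float)
        items = [(X[lo:hi], y[lo:hi]) for lo, hi in _chunks(len(y), cfg.batch_size)]
        for _ in range(iterations):
            order = rng.permutation(len(items))
            tot_loss = tot_correct = tot_n = 0.0
            for k in order:
                xb, yb = items[k]
                logits = model._forward(xb, training=True)
                loss, dlogits, ncorr = _ce_grad(logits, yb, weights)
                opt.zero_grad()
                model._backward(dlogits)
                opt.step()
                tot_loss += loss * len(yb)
                tot_correct += ncorr
                tot_n += len(yb)
            curves["loss"].append(tot_loss / tot_n)
            curves["accuracy"].append(tot_correct / tot_n)
        return model, curves

    # Sequence variants: batch same-length sequences together.
    if cfg.variant == "mls":
        X = np.asarray(train_features, dtype=float)
        seqs = _make_sequences(X, y, cfg.sequence_length)
    else:
        F = np.asarray(train_features, dtype=float)
        S = np.asarray(signals, dtype=float)
        seqs = [
            ((F[lo:hi], S[lo:hi]), y[lo:hi])
            for lo, hi in _chunks(len(y), cfg.sequence_length)
        ]
    for _ in range(iterations):
        order = rng.permutation(len(seqs))
        tot_loss = tot_correct = tot_n = 0.0
        # group shuffled sequences into batches of equal length
        buckets: dict[int, list[int]] = {}
        for k in order:
            T = len(seqs[k][1])
            buckets.setdefault(T, []).append(k)
        for T, idxs in sorted(buckets.items()):
            for b0 in range(0, len(idxs), cfg.batch_size):
                batch = idxs[b0 : b0 + cfg.batch_size]
                yb = np.stack([seqs[k][1] for k in batch])
                if cfg.variant == "mls":
                    xb = np.stack([seqs[k][0] for k in batch])
                else:
                    xb = (
                        np.stack([seqs[k][0][0] for k in batch]),
                        np.stack([seqs[k][0][1] for k in batch]),
                    )
                logits = model._forward(xb, training=True)
                loss, dlogits, ncorr = _ce_grad(logits, yb, weights)
                opt.zero_grad()
                model._backward(dlogits)
                opt.step()
                n = yb.size
                tot_loss += loss * n
                tot_correct += ncorr
                tot_n += n
        curves["loss"].append(tot_loss / tot_n)
        curves["accuracy"].append(tot_correct / tot_n)
    return model, curves


def _ce_grad(logits: np.ndarray, y: np.ndarray, weights: np.ndarray):
    """Weighted softmax cross-entropy: mean loss, dL/dlogits, #correct."""
    p = _softmax(logits)
    flat_p = p.reshape(-1, p.shape[-1])
    flat_y = y.reshape(-1)
    n = flat_y.size
    w = weights[flat_y]
    eps = 1e-12
    loss = float(np.mean(-w * np.log(flat_p[np.arange(n), flat_y] + eps)))
    dflat = flat_p * w[:, None]
    dflat[np.arange(n), flat_y] -= w
    dflat /= n
    ncorr = float(np.sum(flat_p.argmax(axis=1) == flat_y))
    return loss, dflat.reshape(logits.shape), ncorr


# ---------------------------------------------------------------------------
# Checkpoints


def save_model(model: SequenceClassifier, path: str | Path) -> None:
    """Save config + parameters to an .npz with the config embedded as JSON."""
    cfg = model.cfg
    cfg_json = json.dumps(
        {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in vars(cfg).items()
        }
    )
    arrays = {f"p{i}": p for i, (p, _) in enumerate(model._all_params())}
    np.savez(path, config=np.array(cfg_json), **arrays)


def load_model(path: str | Path) -> SequenceClassifier:
    data = np.load(path, allow_pickle=False)
    raw = json.loads(str(data["config"]))
    for key in ("mlp_hidden_sizes", "cnn_channels", "class_weights"):
        if key in raw and isinstance(raw[key], list):
            raw[key] = tuple(raw[key])
    model = SequenceClassifier(ModelConfig(**raw))
    for i, (p, _) in enumerate(model._all_params()):
        p[...] = data[f"p{i}"]
    return model
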