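"""Fully convolutional network for inertial time-series classification.

The architecture is the canonical time-series FCN: stacked blocks of
(temporal convolution -> batch normalization -> ReLU), global average
pooling over time, then a linear softmax head. There are no dense hidden
layers and no pooling between blocks, so the network accepts any window
length at inference.

This is a compact, self-contained NumPy implementation (im2col
convolutions, Adam, backprop) sized for CPU training on 10-second
inertial windows. It is deliberately minimal: no GPU paths, no data
augmentation, single-threaded determinism given a seed.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .records import ImuRecording
from .windowing import ChannelScaler, segment_windows

logger = logging.getLogger(__name__)

__all__ = ["FcnConfig", "FcnClassifier", "PredictionSeries", "predict_recording"]


@dataclass(frozen=True)
class FcnConfig:
    """Architecture and optimization settings for the FCN.

    ``conv_blocks`` is an ordered list of ``(filters, kernel_size)``; the
    default triple (128,8)/(256,5)/(128,3) is the standard time-series
    FCN. Smaller stacks train markedly faster on CPU with little loss on
    clean quasi-periodic signals.
    """

    conv_blocks: tuple = ((128, 8), (256, 5), (128, 3))
    input_channels: int = 9
    n_classes: int = 2
    epochs: int = 30
    batch_size: int = 64
    learning_rate: float = 1e-3
    val_fraction: float = 0.15
    patience: int = 6
    #: temporal block-average decimation applied to inputs before the first
    #: convolution. Slow rehabilitation movements (0.2-1 Hz) need the conv
    #: stack's receptive field to span at least one repetition period; at
    #: 50 Hz raw sampling a factor of 5 brings one period within reach and
    #: cuts compute five-fold.
    downsample: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.conv_blocks) < 1:
            raise ValueError("need at least one conv block")
        for blk in self.conv_blocks:
            if len(blk) != 2 or blk[0] < 1 or blk[1] < 1:
                raise ValueError(f"invalid conv block spec {blk!r}")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.downsample < 1:
            raise ValueError("downsample must be >= 1")


# ---------------------------------------------------------------------------
# layer primitives
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(N, L, C) -> (N, L, k*C) patches under 'same' zero padding."""
    n, L, c = x.shape
    left = (k - 1) // 2
    xp = np.pad(x, ((0, 0), (left, k - 1 - left), (0, 0)))
    s0, s1, s2 = xp.strides
    cols = np.lib.stride_tricks.as_strided(
        xp, shape=(n, L, k, c), strides=(s0, s1, s1, s2), writeable=False)
    return cols.reshape(n, L, k * c)


def _col2im(dcols: np.ndarray, k: int, L: int, c: int) -> np.ndarray:
    """Adjoint of :func:`_im2col`: scatter patch gradients back to (N, L, C)."""
    n = dcols.shape[0]
    d4 = dcols.reshape(n, L, k, c)
    left = (k - 1) // 2
    dxp = np.zeros((n, L + k - 1, c), dtype=dcols.dtype)
    for j in range(k):
        dxp[:, j:j + L, :] += d4[:, :, j, :]
    return dxp[:, left:left + L, :]


class _ConvBlock:
    """Temporal conv ('same') -> batch norm -> ReLU, with backprop."""

    def __init__(self, c_in: int, filters: int, kernel: int,
                 rng: np.random.Generator):
        self.k = kernel
        self.c_in = c_in
        self.f = filters
        scale = np.sqrt(2.0 / (kernel * c_in))  # He init
        self.W = rng.normal(0, scale, size=(kernel * c_in, filters)
                            ).astype(np.float32)
        self.b = np.zeros(filters, dtype=np.float32)
        self.gamma = np.ones(filters, dtype=np.float32)
        self.beta = np.zeros(filters, dtype=np.float32)
        self.run_mean = np.zeros(filters, dtype=np.float32)
        self.run_var = np.ones(filters, dtype=np.float32)
        self.momentum = 0.9
        self.eps = 1e-5

    def params(self):
        return [self.W, self.b, self.gamma, self.beta]

    def forward(self, x: np.ndarray, training: bool):
        cols = _im2col(x, self.k)                      # (N, L, k*C)
        z = cols @ self.W + self.b                     # (N, L, F)
        if training:
            mu = z.mean(axis=(0, 1))
            var = z.var(axis=(0, 1))
            self.run_mean = (self.momentum * self.run_mean
                             + (1 - self.momentum) * mu).astype(np.float32)
            self.run_var = (self.momentum * self.run_var
                            + (1 - self.momentum) * var).astype(np.float32)
        else:
            mu, var = self.run_mean, self.run_var
        inv = 1.0 / np.sqrt(var + self.eps)
        zhat = (z - mu) * inv
        out = np.maximum(self.gamma * zhat + self.beta, 0.0)
        cache = (cols, zhat, inv, out, x.shape)
        return out, cache

    def backward(self, dout: np.ndarray, cache):
        cols, zhat, inv, out, xshape = cache
        n, L, _ = xshape
        m = out.shape[0] * out.shape[1]
        dpre = dout * (out > 0)
        dgamma = (dpre * zhat).sum(axis=(0, 1))
        dbeta = dpre.sum(axis=(0, 1))
        # batch-norm backward (standard closed form)
        dzhat = dpre * self.gamma
        dz = inv / m * (m * dzhat - dzhat.sum(axis=(0, 1))
                        - zhat * (dzhat * zhat).sum(axis=(0, 1)))
        dz = dz.astype(np.float32)
        dW = np.tensordot(cols, dz, axes=([0, 1], [0, 1]))
        db = dz.sum(axis=(0, 1))
        dcols = dz @ self.W.T
        dx = _col2im(dcols, self.k, L, self.c_in)
        return dx, [dW, db, dgamma, dbeta]


# ---------------------------------------------------------------------------
# classifier
# ---------------------------------------------------------------------------

class FcnClassifier:
    """Trainable FCN over fixed-length multichannel windows.

    Follows the fit/predict_proba idiom. Labels may be arbitrary integers
    (exercise class ids, 0/1 binary); they are mapped to an internal
    index and exposed as ``classes_`` in sorted order.
    """

    def __init__(self, config: FcnConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.blocks: list[_ConvBlock] = []
        c_in = config.input_channels
        for filters, kernel in config.conv_blocks:
            self.blocks.append(_ConvBlock(c_in, filters, kernel, rng))
            c_in = filters
        scale = np.sqrt(1.0 / c_in)
        self.W_out = rng.normal(0, scale, size=(c_in, config.n_classes)
                                ).astype(np.float32)
        self.b_out = np.zeros(config.n_classes, dtype=np.float32)
        self.classes_ = np.arange(config.n_classes)
        self.history: list[dict] = []
        self._rng = rng

    # -- parameter plumbing -------------------------------------------------
    def _params(self):
        ps = []
        for blk in self.blocks:
            ps.extend(blk.params())
        ps.extend([self.W_out, self.b_out])
        return ps

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self._params()))

    def _decimate(self, X: np.ndarray) -> np.ndarray:
        d = self.config.downsample
        if d == 1:
            return X
        n, L, c = X.shape
        L2 = L // d
        return X[:, :L2 * d, :].reshape(n, L2, d, c).mean(axis=2)

    # -- forward / loss -----------------------------------------------------
    def _forward(self, X: np.ndarray, training: bool):
        caches = []
        h = X
        for blk in self.blocks:
            h, cache = blk.forward(h, training)
            caches.append(cache)
        pooled = h.mean(axis=1)                       # global average pooling
        logits = pooled @ self.W_out + self.b_out
        return logits, (caches, pooled, h.shape[1])

    @staticmethod
    def _softmax(logits: np.ndarray) -> np.ndarray:
        z = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    def _backward(self, probs, y_idx, cache):
        caches, pooled, L = cache
        n = probs.shape[0]
        dlogits = probs.copy()
        dlogits[np.arange(n), y_idx] -= 1.0
        dlogits /= n
        dW_out = pooled.T @ dlogits
        db_out = dlogits.sum(axis=0)
        dpooled = dlogits @ self.W_out.T
        dh = np.repeat(dpooled[:, None, :] / L, L, axis=1).astype(np.float32)
        grads = [dW_out.astype(np.float32), db_out.astype(np.float32)]
        block_grads = []
        for blk, c in zip(reversed(self.blocks), reversed(caches)):
            dh, g = blk.backward(dh, c)
            block_grads = g + block_grads
        return block_grads + grads

    # -- training -----------------------------------------------------------
    def fit(self, X: np.ndarray, y: np.ndarray,
            groups: np.ndarray | None = None) -> "FcnClassifier":
        """Train by mini-batch Adam on softmax cross-entropy.

        ``X`` is (N, L, C); ``y`` integer labels covering every class.
        When ``groups`` (e.g. patient ids) are given, the early-stopping
        validation fold holds out whole groups so validation windows
        never share a subject with the gradient batches.
        """
        cfg = self.config
        X = self._decimate(np.asarray(X, dtype=np.float32))
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) != cfg.n_classes:
            missing = cfg.n_classes - len(self.classes_)
            raise ValueError(
                f"training data covers {len(self.classes_)} of "
                f"{cfg.n_classes} classes ({missing} absent)")
        idx_of = {c: i for i, c in enumerate(self.classes_)}
        y_idx = np.array([idx_of[v] for v in y])

        # validation fold for early stopping
        n = len(y)
        rng = self._rng
        if cfg.val_fraction > 0 and n >= 20:
            if groups is not None:
                uniq = np.unique(groups)
                rng.shuffle(uniq)
                n_val_g = max(1, int(round(len(uniq) * cfg.val_fraction)))
                val_groups = set(uniq[:n_val_g])
                val_mask = np.array([g in val_groups for g in groups])
                if val_mask.all() or not val_mask.any():
                    val_mask = np.zeros(n, bool)
                    val_mask[rng.permutation(n)[:max(1, int(n * cfg.val_fraction))]] = True
            else:
                val_mask = np.zeros(n, bool)
                val_mask[rng.permutation(n)[:max(1, int(n * cfg.val_fraction))]] = True
            # a usable fold must contain every class on the training side
            if len(np.unique(y_idx[~val_mask])) < cfg.n_classes:
                val_mask = np.zeros(n, bool)
        else:
            val_mask = np.zeros(n, bool)
        Xtr, ytr = X[~val_mask], y_idx[~val_mask]
        Xval, yval = X[val_mask], y_idx[val_mask]

        params = self._params()
        m_t = [np.zeros_like(p) for p in params]
        v_t = [np.zeros_like(p) for p in params]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        t = 0
        best_val_loss, best_state, since_best = np.inf, None, 0
        self.history = []
        for epoch in range(cfg.epochs):
            order = rng.permutation(len(ytr))
            losses = []
            for s in range(0, len(order), cfg.batch_size):
                bidx = order[s:s + cfg.batch_size]
                if len(bidx) < 2:
                    continue  # batch norm needs >= 2 samples
                logits, cache = self._forward(Xtr[bidx], training=True)
                probs = self._softmax(logits)
                loss = -np.mean(np.log(probs[np.arange(len(bidx)),
                                             ytr[bidx]] + 1e-12))
                losses.append(loss)
                grads = self._backward(probs, ytr[bidx], cache)
                t += 1
                lr_t = cfg.learning_rate * np.sqrt(1 - beta2**t) / (1 - beta1**t)
                for p, g, mm, vv in zip(params, grads, m_t, v_t):
                    mm *= beta1
                    mm += (1 - beta1) * g
                    vv *= beta2
                    vv += (1 - beta2) * g * g
                    p -= lr_t * mm / (np.sqrt(vv) + eps)
            rec = {"epoch": epoch, "loss": float(np.mean(losses))}
            if len(yval):
                vprobs = self._proba_decimated(Xval)
                rec["val_accuracy"] = float(
                    (vprobs.argmax(axis=1) == yval).mean())
                # early stopping monitors validation cross-entropy: it is
                # much smoother than accuracy, which can peak by luck on a
                # barely-trained net when the fold is small
                val_loss = float(-np.mean(np.log(
                    vprobs[np.arange(len(yval)), yval] + 1e-12)))
                rec["val_loss"] = val_loss
                if val_loss < best_val_loss:
                    best_val_loss, since_best = val_loss, 0
                    # snapshot weights AND batch-norm running statistics:
                    # restoring one without the other mismatches the
                    # normalization the weights were trained against
                    best_state = ([p.copy() for p in params],
                                  [(b.run_mean.copy(), b.run_var.copy())
                                   for b in self.blocks])
                else:
                    since_best += 1
            self.history.append(rec)
            if len(yval) and since_best >= cfg.patience:
                logger.info("early stopping at epoch %d (best val loss %.4f)",
                            epoch, best_val_loss)
                break
        if best_state is not None:
            saved_params, saved_stats = best_state
            for p, b in zip(params, saved_params):
                p[...] = b
            for blk, (rm, rv) in zip(self.blocks, saved_stats):
                blk.run_mean, blk.run_var = rm, rv
        return self

    # -- inference ----------------------------------------------------------
    def predict_proba(self, X: np.ndarray, batch: int = 256) -> np.ndarray:
        X = self._decimate(np.asarray(X, dtype=np.float32))
        return self._proba_decimated(X, batch)

    def _proba_decimated(self, X: np.ndarray, batch: int = 256) -> np.ndarray:
        """Forward pass over inputs that are already decimated."""
        outs = []
        for s in range(0, len(X), batch):
            logits, _ = self._forward(X[s:s + batch], training=False)
            outs.append(self._softmax(logits))
        return np.concatenate(outs, axis=0) if outs else np.empty((0, self.config.n_classes))

    def _predict_idx(self, X) -> np.ndarray:
        return self.predict_proba(X).argmax(axis=1)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classes_[self._predict_idx(X)]

    # -- persistence ---------------------------------------------------------
    def save(self, path: str | Path) -> None:
        path = Path(path)
        arrays = {}
        for i, blk in enumerate(self.blocks):
            arrays.update({
                f"b{i}_W": blk.W, f"b{i}_b": blk.b,
                f"b{i}_gamma": blk.gamma, f"b{i}_beta": blk.beta,
                f"b{i}_rm": blk.run_mean, f"b{i}_rv": blk.run_var,
            })
        arrays["W_out"] = self.W_out
        arrays["b_out"] = self.b_out
        arrays["classes"] = self.classes_
        np.savez(path.with_suffix(".npz"), **arrays)
        cfg = self.config
        meta = {"conv_blocks": [list(b) for b in cfg.conv_blocks],
                "input_channels": cfg.input_channels,
                "n_classes": cfg.n_classes, "epochs": cfg.epochs,
                "batch_size": cfg.batch_size,
                "learning_rate": cfg.learning_rate,
                "val_fraction": cfg.val_fraction, "patience": cfg.patience,
                "downsample": cfg.downsample,
                "seed": cfg.seed, "history": self.history}
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "FcnClassifier":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        cfg = FcnConfig(
            conv_blocks=tuple(tuple(b) for b in meta["conv_blocks"]),
            input_channels=meta["input_channels"],
            n_classes=meta["n_classes"], epochs=meta["epochs"],
            batch_size=meta["batch_size"],
            learning_rate=meta["learning_rate"],
            val_fraction=meta["val_fraction"], patience=meta["patience"],
            downsample=meta.get("downsample", 1),
            seed=meta["seed"])
        model = cls(cfg)
        data = np.load(path.with_suffix(".npz"))
        for i, blk in enumerate(model.blocks):
            blk.W = data[f"b{i}_W"]
            blk.b = data[f"b{i}_b"]
            blk.gamma = data[f"b{i}_gamma"]
            blk.beta = data[f"b{i}_beta"]
            blk.run_mean = data[f"b{i}_rm"]
            blk.run_var = data[f"b{i}_rv"]
        model.W_out = data["W_out"]
        model.b_out = data["b_out"]
        model.classes_ = data["classes"]
        model.history = meta["history"]
        return model


# ---------------------------------------------------------------------------
# recording-level inference
# ---------------------------------------------------------------------------

@dataclass
class PredictionSeries:
    """Per-window class probabilities over a non-overlapping tiling."""

    patient_id: str
    session_id: str
    setting: str
    window_s: float
    start_times_s: np.ndarray          # offsets into the recording
    start_datetimes: list              # wall-clock window starts
    probabilities: np.ndarray          # (n_windows, n_classes)
    classes: np.ndarray                # column order of probabilities
    predicted: np.ndarray              # argmax class per window

    def __len__(self) -> int:
        return len(self.start_times_s)


def predict_recording(
    model: FcnClassifier,
    recording: ImuRecording,
    scaler: ChannelScaler | None = None,
    window_s: float = 10.0,
    stride_s: float = 10.0,
) -> PredictionSeries:
    """Run the classifier over a recording with a non-overlapping tiling.

    The inference stride defaults to the window length so each second of
    the recording is counted exactly once when predictions are later
    converted to participation minutes. A recording shorter than one
    window yields an empty series with a warning.
    """
    wins = segment_windows(recording, window_s=window_s, stride_s=stride_s)
    if not wins:
        warnings.warn(
            f"recording {recording.session_id} is shorter than one window; "
            "empty prediction series", stacklevel=2)
        return PredictionSeries(
            recording.patient_id, recording.session_id, recording.setting,
            window_s, np.empty(0), [],
            np.empty((0, model.config.n_classes)), model.classes_,
            np.empty(0, dtype=model.classes_.dtype))
    X = np.stack([w.values for w in wins]).astype(np.float32)
    if scaler is not None:
        X = ((X - scaler.mean[None, None, :]) / scaler.std[None, None, :]
             ).astype(np.float32)
    probs = model.predict_proba(X)
    pred = model.classes_[probs.argmax(axis=1)]
    return PredictionSeries(
        recording.patient_id, recording.session_id, recording.setting,
        window_s,
        np.array([w.start_s for w in wins]),
        [recording.time_at(w.start_s) for w in wins],
        probs, model.classes_, pred)
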