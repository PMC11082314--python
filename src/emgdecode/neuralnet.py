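"""Compact convolutional network for 4-class EMG epoch classification.

Architecture (input one E x S epoch, channels-last internally):

1. linear temporal convolution, 128 filters of shape (1 x 16), "same";
2. spatial convolution, 16 filters of shape (E x 1), "valid" (collapses
   the electrode axis), batch norm, ReLU, mean pooling (1 x 4), spatial
   dropout;
3. temporal convolution, 128 filters of shape (1 x 16), "same", batch
   norm, ReLU, mean pooling (1 x 4), spatial dropout;
4. two fully-connected layers of 128 neurons with ReLU;
5. fully-connected output layer of K neurons with softmax.

Weights are Glorot-uniform initialized, U(-sqrt(6/(n_in + n_out)),
+sqrt(6/(n_in + n_out))) with conv fan-in/fan-out counting the receptive
field; training minimizes categorical cross-entropy with Adam (default
starting learning rate 0.005, beta1 = 0.9, beta2 = 0.999, eps = 1e-8).

The network, its backward pass and the optimizer are implemented directly
on numpy arrays (float32), which is ample for epochs of this size on a
desktop CPU. Training is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from sklearn.base import BaseEstimator, ClassifierMixin

_PAD = (7, 8)  # "same" padding for a 16-tap kernel
KERNEL = 16
POOL = 4


@dataclass
class CnnSpec:
    """Hyperparameters of the gesture CNN."""

    n_temporal_filters: int = 128
    n_spatial_filters: int = 16
    n_dense: int = 128
    n_classes: int = 4
    dropout_rate: float = 0.25
    learning_rate: float = 0.005
    batch_size: int = 32
    max_epochs: int = 200
    patience: int = 20
    validation_fraction: float = 0.0
    seed: int = 0


def glorot_uniform(rng, shape, fan_in, fan_out):
    bound = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-bound, bound, size=shape).astype(np.float32)


def _pad_time(x):
    return np.pad(x, [(0, 0)] * (x.ndim - 1) + [_PAD])


def _fold_time(dcols, n_time):
    """Scatter-add im2col gradients back onto the padded time axis."""
    dxp = np.zeros(dcols.shape[:-2] + (n_time + sum(_PAD),), dtype=dcols.dtype)
    for m in range(KERNEL):
        dxp[..., m : m + n_time] += dcols[..., m]
    return dxp[..., _PAD[0] : _PAD[0] + n_time]


class _BatchNorm:
    """Per-channel batch normalization over (batch, time)."""

    def __init__(self, n_channels):
        self.gamma = np.ones(n_channels, dtype=np.float32)
        self.beta = np.zeros(n_channels, dtype=np.float32)
        self.run_mean = np.zeros(n_channels, dtype=np.float32)
        self.run_var = np.ones(n_channels, dtype=np.float32)
        self.momentum = 0.9
        self.eps = 1e-5

    def forward(self, x, training):
        # x: (N, C, T)
        if training:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.run_mean = self.momentum * self.run_mean + (1 - self.momentum) * mean
            self.run_var = self.momentum * self.run_var + (1 - self.momentum) * var
        else:
            mean, var = self.run_mean, self.run_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None]) * inv[None, :, None]
        self._cache = (xhat, inv)
        return self.gamma[None, :, None] * xhat + self.beta[None, :, None]

    def backward(self, dy):
        xhat, inv = self._cache
        dgamma = np.einsum("nct,nct->c", dy, xhat)
        dbeta = dy.sum(axis=(0, 2))
        n = dy.shape[0] * dy.shape[2]
        g = self.gamma[None, :, None] * inv[None, :, None]
        dx = g * (
            dy
            - dbeta[None, :, None] / n
            - xhat * dgamma[None, :, None] / n
        )
        return dx, dgamma, dbeta


class CnnNetwork:
    """The layer stack with forward, backward and Adam state."""

    def __init__(self, n_channels: int, n_samples: int, spec: CnnSpec):
        if n_samples % (POOL * POOL) != 0:
            raise ValueError(f"epoch length {n_samples} must be divisible by {POOL * POOL}")
        self.spec = spec
        self.n_channels = n_channels
        self.n_samples = n_samples
        e, f1, f2 = n_channels, spec.n_temporal_filters, spec.n_spatial_filters
        d = spec.n_dense
        k = spec.n_classes
        flat = f1 * (n_samples // (POOL * POOL))
        rng = np.random.default_rng(spec.seed)
        self.params = {
            "conv1_w": glorot_uniform(rng, (f1, KERNEL), KERNEL, f1 * KERNEL),
            "conv1_b": np.zeros(f1, dtype=np.float32),
            "conv2_w": glorot_uniform(rng, (f2, f1, e), f1 * e, f2 * e),
            "conv2_b": np.zeros(f2, dtype=np.float32),
            "conv3_w": glorot_uniform(rng, (f1, f2, KERNEL), f2 * KERNEL, f1 * KERNEL),
            "conv3_b": np.zeros(f1, dtype=np.float32),
            "fc1_w": glorot_uniform(rng, (flat, d), flat, d),
            "fc1_b": np.zeros(d, dtype=np.float32),
            "fc2_w": glorot_uniform(rng, (d, d), d, d),
            "fc2_b": np.zeros(d, dtype=np.float32),
            "out_w": glorot_uniform(rng, (d, k), d, k),
            "out_b": np.zeros(k, dtype=np.float32),
        }
        self.bn2 = _BatchNorm(f2)
        self.bn3 = _BatchNorm(f1)
        self._adam = None

    @property
    def n_parameters(self) -> int:
        n = sum(p.size for p in self.params.values())
        for bn in (self.bn2, self.bn3):
            n += bn.gamma.size + bn.beta.size
        return n

    # -- forward ----------------------------------------------------------

    def forward(self, x, training=False, rng=None):
        p = self.params
        x = np.ascontiguousarray(x, dtype=np.float32)
        n, e, s = x.shape
        c = {}
        # temporal conv 1 (linear): per electrode row
        cols1 = sliding_window_view(_pad_time(x), KERNEL, axis=-1)  # (N,E,S,16)
        y1 = cols1 @ p["conv1_w"].T + p["conv1_b"]  # (N,E,S,F1)
        c["cols1"] = cols1
        # spatial conv (valid over electrodes)
        y2 = np.einsum("nesc,oce->nos", y1, p["conv2_w"], optimize=True)
        y2 += p["conv2_b"][None, :, None]  # (N,F2,S)
        c["y1"] = y1
        y2 = self.bn2.forward(y2, training)
        relu2 = y2 > 0
        y2 = y2 * relu2
        c["relu2"] = relu2
        pool2 = y2.reshape(n, y2.shape[1], -1, POOL).mean(axis=3)  # (N,F2,S/4)
        if training and self.spec.dropout_rate > 0:
            mask2 = (rng.random((n, pool2.shape[1], 1)) >= self.spec.dropout_rate) / (
                1 - self.spec.dropout_rate
            )
            pool2 = pool2 * mask2
            c["mask2"] = mask2
        # temporal conv 2
        cols3 = sliding_window_view(_pad_time(pool2), KERNEL, axis=-1)  # (N,F2,T1,16)
        y3 = np.einsum("nctm,fcm->nft", cols3, p["conv3_w"], optimize=True)
        y3 += p["conv3_b"][None, :, None]
        c["cols3"] = cols3
        y3 = self.bn3.forward(y3, training)
        relu3 = y3 > 0
        y3 = y3 * relu3
        c["relu3"] = relu3
        pool3 = y3.reshape(n, y3.shape[1], -1, POOL).mean(axis=3)  # (N,F1,S/16)
        if training and self.spec.dropout_rate > 0:
            mask3 = (rng.random((n, pool3.shape[1], 1)) >= self.spec.dropout_rate) / (
                1 - self.spec.dropout_rate
            )
            pool3 = pool3 * mask3
            c["mask3"] = mask3
        flat = pool3.reshape(n, -1)
        c["flat"] = flat
        h1 = flat @ p["fc1_w"] + p["fc1_b"]
        r1 = h1 > 0
        h1 *= r1
        h2 = h1 @ p["fc2_w"] + p["fc2_b"]
        r2 = h2 > 0
        h2 *= r2
        logits = h2 @ p["out_w"] + p["out_b"]
        c.update(h1=h1, r1=r1, h2=h2, r2=r2, pool3_shape=pool3.shape, y2_shape=y2.shape)
        self._cache = c
        return logits

    def predict_proba(self, x, batch_size=256):
        out = []
        for i in range(0, len(x), batch_size):
            logits = self.forward(x[i : i + batch_size], training=False)
            out.append(_softmax(logits))
        return np.concatenate(out)

    # -- backward ---------------------------------------------------------

    def backward(self, dlogits):
        p, c = self.params, self._cache
        g = {}
        g["out_w"] = c["h2"].T @ dlogits
        g["out_b"] = dlogits.sum(axis=0)
        dh2 = (dlogits @ p["out_w"].T) * c["r2"]
        g["fc2_w"] = c["h1"].T @ dh2
        g["fc2_b"] = dh2.sum(axis=0)
        dh1 = (dh2 @ p["fc2_w"].T) * c["r1"]
        g["fc1_w"] = c["flat"].T @ dh1
        g["fc1_b"] = dh1.sum(axis=0)
        dpool3 = (dh1 @ p["fc1_w"].T).reshape(c["pool3_shape"])
        if "mask3" in c:
            dpool3 = dpool3 * c["mask3"]
        dy3 = np.repeat(dpool3 / POOL, POOL, axis=2) * c["relu3"]
        dy3, g["bn3_gamma"], g["bn3_beta"] = self.bn3.backward(dy3)
        g["conv3_w"] = np.einsum("nft,nctm->fcm", dy3, c["cols3"], optimize=True)
        g["conv3_b"] = dy3.sum(axis=(0, 2))
        dcols3 = np.einsum("nft,fcm->nctm", dy3, p["conv3_w"], optimize=True)
        dpool2 = _fold_time(dcols3, c["cols3"].shape[2])
        if "mask2" in c:
            dpool2 = dpool2 * c["mask2"]
        dy2 = np.repeat(dpool2 / POOL, POOL, axis=2) * c["relu2"]
        dy2, g["bn2_gamma"], g["bn2_beta"] = self.bn2.backward(dy2)
        g["conv2_w"] = np.einsum("nos,nesc->oce", dy2, c["y1"], optimize=True)
        g["conv2_b"] = dy2.sum(axis=(0, 2))
        dy1 = np.einsum("nos,oce->nesc", dy2, p["conv2_w"], optimize=True)
        g["conv1_w"] = np.einsum("nesm,nesf->fm", c["cols1"], dy1, optimize=True)
        g["conv1_b"] = dy1.sum(axis=(0, 1, 2))
        return g

    # -- Adam -------------------------------------------------------------

    def adam_step(self, grads, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        bn_params = {
            "bn2_gamma": self.bn2.gamma,
            "bn2_beta": self.bn2.beta,
            "bn3_gamma": self.bn3.gamma,
            "bn3_beta": self.bn3.beta,
        }
        if self._adam is None:
            self._adam = {
                "t": 0,
                "m": {k: np.zeros_like(v) for k, v in {**self.params, **bn_params}.items()},
                "v": {k: np.zeros_like(v) for k, v in {**self.params, **bn_params}.items()},
            }
        st = self._adam
        st["t"] += 1
        t = st["t"]
        for k, grad in grads.items():
            target = self.params[k] if k in self.params else bn_params[k]
            st["m"][k] = beta1 * st["m"][k] + (1 - beta1) * grad
            st["v"][k] = beta2 * st["v"][k] + (1 - beta2) * grad**2
            mhat = st["m"][k] / (1 - beta1**t)
            vhat = st["v"][k] / (1 - beta2**t)
            target -= (lr * mhat / (np.sqrt(vhat) + eps)).astype(np.float32)


def _softmax(logits):
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def build_cnn(n_channels: int, n_samples: int, spec: CnnSpec | None = None) -> CnnNetwork:
    """Instantiate the layer stack for E x S epochs."""
    return CnnNetwork(n_channels, n_samples, spec or CnnSpec())


def train_cnn(net: CnnNetwork, X, y_idx, spec: CnnSpec | None = None) -> dict:
    """Adam / cross-entropy training loop; returns the loss history.

    ``y_idx`` are integer class indices. With ``validation_fraction`` > 0
    a tail split is held out and early stopping monitors its loss with the
    configured patience. Raises on divergence (non-finite loss).
    """
    spec = spec or net.spec
    X = np.ascontiguousarray(X, dtype=np.float32)
    y_idx = np.asarray(y_idx)
    rng = np.random.default_rng(spec.seed + 1)
    n_val = int(round(spec.validation_fraction * len(X)))
    if n_val:
        perm = rng.permutation(len(X))
        X, y_idx = X[perm], y_idx[perm]
        X_val, y_val = X[-n_val:], y_idx[-n_val:]
        X, y_idx = X[:-n_val], y_idx[:-n_val]
    history = {"loss": [], "val_loss": []}
    best_val, best_epoch = np.inf, 0
    n = len(X)
    k = spec.n_classes
    onehot = np.eye(k, dtype=np.float32)
    for epoch in range(spec.max_epochs):
        order = rng.permutation(n)
        losses = []
        for i in range(0, n, spec.batch_size):
            idx = order[i : i + spec.batch_size]
            xb, yb = X[idx], y_idx[idx]
            logits = net.forward(xb, training=True, rng=rng)
            proba = _softmax(logits)
            loss = -np.mean(np.log(proba[np.arange(len(yb)), yb] + 1e-12))
            if not np.isfinite(loss):
                raise RuntimeError(f"training diverged at epoch {epoch} (loss={loss})")
            losses.append(loss)
            dlogits = (proba - onehot[yb]) / len(yb)
            grads = net.backward(dlogits)
            net.adam_step(grads, lr=spec.learning_rate)
        history["loss"].append(float(np.mean(losses)))
        if n_val:
            val_proba = net.predict_proba(X_val)
            val_loss = -np.mean(np.log(val_proba[np.arange(n_val), y_val] + 1e-12))
            history["val_loss"].append(float(val_loss))
            if val_loss < best_val - 1e-5:
                best_val, best_epoch = val_loss, epoch
            elif epoch - best_epoch >= spec.patience:
                break
    return history


class EmgCnnClassifier(BaseEstimator, ClassifierMixin):
    """scikit-learn front end for the gesture CNN.

    Accepts (N, E, S) epochs with S divisible by 16 (two x4 mean
    poolings). Deterministic given ``seed``.
    """

    def __init__(
        self,
        dropout_rate: float = 0.25,
        learning_rate: float = 0.005,
        batch_size: int = 32,
        max_epochs: int = 200,
        patience: int = 20,
        validation_fraction: float = 0.0,
        seed: int = 0,
    ):
        self.dropout_rate = dropout_rate
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.validation_fraction = validation_fraction
        self.seed = seed

    def _spec(self, n_classes):
        return CnnSpec(
            n_classes=n_classes,
            dropout_rate=self.dropout_rate,
            learning_rate=self.learning_rate,
            batch_size=self.batch_size,
            max_epochs=self.max_epochs,
            patience=self.patience,
            validation_fraction=self.validation_fraction,
            seed=self.seed,
        )

    def fit(self, X, y):
        X = np.asarray(X)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if self.classes_.size < 2:
            raise ValueError("need at least 2 classes")
        y_idx = np.searchsorted(self.classes_, y)
        spec = self._spec(self.classes_.size)
        self.network_ = CnnNetwork(X.shape[1], X.shape[2], spec)
        self.history_ = train_cnn(self.network_, X, y_idx, spec)
        return self

    def predict_proba(self, X):
        return self.network_.predict_proba(np.asarray(X))

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]
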