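"""A small 1-D convolutional network on triaxial acceleration windows.

Implemented directly in numpy with im2col convolutions and Adam.  The
architecture is deliberately tiny — two convolution blocks (16 then 32
filters, kernel 5, ReLU, max-pool 2), global average pooling, and a
2-way softmax — sized for CPU training on cohort-scale window sets.

`WindowCNNClassifier` follows the scikit-learn estimator protocol
(fit/predict/predict_proba, get_params/set_params) except that its input
is a 3-D array of shape (n_windows, n_samples, 3).
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(N, T, C) -> (N, T-k+1, k*C) sliding patches."""
    n, t, c = x.shape
    idx = np.arange(t - k + 1)[:, None] + np.arange(k)[None, :]
    return x[:, idx, :].reshape(n, t - k + 1, k * c)


def _col2im(dcol: np.ndarray, t: int, k: int, c: int) -> np.ndarray:
    """Adjoint of `_im2col`: scatter patch gradients back to the signal."""
    n, length, _ = dcol.shape
    dcol = dcol.reshape(n, length, k, c)
    dx = np.zeros((n, t, c), dtype=dcol.dtype)
    for j in range(k):
        dx[:, j : j + length, :] += dcol[:, :, j, :]
    return dx


class _Conv1D:
    """Valid-mode 1-D convolution, He-initialized."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (k * c_in))
        self.W = rng.normal(0.0, scale, size=(k * c_in, c_out))
        self.b = np.zeros(c_out)
        self.k, self.c_in = k, c_in

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x_shape = x.shape
        self._cols = _im2col(x, self.k)
        return self._cols @ self.W + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, length, c_out = dy.shape
        flat_cols = self._cols.reshape(-1, self.W.shape[0])
        self.dW = flat_cols.T @ dy.reshape(-1, c_out)
        self.db = dy.sum(axis=(0, 1))
        dcol = dy @ self.W.T
        return _col2im(dcol, self._x_shape[1], self.k, self.c_in)

    def params(self):
        return [("W", self), ("b", self)]


class _Adam:
    """Adam over a flat list of (layer, attr) parameter slots."""

    def __init__(self, slots, lr: float = 1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.slots = slots
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(getattr(layer, attr)) for layer, attr in slots]
        self.v = [np.zeros_like(getattr(layer, attr)) for layer, attr in slots]
        self.t = 0

    def step(self):
        self.t += 1
        for i, (layer, attr) in enumerate(self.slots):
            g = getattr(layer, "d" + attr)
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p = getattr(layer, attr)
            setattr(layer, attr, p - self.lr * mhat / (np.sqrt(vhat) + self.eps))


class _Dense:
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.W = rng.normal(0.0, np.sqrt(2.0 / d_in), size=(d_in, d_out))
        self.b = np.zeros(d_out)

    def forward(self, x):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dy):
        self.dW = self._x.T @ dy
        self.db = dy.sum(axis=0)
        return dy @ self.W.T


def _maxpool2(x):
    n, t, c = x.shape
    t2 = t - (t % 2)
    xr = x[:, :t2].reshape(n, t2 // 2, 2, c)
    arg = xr.argmax(axis=2)
    return xr.max(axis=2), (arg, t, t2)


def _maxpool2_back(dy, cache):
    arg, t, t2 = cache
    n, half, c = dy.shape
    dx = np.zeros((n, t, c), dtype=dy.dtype)
    dr = dx[:, :t2].reshape(n, half, 2, c)
    np.put_along_axis(dr, arg[:, :, None, :], dy[:, :, None, :], axis=2)
    dx[:, :t2] = dr.reshape(n, t2, c)
    return dx


class WindowCNNClassifier(ClassifierMixin, BaseEstimator):
    """Per-window binary classifier for fixed-length triaxial windows.

    Parameters
    ----------
    n_filters : tuple of int
        Channels of the two convolution blocks.
    kernel_size : int
        Convolution kernel length in samples.
    epochs : int
        Maximum training epochs; training stops early when the epoch
        loss plateaus (relative improvement < `tol` for `patience`
        consecutive epochs).
    batch_size, learning_rate : usual Adam minibatch settings.
    random_state : int
        Seeds weight initialization and shuffling; training is fully
        deterministic given the seed.

    Attributes
    ----------
    classes_ : ndarray of the two labels, sorted.
    channel_mean_, channel_std_ : per-channel training statistics used
        to standardize inputs (computed from the training windows only).
    loss_history_ : per-epoch mean cross-entropy.
    """

    def __init__(
        self,
        n_filters=(16, 32),
        kernel_size: int = 5,
        epochs: int = 30,
        batch_size: int = 64,
        learning_rate: float = 1e-3,
        tol: float = 1e-4,
        patience: int = 5,
        random_state: int = 0,
    ):
        self.n_filters = n_filters
        self.kernel_size = kernel_size
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.tol = tol
        self.patience = patience
        self.random_state = random_state

    # -- internals ---------------------------------------------------------

    def _forward(self, x, train=False):
        h = self.conv1_.forward(x)
        self._m1 = h > 0
        h = h * self._m1
        h, self._p1 = _maxpool2(h)
        h = self.conv2_.forward(h)
        self._m2 = h > 0
        h = h * self._m2
        h, self._p2 = _maxpool2(h)
        self._gap_len = h.shape[1]
        g = h.mean(axis=1)
        return self.dense_.forward(g)

    def _backward(self, dlogits):
        dg = self.dense_.backward(dlogits)
        dh = np.repeat(dg[:, None, :], self._gap_len, axis=1) / self._gap_len
        dh = _maxpool2_back(dh, self._p2)
        dh = self.conv2_.backward(dh * self._m2)
        dh = _maxpool2_back(dh, self._p1)
        self.conv1_.backward(dh * self._m1)

    def _standardize(self, X):
        return (X - self.channel_mean_) / self.channel_std_

    # -- estimator API -----------------------------------------------------

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 3:
            raise ValueError("X must be (n_windows, n_samples, n_channels)")
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError("training windows must contain exactly 2 classes")
        yi = np.searchsorted(self.classes_, y)

        self.channel_mean_ = X.mean(axis=(0, 1), keepdims=True)
        self.channel_std_ = X.std(axis=(0, 1), keepdims=True)
        self.channel_std_[self.channel_std_ == 0] = 1.0
        Xs = self._standardize(X)

        rng = np.random.default_rng(self.random_state)
        c_in = X.shape[2]
        f1, f2 = self.n_filters
        self.conv1_ = _Conv1D(c_in, f1, self.kernel_size, rng)
        self.conv2_ = _Conv1D(f1, f2, self.kernel_size, rng)
        self.dense_ = _Dense(f2, 2, rng)
        slots = [
            (self.conv1_, "W"), (self.conv1_, "b"),
            (self.conv2_, "W"), (self.conv2_, "b"),
            (self.dense_, "W"), (self.dense_, "b"),
        ]
        opt = _Adam(slots, lr=self.learning_rate)

        n = len(Xs)
        self.loss_history_ = []
        stall = 0
        best = np.inf
        for _epoch in range(self.epochs):
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                logits = self._forward(Xs[idx], train=True)
                logits -= logits.max(axis=1, keepdims=True)
                p = np.exp(logits)
                p /= p.sum(axis=1, keepdims=True)
                yb = yi[idx]
                losses.append(-np.mean(np.log(p[np.arange(len(idx)), yb] + 1e-12)))
                dlogits = p.copy()
                dlogits[np.arange(len(idx)), yb] -= 1.0
                dlogits /= len(idx)
                self._backward(dlogits)
                opt.step()
            epoch_loss = float(np.mean(losses))
            self.loss_history_.append(epoch_loss)
            if epoch_loss < best * (1 - self.tol):
                best = epoch_loss
                stall = 0
            else:
                stall += 1
                if stall >= self.patience:
                    break
        return self

    def decision_scores(self, X):
        check_is_fitted(self)
        X = self._standardize(np.asarray(X, dtype=float))
        out = []
        for start in range(0, len(X), 512):
            out.append(self._forward(X[start : start + 512]))
        return np.vstack(out)

    def predict_proba(self, X):
        logits = self.decision_scores(X)
        logits -= logits.max(axis=1, keepdims=True)
        p = np.exp(logits)
        return p / p.sum(axis=1, keepdims=True)

    def predict(self, X):
        return self.classes_[self.decision_scores(X).argmax(axis=1)]
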