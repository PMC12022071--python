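"""Minimal numpy convolutional network used by the plaque classifier.

Implements exactly the pieces the morphotype classifier needs — 3x3
same-padding convolution (im2col), batch normalisation, ReLU, 2x2 max
pooling, dense layers, inverted dropout, a softmax cross-entropy head and
the Adam optimizer with a stepwise learning-rate decay.  Arrays are NHWC
float32; the implementation favours large BLAS matmuls so CPU training of
the small plaque-patch model stays in the minutes range.
"""

from __future__ import annotations

import numpy as np

__all__ = ["SmallCNN", "softmax", "Adam"]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _he_init(rng, shape, fan_in):
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)


class _Conv3x3:
    """3x3 stride-1 convolution with zero padding 1 (shape-preserving)."""

    def __init__(self, rng, c_in, c_out):
        self.W = _he_init(rng, (9 * c_in, c_out), 9 * c_in)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    @staticmethod
    def _im2col(x):
        n, h, w, c = x.shape
        xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
        cols = np.empty((n, h, w, 3, 3, c), dtype=x.dtype)
        for ki in range(3):
            for kj in range(3):
                cols[:, :, :, ki, kj, :] = xp[:, ki : ki + h, kj : kj + w, :]
        return cols.reshape(n * h * w, 9 * c)

    def forward(self, x, train):
        self._shape = x.shape
        self._cols = self._im2col(x)
        n, h, w, _ = x.shape
        out = self._cols @ self.W + self.b
        return out.reshape(n, h, w, -1)

    def backward(self, dout):
        n, h, w, c = self._shape
        dm = dout.reshape(n * h * w, -1)
        self.grads[0][...] = self._cols.T @ dm
        self.grads[1][...] = dm.sum(axis=0)
        dcols = (dm @ self.W.T).reshape(n, h, w, 3, 3, c)
        dxp = np.zeros((n, h + 2, w + 2, c), dtype=dout.dtype)
        for ki in range(3):
            for kj in range(3):
                dxp[:, ki : ki + h, kj : kj + w, :] += dcols[:, :, :, ki, kj, :]
        self._cols = None
        return dxp[:, 1:-1, 1:-1, :]


class _BatchNorm:
    def __init__(self, c, momentum=0.9, eps=1e-5):
        self.gamma = np.ones(c, dtype=np.float32)
        self.beta = np.zeros(c, dtype=np.float32)
        self.params = [self.gamma, self.beta]
        self.grads = [np.zeros_like(self.gamma), np.zeros_like(self.beta)]
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self.momentum, self.eps = momentum, eps
        self._seen = False  # first batch seeds the running statistics

    def forward(self, x, train):
        axes = tuple(range(x.ndim - 1))
        if train:
            xr = x.reshape(-1, x.shape[-1])
            mean = xr.mean(axis=0)
            var = np.einsum("nc,nc->c", xr, xr, optimize=True) / xr.shape[0] \
                - mean * mean
            if not self._seen:
                self.running_mean = mean.astype(np.float32)
                self.running_var = var.astype(np.float32)
                self._seen = True
            else:
                self.running_mean = (self.momentum * self.running_mean
                                     + (1 - self.momentum) * mean
                                     ).astype(np.float32)
                self.running_var = (self.momentum * self.running_var
                                    + (1 - self.momentum) * var
                                    ).astype(np.float32)
        else:
            mean, var = self.running_mean, self.running_var
        self._istd = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mean) * self._istd
        self._axes = axes
        self._m = x.size // x.shape[-1]
        return self.gamma * self._xhat + self.beta

    def backward(self, dout):
        self.grads[0][...] = (dout * self._xhat).sum(axis=self._axes)
        self.grads[1][...] = dout.sum(axis=self._axes)
        dxhat = dout * self.gamma
        m = self._m
        dx = (self._istd / m) * (
            m * dxhat
            - dxhat.sum(axis=self._axes)
            - self._xhat * (dxhat * self._xhat).sum(axis=self._axes)
        )
        self._xhat = None
        return dx.astype(np.float32)


class _ReLU:
    params: list = []
    grads: list = []

    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        out = dout * self._mask
        self._mask = None
        return out


class _MaxPool2:
    params: list = []
    grads: list = []

    def forward(self, x, train):
        n, h, w, c = x.shape
        xr = x.reshape(n, h // 2, 2, w // 2, 2, c)
        out = xr.max(axis=(2, 4))
        self._mask = xr == out[:, :, None, :, None, :]
        return out

    def backward(self, dout):
        dx = self._mask * dout[:, :, None, :, None, :]
        self._mask = None
        n, hh, _, ww, _, c = dx.shape
        return dx.reshape(n, hh * 2, ww * 2, c)


class _Flatten:
    params: list = []
    grads: list = []

    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class _Dense:
    def __init__(self, rng, d_in, d_out):
        self.W = _he_init(rng, (d_in, d_out), d_in)
        self.b = np.zeros(d_out, dtype=np.float32)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, train):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout):
        self.grads[0][...] = self._x.T @ dout
        self.grads[1][...] = dout.sum(axis=0)
        dx = dout @ self.W.T
        self._x = None
        return dx


class _Dropout:
    params: list = []
    grads: list = []

    def __init__(self, rate, rng):
        self.rate, self.rng = rate, rng

    def forward(self, x, train):
        if not train or self.rate <= 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class Adam:
    """Adam with a stepwise-decayed learning rate (factor per 10 epochs)."""

    def __init__(self, params, lr=1e-3, decay=0.96, decay_every=10,
                 beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr0, self.decay, self.decay_every = lr, decay, decay_every
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def lr_at(self, epoch: int) -> float:
        return self.lr0 * self.decay ** (epoch // self.decay_every)

    def step(self, grads, epoch: int):
        self.t += 1
        lr = self.lr_at(epoch)
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p -= lr * mhat / (np.sqrt(vhat) + self.eps)


class SmallCNN:
    """Conv(3x3)/BN/ReLU/maxpool blocks -> dense -> dropout -> softmax head.

    Default widths (32, 64, 128) with a 128-unit dense layer; widths are
    configurable so unit tests can run a narrow smoke-scale model.  Input is
    ``(n, size, size, 1)`` float32 in [0, 1]; ``size`` must be divisible by
    ``2**len(filters)``.
    """

    def __init__(self, n_classes=3, filters=(32, 64, 128), dense_units=128,
                 dropout=0.5, input_size=120, seed=0):
        rng = np.random.default_rng(seed)
        self.input_size = input_size
        self.n_classes = n_classes
        layers = []
        c_in, size = 1, input_size
        for f in filters:
            layers += [_Conv3x3(rng, c_in, f), _BatchNorm(f), _ReLU(), _MaxPool2()]
            c_in = f
            if size % 2:
                raise ValueError("input size must halve cleanly at every pool")
            size //= 2
        layers += [
            _Flatten(),
            _Dense(rng, size * size * c_in, dense_units),
            _ReLU(),
            _Dropout(dropout, rng),
            _Dense(rng, dense_units, n_classes),
        ]
        self.layers = layers

    # -- plumbing -----------------------------------------------------------
    @property
    def params(self):
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self):
        return [g for layer in self.layers for g in layer.grads]

    def forward(self, x, train=False):
        out = np.asarray(x, dtype=np.float32)
        if out.ndim == 3:
            out = out[..., None]
        for layer in self.layers:
            out = layer.forward(out, train)
        return out

    def predict_proba(self, x, batch_size=64):
        x = np.asarray(x, dtype=np.float32)
        outs = [softmax(self.forward(x[i : i + batch_size], train=False))
                for i in range(0, len(x), batch_size)]
        return np.concatenate(outs, axis=0)

    def get_state(self) -> list[np.ndarray]:
        """All learnable parameters plus batch-norm running statistics."""
        state = [p.copy() for p in self.params]
        for layer in self.layers:
            if isinstance(layer, _BatchNorm):
                state += [layer.running_mean.copy(), layer.running_var.copy()]
        return state

    def set_state(self, state: list[np.ndarray]) -> None:
        n = len(self.params)
        for p, s in zip(self.params, state[:n]):
            p[...] = s
        rest = iter(state[n:])
        for layer in self.layers:
            if isinstance(layer, _BatchNorm):
                layer.running_mean = next(rest).astype(np.float32)
                layer.running_var = next(rest).astype(np.float32)

    def loss_and_grad(self, x, y_onehot):
        """Categorical cross-entropy; runs forward (train mode) + backward."""
        logits = self.forward(x, train=True)
        probs = softmax(logits)
        n = len(x)
        loss = -np.log(np.clip(probs[np.arange(n), y_onehot.argmax(1)],
                               1e-12, None)).mean()
        dlogits = (probs - y_onehot).astype(np.float32) / n
        dout = dlogits
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return float(loss)
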