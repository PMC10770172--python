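"""Minimal NumPy CNN engine for the two small convolutional decks.

Implements exactly the layer vocabulary the deck architectures need — valid
3x3 convolutions, batch normalisation, 2x2 max pooling, dropout, dense layers,
ReLU, and softmax/sigmoid heads with cross-entropy losses — together with Adam
and Adamax optimisers and full backpropagation. Tensors are NHWC float64.
Everything is seeded through ``numpy.random.Generator``; there is no global
state, so identical seeds give bit-identical training runs.
"""

from __future__ import annotations

import numpy as np

from .errors import InvalidArchitectureError


def pool_output_size(n: int, f: int, stride: int, *, literal: bool = False):
    """Output extent of a pooling/convolution stage along one dimension.

    The executable form is ``floor((n - f) / stride) + 1``.  ``literal=True``
    returns the expository textbook form ``(n - f + 1) / stride`` as a float;
    for a 2x2 pool with stride 2 that form is non-integral, which is why the
    floor form is the one the layer stack actually uses.
    """
    if literal:
        return (n - f + 1) / stride
    return (n - f) // stride + 1


class Layer:
    params: list
    grads: list

    def __init__(self):
        self.params = []
        self.grads = []

    def forward(self, x, training):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, grad):  # pragma: no cover - interface
        raise NotImplementedError


class Conv2D(Layer):
    """Valid convolution, stride 1, square kernel, NHWC."""

    def __init__(self, in_ch, out_ch, ksize, rng):
        super().__init__()
        self.k = ksize
        scale = np.sqrt(2.0 / (in_ch * ksize * ksize))
        self.W = rng.normal(0.0, scale, size=(out_ch, in_ch, ksize, ksize))
        self.b = np.zeros(out_ch)
        self.params = ["W", "b"]

    def forward(self, x, training):
        k = self.k
        n, h, w, c = x.shape
        oh, ow = h - k + 1, w - k + 1
        if oh < 1 or ow < 1:
            raise InvalidArchitectureError(
                f"feature map {h}x{w} too small for a {k}x{k} convolution"
            )
        self._x = x
        y = np.zeros((n, oh, ow, self.W.shape[0]))
        for i in range(k):
            for j in range(k):
                # (n,oh,ow,c) @ (c,out)
                y += x[:, i : i + oh, j : j + ow, :] @ self.W[:, :, i, j].T
        return y + self.b

    def backward(self, grad):
        k = self.k
        x = self._x
        n, h, w, c = x.shape
        oh, ow = grad.shape[1], grad.shape[2]
        dW = np.zeros_like(self.W)
        dx = np.zeros_like(x)
        for i in range(k):
            for j in range(k):
                patch = x[:, i : i + oh, j : j + ow, :]
                dW[:, :, i, j] = np.einsum("nhwc,nhwo->oc", patch, grad)
                dx[:, i : i + oh, j : j + ow, :] += grad @ self.W[:, :, i, j]
        self.dW = dW
        self.db = grad.sum(axis=(0, 1, 2))
        return dx


class BatchNorm(Layer):
    """Per-channel batch normalisation (NHWC), momentum 0.9."""

    def __init__(self, channels, momentum=0.9, eps=1e-5):
        super().__init__()
        self.gamma = np.ones(channels)
        self.beta = np.zeros(channels)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum = momentum
        self.eps = eps
        self.params = ["gamma", "beta"]

    def forward(self, x, training):
        axes = tuple(range(x.ndim - 1))
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mean) / self._std
        self._m = int(np.prod([x.shape[a] for a in axes]))
        return self.gamma * self._xhat + self.beta

    def backward(self, grad):
        axes = tuple(range(grad.ndim - 1))
        xhat, std, m = self._xhat, self._std, self._m
        self.dgamma = (grad * xhat).sum(axis=axes)
        self.dbeta = grad.sum(axis=axes)
        dxhat = grad * self.gamma
        return (dxhat - dxhat.mean(axis=axes) - xhat * (dxhat * xhat).mean(axis=axes)) / std


class ReLU(Layer):
    def forward(self, x, training):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class MaxPool2(Layer):
    """2x2 max pooling, stride 2; odd trailing rows/columns are dropped."""

    def forward(self, x, training):
        n, h, w, c = x.shape
        oh, ow = h // 2, w // 2
        if oh < 1 or ow < 1:
            raise InvalidArchitectureError(f"feature map {h}x{w} too small for 2x2 pooling")
        self._in_shape = x.shape
        r = x[:, : oh * 2, : ow * 2, :].reshape(n, oh, 2, ow, 2, c)
        r = r.transpose(0, 1, 3, 2, 4, 5).reshape(n, oh, ow, 4, c)
        self._arg = r.argmax(axis=3)
        return np.take_along_axis(r, self._arg[:, :, :, None, :], axis=3)[:, :, :, 0, :]

    def backward(self, grad):
        n, h, w, c = self._in_shape
        oh, ow = h // 2, w // 2
        dr = np.zeros((n, oh, ow, 4, c))
        np.put_along_axis(dr, self._arg[:, :, :, None, :], grad[:, :, :, None, :], axis=3)
        dx = np.zeros(self._in_shape)
        dx[:, : oh * 2, : ow * 2, :] = (
            dr.reshape(n, oh, ow, 2, 2, c).transpose(0, 1, 3, 2, 4, 5).reshape(n, oh * 2, ow * 2, c)
        )
        return dx


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate, rng):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise InvalidArchitectureError(f"dropout rate {rate} outside [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x, training):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class Flatten(Layer):
    def forward(self, x, training):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Dense(Layer):
    def __init__(self, in_units, out_units, rng):
        super().__init__()
        self.W = rng.normal(0.0, np.sqrt(2.0 / in_units), size=(in_units, out_units))
        self.b = np.zeros(out_units)
        self.params = ["W", "b"]

    @property
    def units(self):
        return self.W.shape[1]

    def forward(self, x, training):
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad):
        self.dW = self._x.T @ grad
        self.db = grad.sum(axis=0)
        return grad @ self.W.T


class Softmax(Layer):
    """Softmax head; with cross-entropy the combined gradient is (p - y)/n."""

    def forward(self, x, training):
        z = x - x.max(axis=1, keepdims=True)
        e = np.exp(z)
        self._p = e / e.sum(axis=1, keepdims=True)
        return self._p

    def backward(self, grad):
        # grad already folded with the loss: caller passes (p - y) / n
        return grad


class Sigmoid(Layer):
    def forward(self, x, training):
        self._p = 1.0 / (1.0 + np.exp(-x))
        return self._p

    def backward(self, grad):
        return grad


class Sequential:
    """A plain layer stack with a probabilistic 2-unit head.

    ``head`` is "softmax" (deck one) or "sigmoid" (deck two); both heads are
    trained against one-hot targets with (binary) cross-entropy, for which the
    fused head+loss gradient is ``(p - y) / n``.
    """

    def __init__(self, layers, head):
        self.layers = layers
        self.head = head

    def forward(self, x, training=False):
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def predict_proba(self, x):
        return self.forward(np.asarray(x, dtype=float), training=False)

    def loss_and_grad(self, x, y_onehot):
        p = self.forward(x, training=True)
        eps = 1e-12
        n = x.shape[0]
        loss = -np.mean(np.sum(y_onehot * np.log(p + eps) + (1 - y_onehot) * np.log(1 - p + eps), axis=1)) \
            if self.head == "sigmoid" else -np.mean(np.sum(y_onehot * np.log(p + eps), axis=1))
        grad = (p - y_onehot) / n
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return loss

    def parameters(self):
        out = []
        for layer in self.layers:
            for name in layer.params:
                out.append((layer, name))
        return out


class _MomentOptimizer:
    def __init__(self, model, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.model = model
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = {}
        self.v = {}
        for layer, name in model.parameters():
            self.m[(id(layer), name)] = np.zeros_like(getattr(layer, name))
            self.v[(id(layer), name)] = np.zeros_like(getattr(layer, name))

    def step(self):
        self.t += 1
        for layer, name in self.model.parameters():
            g = getattr(layer, "d" + name)
            key = (id(layer), name)
            m = self.m[key] = self.beta1 * self.m[key] + (1 - self.beta1) * g
            mhat = m / (1 - self.beta1**self.t)
            self._apply(layer, name, key, g, mhat)

    def _apply(self, layer, name, key, g, mhat):  # pragma: no cover - interface
        raise NotImplementedError


class Adam(_MomentOptimizer):
    def _apply(self, layer, name, key, g, mhat):
        v = self.v[key] = self.beta2 * self.v[key] + (1 - self.beta2) * g * g
        vhat = v / (1 - self.beta2**self.t)
        setattr(layer, name, getattr(layer, name) - self.lr * mhat / (np.sqrt(vhat) + self.eps))


class Adamax(_MomentOptimizer):
    def _apply(self, layer, name, key, g, mhat):
        u = self.v[key] = np.maximum(self.beta2 * self.v[key], np.abs(g))
        setattr(layer, name, getattr(layer, name) - self.lr * mhat / (u + self.eps))


def train(model, images, labels, *, epochs, batch_size, learning_rate, seed, optimizer="adam"):
    """Mini-batch training; returns the per-epoch mean training loss.

    ``images`` are float arrays scaled to [0, 1], NHWC; ``labels`` binary.
    ``epochs=0`` leaves the model untouched and returns an empty history.
    """
    x = np.asarray(images, dtype=float)
    y = np.asarray(labels, dtype=int)
    onehot = np.eye(2)[y]
    opt_cls = {"adam": Adam, "adamax": Adamax}[optimizer]
    opt = opt_cls(model, learning_rate)
    rng = np.random.default_rng(seed)
    history = []
    for _ in range(epochs):
        order = rng.permutation(len(x))
        losses = []
        for start in range(0, len(x), batch_size):
            idx = order[start : start + batch_size]
            losses.append(model.loss_and_grad(x[idx], onehot[idx]))
            opt.step()
        history.append(float(np.mean(losses)))
    return history
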