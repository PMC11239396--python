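"""Minimal feed-forward network framework (NumPy).

Provides the layer kinds needed by the modality CNNs and the relevance
engine: dense, 1D convolution, max/average pooling, ReLU and flatten.
Layers cache their inputs on forward passes so that both gradient
backpropagation (training) and relevance propagation (attribution) can
revisit the exact activations of a pass.

Conventions
-----------
* Dense layers operate on ``(n, features)`` arrays, weights ``(in, out)``.
* Conv1d layers operate on ``(n, channels, length)`` arrays, weights
  ``(out_channels, in_channels, kernel)``, valid padding.
* All computations are float64; training is deterministic given a seed.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Dense",
    "Conv1d",
    "ReLU",
    "Flatten",
    "MaxPool1d",
    "AvgPool1d",
    "Network",
    "train_network",
]


class Layer:
    """Base layer: subclasses set ``kind`` and implement forward/backward."""

    kind = "abstract"
    #: parameters as {name: array}; empty for parameter-free layers
    params: dict

    def __init__(self):
        self.params = {}
        self.grads = {}
        self.cache = None

    def forward(self, x):  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, grad):  # pragma: no cover - abstract
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, n_in, n_out, rng=None, bias=True):
        super().__init__()
        self.kind = "dense"
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / n_in)
        self.params = {"W": rng.normal(0.0, scale, size=(n_in, n_out))}
        if bias:
            self.params["b"] = np.zeros(n_out)

    def forward(self, x):
        self.cache = x
        out = x @ self.params["W"]
        if "b" in self.params:
            out = out + self.params["b"]
        return out

    def backward(self, grad):
        x = self.cache
        self.grads["W"] = x.T @ grad
        if "b" in self.params:
            self.grads["b"] = grad.sum(axis=0)
        return grad @ self.params["W"].T


class Conv1d(Layer):
    """Valid-padding 1D convolution over ``(n, c_in, length)`` input."""

    def __init__(self, c_in, c_out, kernel, stride=1, rng=None, bias=True):
        super().__init__()
        self.kind = "conv1d"
        self.kernel = kernel
        self.stride = stride
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / (c_in * kernel))
        self.params = {"W": rng.normal(0.0, scale, size=(c_out, c_in, kernel))}
        if bias:
            self.params["b"] = np.zeros(c_out)

    def out_length(self, length):
        return (length - self.kernel) // self.stride + 1

    def _windows(self, x):
        """Stack kernel-offset views: (n, c_in, kernel, out_len)."""
        lo = self.out_length(x.shape[-1])
        s = self.stride
        return np.stack(
            [x[:, :, k : k + lo * s : s] for k in range(self.kernel)], axis=2
        )

    def forward(self, x):
        self.cache = x
        xs = self._windows(x)
        out = np.einsum("nckl,ock->nol", xs, self.params["W"])
        if "b" in self.params:
            out = out + self.params["b"][None, :, None]
        return out

    def backward(self, grad):
        x = self.cache
        xs = self._windows(x)
        self.grads["W"] = np.einsum("nckl,nol->ock", xs, grad)
        if "b" in self.params:
            self.grads["b"] = grad.sum(axis=(0, 2))
        dx = np.zeros_like(x)
        lo = grad.shape[-1]
        s = self.stride
        W = self.params["W"]
        for k in range(self.kernel):
            dx[:, :, k : k + lo * s : s] += np.einsum("nol,oc->ncl", grad, W[:, :, k])
        return dx


class ReLU(Layer):
    def __init__(self):
        super().__init__()
        self.kind = "activation"

    def forward(self, x):
        self.cache = x > 0
        return np.where(self.cache, x, 0.0)

    def backward(self, grad):
        return np.where(self.cache, grad, 0.0)


class Flatten(Layer):
    def __init__(self):
        super().__init__()
        self.kind = "flatten"

    def forward(self, x):
        self.cache = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self.cache)


class _Pool1d(Layer):
    def __init__(self, kernel, stride=None):
        super().__init__()
        self.kernel = kernel
        self.stride = stride or kernel

    def out_length(self, length):
        return (length - self.kernel) // self.stride + 1

    def _windows(self, x):
        lo = self.out_length(x.shape[-1])
        s = self.stride
        return np.stack(
            [x[:, :, k : k + lo * s : s] for k in range(self.kernel)], axis=2
        )


class MaxPool1d(_Pool1d):
    def __init__(self, kernel, stride=None):
        super().__init__(kernel, stride)
        self.kind = "pool"
        self.mode = "max"

    def forward(self, x):
        xs = self._windows(x)
        self.cache = (x, xs.argmax(axis=2))
        return xs.max(axis=2)

    def backward(self, grad):
        x, argmax = self.cache
        dx = np.zeros_like(x)
        n, c, lo = grad.shape
        pos = argmax + np.arange(lo)[None, None, :] * self.stride
        np.add.at(
            dx,
            (np.arange(n)[:, None, None], np.arange(c)[None, :, None], pos),
            grad,
        )
        return dx


class AvgPool1d(_Pool1d):
    def __init__(self, kernel, stride=None):
        super().__init__(kernel, stride)
        self.kind = "pool"
        self.mode = "avg"

    def forward(self, x):
        self.cache = x
        return self._windows(x).mean(axis=2)

    def backward(self, grad):
        x = self.cache
        dx = np.zeros_like(x)
        lo = grad.shape[-1]
        s = self.stride
        for k in range(self.kernel):
            dx[:, :, k : k + lo * s : s] += grad / self.kernel
        return dx


class Network:
    """Ordered stack of layers with recorded activations.

    ``forward`` stores the input seen by every layer (``inputs[i]`` feeds
    ``layers[i]``; ``inputs[-1]`` is the network output), which is what the
    relevance engine walks backwards over.
    """

    def __init__(self, layers):
        if not layers:
            raise ValueError("network needs at least one layer")
        self.layers = list(layers)
        self.inputs = None
        self.meta = {}

    def forward(self, x, record=True):
        acts = [np.asarray(x, dtype=float)]
        for layer in self.layers:
            acts.append(layer.forward(acts[-1]))
        if record:
            self.inputs = acts
        return acts[-1]

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    @property
    def n_outputs(self):
        last = self.layers[-1]
        if last.kind != "dense":
            raise ValueError("network must end in a dense output layer")
        return last.params["W"].shape[1]

    def parameters(self):
        for layer in self.layers:
            for name, value in layer.params.items():
                yield layer, name, value


def softmax_cross_entropy(logits, labels):
    """Mean cross-entropy and gradient w.r.t. logits for integer labels."""
    z = logits - logits.max(axis=1, keepdims=True)
    expz = np.exp(z)
    probs = expz / expz.sum(axis=1, keepdims=True)
    n = len(labels)
    loss = -np.log(probs[np.arange(n), labels] + 1e-12).mean()
    grad = probs.copy()
    grad[np.arange(n), labels] -= 1.0
    return loss, grad / n


def train_network(
    net,
    X,
    y,
    epochs=40,
    batch_size=32,
    lr=1e-3,
    seed=0,
    weight_decay=0.0,
    clip_norm=5.0,
):
    """Train ``net`` as a softmax classifier with Adam.

    Deterministic given ``seed`` (controls batch shuffling only; layer
    initialisation is seeded at construction). Returns a history dict with
    the final training loss and accuracy.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("training requires at least two classes")
    rng = np.random.default_rng(seed)
    # Adam state per parameter
    state = {
        (id(layer), name): (np.zeros_like(v), np.zeros_like(v))
        for layer, name, v in net.parameters()
    }
    b1, b2, eps = 0.9, 0.999, 1e-8
    t = 0
    n = len(X)
    loss = np.nan
    for _ in range(epochs):
        order = rng.permutation(n)
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            logits = net.forward(X[idx], record=False)
            loss, grad = softmax_cross_entropy(logits, y[idx])
            net.backward(grad)
            if clip_norm:  # guard against early-step explosions
                total = np.sqrt(
                    sum(float((layer.grads[name] ** 2).sum())
                        for layer, name, _ in net.parameters())
                )
                if total > clip_norm:
                    scale = clip_norm / total
                    for layer, name, _ in net.parameters():
                        layer.grads[name] *= scale
            t += 1
            for layer, name, value in net.parameters():
                g = layer.grads[name]
                if weight_decay and name == "W":
                    g = g + weight_decay * value
                m, v = state[(id(layer), name)]
                m[:] = b1 * m + (1 - b1) * g
                v[:] = b2 * v + (1 - b2) * g * g
                mhat = m / (1 - b1**t)
                vhat = v / (1 - b2**t)
                value -= lr * mhat / (np.sqrt(vhat) + eps)
    logits = net.forward(X, record=False)
    final_loss, _ = softmax_cross_entropy(logits, y)
    accuracy = float((logits.argmax(axis=1) == y).mean())
    net.meta.update({"final_loss": float(final_loss), "train_accuracy": accuracy})
    return {"final_loss": float(final_loss), "train_accuracy": accuracy}
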