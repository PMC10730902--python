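"""A small NumPy neural-network core.

Implements exactly the layers the sub-band CNN and MLP head need — 3x3
same-padded convolution, batch normalization, ReLU, 2x2 max-pooling, flatten,
dense, dropout — with hand-written backward passes, a softmax cross-entropy
loss and an Adam optimizer.  Arrays are channels-last ``(N, H, W, C)`` for
spatial layers and ``(N, D)`` for dense layers.

Convolution is evaluated as nine shifted matrix products (one per kernel
tap), which keeps both directions BLAS-bound without im2col copies.  All
randomness (initialization, shuffling, dropout) flows through explicitly
passed NumPy generators, so training is reproducible for a fixed seed on a
fixed thread configuration.
"""

from __future__ import annotations

import copy

import numpy as np


class Layer:
    """Base layer: subclasses fill ``params``/``grads`` dicts as needed."""

    def __init__(self, name: str = ""):
        self.name = name
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def n_params(self) -> int:
        return int(sum(p.size for p in self.params.values()))


class Conv2D(Layer):
    """3x3 (or k x k) zero-padded stride-1 convolution, channels-last."""

    def __init__(self, c_in: int, c_out: int, kernel: int = 3, name: str = "conv",
                 rng: np.random.Generator | None = None, dtype=np.float32):
        super().__init__(name)
        rng = rng or np.random.default_rng(0)
        fan_in = kernel * kernel * c_in
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), (kernel, kernel, c_in, c_out))
        self.params = {"W": w.astype(dtype), "b": np.zeros(c_out, dtype=dtype)}
        self.kernel = kernel
        self.pad = kernel // 2

    def forward(self, x, train=False, rng=None):
        k, p = self.kernel, self.pad
        n, h, w, c_in = x.shape
        self._x_padded = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        weights = self.params["W"]
        c_out = weights.shape[-1]
        flat = np.zeros((n * h * w, c_out), dtype=x.dtype)
        for i in range(k):
            for j in range(k):
                patch = self._x_padded[:, i:i + h, j:j + w, :]
                flat += patch.reshape(-1, c_in) @ weights[i, j]
        self._in_shape = x.shape
        return flat.reshape(n, h, w, c_out) + self.params["b"]

    def backward(self, dout):
        k, p = self.kernel, self.pad
        n, h, w, c_in = self._in_shape
        c_out = dout.shape[-1]
        dflat = dout.reshape(-1, c_out)
        weights = self.params["W"]
        dw = np.empty_like(weights)
        dx_padded = np.zeros_like(self._x_padded)
        for i in range(k):
            for j in range(k):
                patch = self._x_padded[:, i:i + h, j:j + w, :].reshape(-1, c_in)
                dw[i, j] = patch.T @ dflat
                dx_padded[:, i:i + h, j:j + w, :] += (dflat @ weights[i, j].T
                                                      ).reshape(n, h, w, c_in)
        self.grads = {"W": dw, "b": dout.sum(axis=(0, 1, 2))}
        return dx_padded[:, p:p + h, p:p + w, :]


class BatchNorm(Layer):
    """Batch normalization over all axes but the last (channels/features)."""

    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5,
                 name: str = "bn", dtype=np.float32):
        super().__init__(name)
        self.params = {"gamma": np.ones(c, dtype=dtype),
                       "beta": np.zeros(c, dtype=dtype)}
        self.running_mean = np.zeros(c, dtype=dtype)
        self.running_var = np.ones(c, dtype=dtype)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x, train=False, rng=None):
        axes = tuple(range(x.ndim - 1))
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (self.momentum * self.running_mean
                                 + (1 - self.momentum) * mean)
            self.running_var = (self.momentum * self.running_var
                                + (1 - self.momentum) * var)
        else:
            mean, var = self.running_mean, self.running_var
        self._inv_std = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mean) * self._inv_std
        self._m = int(np.prod([x.shape[a] for a in axes]))
        self._train_mode = train
        return self.params["gamma"] * self._xhat + self.params["beta"]

    def backward(self, dout):
        axes = tuple(range(dout.ndim - 1))
        xhat, inv_std, m = self._xhat, self._inv_std, self._m
        self.grads = {"gamma": (dout * xhat).sum(axis=axes),
                      "beta": dout.sum(axis=axes)}
        dxhat = dout * self.params["gamma"]
        if not self._train_mode:
            # inference: mean/var are constants (running statistics)
            return dxhat * inv_std
        return (inv_std / m) * (m * dxhat - dxhat.sum(axis=axes)
                                - xhat * (dxhat * xhat).sum(axis=axes))


class ReLU(Layer):
    def forward(self, x, train=False, rng=None):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class MaxPool2x2(Layer):
    def forward(self, x, train=False, rng=None):
        n, h, w, c = x.shape
        xr = x.reshape(n, h // 2, 2, w // 2, 2, c)
        out = xr.max(axis=(2, 4))
        # tie-safe subgradient: split evenly among equal maxima in a window
        up = np.repeat(np.repeat(out, 2, axis=1), 2, axis=2)
        mask = (x == up)
        counts = mask.reshape(n, h // 2, 2, w // 2, 2, c).sum(axis=(2, 4))
        self._mask = mask
        self._counts = counts
        return out

    def backward(self, dout):
        share = dout / self._counts
        up = np.repeat(np.repeat(share, 2, axis=1), 2, axis=2)
        return up * self._mask


class Flatten(Layer):
    def forward(self, x, train=False, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Dense(Layer):
    def __init__(self, d_in: int, d_out: int, name: str = "dense",
                 rng: np.random.Generator | None = None, dtype=np.float32):
        super().__init__(name)
        rng = rng or np.random.default_rng(0)
        w = rng.normal(0.0, np.sqrt(2.0 / d_in), (d_in, d_out))
        self.params = {"W": w.astype(dtype), "b": np.zeros(d_out, dtype=dtype)}

    def forward(self, x, train=False, rng=None):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout):
        self.grads = {"W": self._x.T @ dout, "b": dout.sum(axis=0)}
        return dout @ self.params["W"].T


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float, name: str = "dropout"):
        super().__init__(name)
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must lie in [0, 1)")
        self.rate = rate

    def forward(self, x, train=False, rng=None):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("dropout in training mode needs an rng")
        self._mask = (rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask.astype(x.dtype)

    def backward(self, dout):
        if self._mask is None:
            return dout
        return dout * self._mask


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class Network:
    """A plain sequential network with softmax cross-entropy loss."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def layer(self, name: str) -> Layer:
        for lyr in self.layers:
            if lyr.name == name:
                return lyr
        raise KeyError(f"no layer named {name!r}")

    def forward(self, x, train: bool = False,
                rng: np.random.Generator | None = None,
                upto: str | None = None) -> np.ndarray:
        out = x
        for lyr in self.layers:
            out = lyr.forward(out, train=train, rng=rng)
            if upto is not None and lyr.name == upto:
                return out
        return out

    def backward(self, dout: np.ndarray, downto: str | None = None) -> np.ndarray:
        """Propagate ``dout`` backwards; stops after (and returns the gradient
        at the *output* of) the layer named ``downto``."""
        grad = dout
        for lyr in reversed(self.layers):
            if downto is not None and lyr.name == downto:
                return grad
            grad = lyr.backward(grad)
        return grad

    def predict_proba(self, x, batch_size: int = 64) -> np.ndarray:
        outs = [softmax(self.forward(x[i:i + batch_size], train=False))
                for i in range(0, len(x), batch_size)]
        return np.concatenate(outs, axis=0)

    def loss_and_grad(self, x, y_onehot, rng=None):
        logits = self.forward(x, train=True, rng=rng)
        probs = softmax(logits)
        eps = 1e-12
        loss = -np.mean(np.sum(y_onehot * np.log(probs + eps), axis=1))
        dlogits = (probs - y_onehot) / len(x)
        self.backward(dlogits.astype(logits.dtype))
        return float(loss), probs

    def n_params(self) -> int:
        return int(sum(lyr.n_params() for lyr in self.layers))

    def state_dict(self) -> dict:
        state = {}
        for i, lyr in enumerate(self.layers):
            for k, v in lyr.params.items():
                state[f"{i}:{k}"] = v.copy()
            if isinstance(lyr, BatchNorm):
                state[f"{i}:running_mean"] = lyr.running_mean.copy()
                state[f"{i}:running_var"] = lyr.running_var.copy()
        return state

    def load_state_dict(self, state: dict) -> None:
        for i, lyr in enumerate(self.layers):
            for k in lyr.params:
                lyr.params[k] = state[f"{i}:{k}"].copy()
            if isinstance(lyr, BatchNorm):
                lyr.running_mean = state[f"{i}:running_mean"].copy()
                lyr.running_var = state[f"{i}:running_var"].copy()


class Adam:
    def __init__(self, network: Network, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.network = network
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        corr = self.lr * np.sqrt(1 - b2 ** self.t) / (1 - b1 ** self.t)
        for i, lyr in enumerate(self.network.layers):
            for k, p in lyr.params.items():
                g = lyr.grads.get(k)
                if g is None:
                    continue
                key = f"{i}:{k}"
                m = self.m.setdefault(key, np.zeros_like(p))
                v = self.v.setdefault(key, np.zeros_like(p))
                m += (1 - b1) * (g - m)
                v += (1 - b2) * (g * g - v)
                p -= corr * m / (np.sqrt(v) + self.eps)


def fit_network(network: Network, x_train, y_train, x_val, y_val, *,
                lr: float = 1e-3, batch_size: int = 8, max_epochs: int = 100,
                seed: int = 0, verbose: bool = False) -> dict:
    """Mini-batch Adam training with best-validation-accuracy checkpointing.

    Labels are one-hot arrays.  Returns the history dict; the network is left
    holding the best-validation weights.
    """
    rng = np.random.default_rng(seed)
    opt = Adam(network, lr=lr)
    n = len(x_train)
    history = {"loss": [], "train_acc": [], "val_acc": []}
    best_acc, best_state = -1.0, None
    for epoch in range(max_epochs):
        order = rng.permutation(n)
        losses, correct = [], 0
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            loss, probs = network.loss_and_grad(x_train[idx], y_train[idx], rng=rng)
            opt.step()
            losses.append(loss)
            correct += int((probs.argmax(1) == y_train[idx].argmax(1)).sum())
        val_probs = network.predict_proba(x_val)
        val_acc = float((val_probs.argmax(1) == y_val.argmax(1)).mean())
        history["loss"].append(float(np.mean(losses)))
        history["train_acc"].append(correct / n)
        history["val_acc"].append(val_acc)
        if val_acc > best_acc:
            best_acc = val_acc
            best_state = network.state_dict()
        if verbose:
            print(f"epoch {epoch + 1}: loss {history['loss'][-1]:.4f} "
                  f"train {history['train_acc'][-1]:.3f} val {val_acc:.3f}")
    if best_state is not None:
        network.load_state_dict(best_state)
    history["best_val_acc"] = best_acc
    return history


def clone_network(network: Network) -> Network:
    return copy.deepcopy(network)
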