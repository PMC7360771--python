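"""Per-species atomic networks and a full-batch Adam optimizer.

Each species owns a small multilayer perceptron mapping that species'
preprocessed invariants to an atomic energy contribution; the total energy is
the sum of atomic outputs, which makes the model permutation invariant by
construction.  Hidden layers use the sigmoid activation; the head is linear
with an optional trainable bias (a per-species atomic reference energy).

Gradients are computed analytically by hand-rolled backpropagation: the
potential-assembly path requires exact derivatives of the energy with respect
to the input features, not finite differences.  Hidden layers can be frozen
(their parameters excluded from updates) to support layer-wise growth during
iterative training.
"""

from __future__ import annotations

import numpy as np


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class AtomicNetwork:
    """MLP: sigmoid hidden layers, linear scalar head.

    Parameters are stored as a flat list ``[W1, b1, ..., Wk, bk, w, b]``;
    ``n_frozen`` leading hidden layers are excluded from training updates.
    """

    def __init__(self, n_in: int, hidden: list[int], rng: np.random.Generator,
                 head_bias: bool = True):
        self.n_in = int(n_in)
        self.hidden = [int(h) for h in hidden]
        self.head_bias = bool(head_bias)
        self.n_frozen = 0
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        fan_in = self.n_in
        for h in self.hidden:
            scale = np.sqrt(2.0 / (fan_in + h))
            self.weights.append(rng.normal(0.0, scale, size=(h, fan_in)))
            self.biases.append(np.zeros(h))
            fan_in = h
        scale = np.sqrt(2.0 / (fan_in + 1))
        self.weights.append(rng.normal(0.0, scale, size=(1, fan_in)))
        self.biases.append(np.zeros(1))

    # -- structure ---------------------------------------------------------

    @property
    def n_layers(self) -> int:
        return len(self.hidden)

    def copy(self) -> "AtomicNetwork":
        new = object.__new__(AtomicNetwork)
        new.n_in = self.n_in
        new.hidden = list(self.hidden)
        new.head_bias = self.head_bias
        new.n_frozen = self.n_frozen
        new.weights = [w.copy() for w in self.weights]
        new.biases = [b.copy() for b in self.biases]
        return new

    def grow(self, width: int, rng: np.random.Generator) -> "AtomicNetwork":
        """Freeze all current hidden layers and append a new trainable one.

        The new hidden layer is inserted between the last hidden layer and
        the linear head; the head is re-initialized (it remains trainable).
        """
        new = self.copy()
        new.n_frozen = len(new.hidden)
        fan_in = new.hidden[-1] if new.hidden else new.n_in
        scale = np.sqrt(2.0 / (fan_in + width))
        W_new = rng.normal(0.0, scale, size=(width, fan_in))
        head_scale = np.sqrt(2.0 / (width + 1))
        w_head = rng.normal(0.0, head_scale, size=(1, width))
        new.weights = new.weights[:-1] + [W_new, w_head]
        new.biases = new.biases[:-1] + [np.zeros(width), self.biases[-1].copy()]
        new.hidden = new.hidden + [int(width)]
        return new

    def trainable_mask(self) -> list[bool]:
        """Per-parameter-array trainability (frozen hidden layers excluded)."""
        mask = []
        for i in range(len(self.weights)):
            frozen = i < self.n_frozen
            mask.append(not frozen)           # weight
            mask.append(not frozen)           # bias
        if not self.head_bias:
            mask[-1] = False
        return mask

    def parameters(self) -> list[np.ndarray]:
        out = []
        for W, b in zip(self.weights, self.biases):
            out.extend([W, b])
        return out

    # -- evaluation --------------------------------------------------------

    def _forward(self, X: np.ndarray):
        """Forward pass; returns (outputs, activations per layer)."""
        acts = [X]
        a = X
        for i in range(self.n_layers):
            a = sigmoid(a @ self.weights[i].T + self.biases[i])
            acts.append(a)
        out = a @ self.weights[-1].T + self.biases[-1]
        return out[:, 0], acts

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Atomic energies for a (n_atoms, n_in) feature matrix."""
        return self._forward(np.atleast_2d(X))[0]

    def grad_input(self, X: np.ndarray) -> np.ndarray:
        """d(output)/d(input) for every row: (n_atoms, n_in)."""
        X = np.atleast_2d(X)
        out, acts = self._forward(X)
        g = np.repeat(self.weights[-1], X.shape[0], axis=0)  # (n, width)
        for i in range(self.n_layers - 1, -1, -1):
            a = acts[i + 1]
            g = (g * a * (1.0 - a)) @ self.weights[i]
        return g

    def backprop(self, X: np.ndarray, upstream: np.ndarray):
        """Parameter gradients of sum_i upstream_i * output_i.

        Returns a list aligned with :meth:`parameters`.
        """
        X = np.atleast_2d(X)
        upstream = np.asarray(upstream, dtype=float).reshape(-1, 1)
        out, acts = self._forward(X)
        grads: list[np.ndarray] = [None] * (2 * (self.n_layers + 1))
        delta = upstream                                  # (n, 1)
        grads[-2] = delta.T @ acts[-1]                    # head weight
        grads[-1] = delta.sum(axis=0)                     # head bias
        d = delta @ self.weights[-1]                      # (n, width)
        for i in range(self.n_layers - 1, -1, -1):
            a = acts[i + 1]
            d = d * a * (1.0 - a)
            grads[2 * i] = d.T @ acts[i]
            grads[2 * i + 1] = d.sum(axis=0)
            d = d @ self.weights[i]
        return grads


class Adam:
    """Full-batch Adam over a list of parameter arrays."""

    def __init__(self, params: list[np.ndarray], lr: float = 0.001,
                 beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8, mask: list[bool] | None = None):
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.mask = [True] * len(params) if mask is None else list(mask)
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v, active in zip(self.params, grads, self.m, self.v,
                                      self.mask):
            if not active or g is None:
                continue
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g ** 2
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
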