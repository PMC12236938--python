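"""Small fully connected networks with hand-written backpropagation.

Both networks used by the pipeline are tiny (3-4 hidden layers, 64-128
units), so a compact numpy implementation with explicit forward/backward
passes and an Adam optimizer is sufficient and keeps the package free of a
deep-learning framework dependency.

Lipschitz control is implemented as an exact spectral projection: after
every optimizer step each weight matrix is divided by its top singular
value whenever that value exceeds the configured cap.  Because ReLU and
tanh are 1-Lipschitz, a network whose layers all satisfy ``sigma(W) <= c``
is globally ``c**n_layers``-Lipschitz, and the bound is exact rather than
estimated.
"""

from __future__ import annotations

import numpy as np

__all__ = ["MLP", "Adam", "spectral_norm"]


def spectral_norm(W: np.ndarray) -> float:
    """Largest singular value of a weight matrix (exact)."""
    if W.shape[0] == 1 or W.shape[1] == 1:
        return float(np.linalg.norm(W))
    return float(np.linalg.norm(W, 2))


def _maxmin_forward(z):
    """GroupSort-2: sort each adjacent pair of units descending.

    1-Lipschitz and gradient-norm preserving, unlike ReLU whose dead units
    shrink gradient norms under spectral-norm constraints.
    """
    n, h = z.shape
    z2 = z.reshape(n, h // 2, 2)
    idx = np.argsort(-z2, axis=2)
    return np.take_along_axis(z2, idx, axis=2).reshape(n, h), idx


def _maxmin_backward(cache, da):
    idx = cache
    n = da.shape[0]
    da2 = da.reshape(n, -1, 2)
    dz2 = np.empty_like(da2)
    np.put_along_axis(dz2, idx, da2, axis=2)
    return dz2.reshape(da.shape)


# name -> (forward(z) -> (a, cache), backward(cache, d_a) -> d_z)
_ACTIVATIONS = {
    "relu": (lambda z: (np.maximum(z, 0.0), z > 0),
             lambda cache, da: da * cache),
    "tanh": (lambda z: ((a := np.tanh(z)), a),
             lambda cache, da: da * (1.0 - cache * cache)),
    "maxmin": (_maxmin_forward, _maxmin_backward),
}


class MLP:
    """Feed-forward network ``sizes[0] -> ... -> sizes[-1]``, linear output.

    Parameters
    ----------
    sizes
        Layer widths including input and output dimension.
    activation
        ``"relu"`` or ``"tanh"``, applied after every layer except the last.
    rng
        Source of randomness for He-style weight initialization.
    spectral_cap
        If given, every weight matrix is projected so its spectral norm
        never exceeds this value (applied at init and after each step).
    """

    def __init__(self, sizes, activation: str, rng: np.random.Generator,
                 spectral_cap: float | None = None):
        if activation not in _ACTIVATIONS:
            raise ValueError(f"unknown activation {activation!r}")
        self.sizes = list(sizes)
        self.activation = activation
        self.spectral_cap = spectral_cap
        if activation == "maxmin" and any(h % 2 for h in sizes[1:-1]):
            raise ValueError("maxmin activation needs even hidden widths")
        self.W: list[np.ndarray] = []
        self.b: list[np.ndarray] = []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            scale = np.sqrt(2.0 / fan_in) if activation == "relu" else np.sqrt(1.0 / fan_in)
            self.W.append(rng.standard_normal((fan_in, fan_out)) * scale)
            self.b.append(np.zeros(fan_out))
        self.project()

    # -- spectral projection -------------------------------------------------
    def project(self) -> None:
        """Clip every layer's spectral norm at ``spectral_cap`` (exact)."""
        cap = self.spectral_cap
        if cap is None:
            return
        for l, W in enumerate(self.W):
            s = spectral_norm(W)
            if s > cap:
                self.W[l] = W * (cap / s)

    def project_fast(self, n_power_iters: int = 2) -> None:
        """Approximate projection via persistent power iteration.

        Cheap enough to run after every optimizer step; may leave a layer
        marginally above the cap, so callers that need the certified bound
        finish with an exact :meth:`project`.
        """
        cap = self.spectral_cap
        if cap is None:
            return
        if not hasattr(self, "_u"):
            self._u = [np.ones(W.shape[1]) / np.sqrt(W.shape[1]) for W in self.W]
        for l, W in enumerate(self.W):
            u = self._u[l]
            for _ in range(n_power_iters):
                v = W @ u
                v /= np.linalg.norm(v) + 1e-12
                u = W.T @ v
                nu = np.linalg.norm(u) + 1e-12
                u /= nu
            self._u[l] = u
            s = float(v @ (W @ u))
            if s > cap:
                self.W[l] = W * (cap / s)

    def lipschitz_bound(self) -> float:
        """Product of layer spectral norms — a certified Lipschitz constant."""
        return float(np.prod([spectral_norm(W) for W in self.W]))

    # -- forward / backward --------------------------------------------------
    def forward(self, X: np.ndarray, cache: bool = False):
        """Evaluate the network; with ``cache=True`` also return tape for backward."""
        act_fwd, _ = _ACTIVATIONS[self.activation]
        a = np.asarray(X, dtype=float)
        tape = [] if cache else None
        n_layers = len(self.W)
        for l, (W, b) in enumerate(zip(self.W, self.b)):
            z = a @ W + b
            if l < n_layers - 1:
                a_next, act_cache = act_fwd(z)
            else:
                a_next, act_cache = z, None
            if cache:
                tape.append((a, act_cache))
            a = a_next
        return (a, tape) if cache else a

    def backward(self, tape, dout: np.ndarray):
        """Backpropagate ``dout`` (d loss / d output).

        Returns ``(dW, db, dX)`` — gradients of the scalar loss w.r.t.
        parameters and the network input.
        """
        _, act_bwd = _ACTIVATIONS[self.activation]
        n_layers = len(self.W)
        dW = [None] * n_layers
        db = [None] * n_layers
        delta = np.asarray(dout, dtype=float)
        for l in range(n_layers - 1, -1, -1):
            a_in, act_cache = tape[l]
            if l < n_layers - 1:
                delta = act_bwd(act_cache, delta)
            dW[l] = a_in.T @ delta
            db[l] = delta.sum(axis=0)
            delta = delta @ self.W[l].T
        return dW, db, delta

    def input_gradient(self, X: np.ndarray) -> np.ndarray:
        """Gradient of a scalar-output network w.r.t. each input row."""
        if self.sizes[-1] != 1:
            raise ValueError("input_gradient requires a scalar-output network")
        out, tape = self.forward(X, cache=True)
        _, _, dX = self.backward(tape, np.ones_like(out))
        return dX

    # -- parameter plumbing ---------------------------------------------------
    def copy_weights_from(self, other: "MLP") -> None:
        self.W = [W.copy() for W in other.W]
        self.b = [b.copy() for b in other.b]


class Adam:
    """Adam optimizer over an :class:`MLP`'s parameter lists (minimizes)."""

    def __init__(self, net: MLP, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.net = net
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.mW = [np.zeros_like(W) for W in net.W]
        self.vW = [np.zeros_like(W) for W in net.W]
        self.mb = [np.zeros_like(b) for b in net.b]
        self.vb = [np.zeros_like(b) for b in net.b]

    def step(self, dW, db) -> None:
        """Apply one descent step along the given gradients, then re-project."""
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1 ** self.t
        bias2 = 1.0 - b2 ** self.t
        for l in range(len(self.net.W)):
            self.mW[l] = b1 * self.mW[l] + (1 - b1) * dW[l]
            self.vW[l] = b2 * self.vW[l] + (1 - b2) * dW[l] ** 2
            self.net.W[l] -= self.lr * (self.mW[l] / bias1) / (np.sqrt(self.vW[l] / bias2) + self.eps)
            self.mb[l] = b1 * self.mb[l] + (1 - b1) * db[l]
            self.vb[l] = b2 * self.vb[l] + (1 - b2) * db[l] ** 2
            self.net.b[l] -= self.lr * (self.mb[l] / bias1) / (np.sqrt(self.vb[l] / bias2) + self.eps)
        self.net.project_fast()
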