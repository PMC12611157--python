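"""Minimal feed-forward network with hand-written reverse mode and Adam.

Shared by the neural-ODE surrogate and the Jacobian estimator. Everything is
plain float64 numpy, fully seeded: a forward pass can record a tape, and
``mlp_vjp`` pulls a cotangent back through it, returning input and parameter
gradients. Works on single states (1-D input) or batches (2-D input).
"""

from __future__ import annotations

from typing import Callable, List, Sequence, Tuple

import numpy as np

__all__ = ["MLP", "Adam", "swish", "relu"]

Params = List[Tuple[np.ndarray, np.ndarray]]


def relu(z: np.ndarray) -> np.ndarray:
    return np.maximum(z, 0.0)


def _relu_grad(z: np.ndarray) -> np.ndarray:
    return (z > 0.0).astype(z.dtype)


def swish(z: np.ndarray) -> np.ndarray:
    return z / (1.0 + np.exp(-z))


def _swish_grad(z: np.ndarray) -> np.ndarray:
    sig = 1.0 / (1.0 + np.exp(-z))
    return sig * (1.0 + z * (1.0 - sig))


_ACTIVATIONS: dict[str, tuple[Callable, Callable]] = {
    "relu": (relu, _relu_grad),
    "swish": (swish, _swish_grad),
}


class MLP:
    """Fully connected network, linear output layer."""

    def __init__(
        self,
        sizes: Sequence[int],
        activation: str = "relu",
        rng: np.random.Generator | int | None = None,
    ) -> None:
        if activation not in _ACTIVATIONS:
            raise ValueError(f"unknown activation {activation!r}")
        self.sizes = list(sizes)
        self.activation = activation
        self._act, self._act_grad = _ACTIVATIONS[activation]
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        self.params: Params = []
        for n_in, n_out in zip(sizes[:-1], sizes[1:]):
            w = rng.standard_normal((n_in, n_out)) * np.sqrt(2.0 / n_in)
            b = np.zeros(n_out)
            self.params.append((w, b))

    # -- forward -----------------------------------------------------------
    def forward(self, x: np.ndarray, tape: list | None = None) -> np.ndarray:
        """Evaluate the network; if ``tape`` is given, record for the vjp."""
        a = x
        if tape is not None:
            tape.append(a)
        last = len(self.params) - 1
        for i, (w, b) in enumerate(self.params):
            z = a @ w + b
            a = z if i == last else self._act(z)
            if tape is not None:
                tape.append(z)
                if i != last:
                    tape.append(a)
        return a

    __call__ = forward

    def vjp(self, tape: list, grad_out: np.ndarray) -> tuple[np.ndarray, Params]:
        """Pull ``grad_out`` back through a recorded tape.

        Returns (grad wrt input, per-layer parameter gradients).
        """
        n_layers = len(self.params)
        grads: Params = [None] * n_layers  # type: ignore[list-item]
        delta = grad_out
        pos = len(tape) - 1
        for i in range(n_layers - 1, -1, -1):
            if i != n_layers - 1:
                pos -= 1  # skip activation output
                z = tape[pos]
                delta = delta * self._act_grad(z)
            else:
                z = tape[pos]
            pos -= 1
            a_prev = tape[pos]
            w, _ = self.params[i]
            if a_prev.ndim == 1:
                gw = np.outer(a_prev, delta)
                gb = delta
            else:
                gw = a_prev.T @ delta
                gb = delta.sum(axis=0)
            grads[i] = (gw, gb)
            delta = delta @ w.T
        return delta, grads

    # -- constraints -------------------------------------------------------
    def apply_max_norm(self, max_norm: float) -> None:
        """Rescale incoming-weight columns whose L2 norm exceeds ``max_norm``."""
        for w, _ in self.params:
            norms = np.linalg.norm(w, axis=0, keepdims=True)
            np.multiply(w, np.minimum(1.0, max_norm / np.maximum(norms, 1e-30)),
                        out=w)


class Adam:
    """Adam optimizer over an MLP's parameter list, with optional L2 decay
    and global-norm gradient clipping."""

    def __init__(
        self,
        params: Params,
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 0.0,
    ) -> None:
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [(np.zeros_like(w), np.zeros_like(b)) for w, b in params]
        self.v = [(np.zeros_like(w), np.zeros_like(b)) for w, b in params]

    @staticmethod
    def clip_global_norm(grads: Params, max_norm: float) -> Params:
        total = np.sqrt(sum(float(np.sum(g**2)) + float(np.sum(gb**2))
                            for g, gb in grads))
        if total > max_norm > 0:
            scale = max_norm / total
            grads = [(g * scale, gb * scale) for g, gb in grads]
        return grads

    def step(self, grads: Params) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for i, ((w, b), (gw, gb)) in enumerate(zip(self.params, grads)):
            if self.weight_decay:
                gw = gw + self.weight_decay * w
                gb = gb + self.weight_decay * b
            mw, mb = self.m[i]
            vw, vb = self.v[i]
            mw *= self.b1; mw += (1 - self.b1) * gw
            mb *= self.b1; mb += (1 - self.b1) * gb
            vw *= self.b2; vw += (1 - self.b2) * gw**2
            vb *= self.b2; vb += (1 - self.b2) * gb**2
            w -= self.lr * (mw / b1t) / (np.sqrt(vw / b2t) + self.eps)
            b -= self.lr * (mb / b1t) / (np.sqrt(vb / b2t) + self.eps)
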