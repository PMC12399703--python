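"""Feedforward network primitives shared by both fitting routes.

Two network flavours live here:

* :class:`SimpleNet` — a one-hidden-layer ReLU network with an explicit,
  positionally addressable parameter registry (the "spreadsheet" network:
  one input node for time, 1-5 hidden neurons, three output nodes, one per
  compartment).
* :class:`MLP` — a general dense ReLU network (default 1 -> 64 -> 64 -> 64
  -> 3) with Glorot-Uniform initialization, forward evaluation, the exact
  derivative of each output with respect to the time input, and reverse-mode
  gradients of any loss through *both* the outputs and their time
  derivatives.

For a ReLU network the time derivative at input ``t`` is the product of the
layer matrices masked by the active units,

    du/dt = W_L D_{L-1} W_{L-1} ... D_1 W_1,

with ``D_k = diag(1[z_k > 0])``.  Treating the masks as locally constant
(exact almost everywhere, and precisely what reverse-mode autodiff computes
for ReLU) makes the gradient of a loss that consumes both ``u`` and
``du/dt`` available in closed form; :meth:`MLP.backprop` implements it.  The
test suite checks these gradients against central finite differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "relu",
    "eval_composite",
    "SimpleNet",
    "eval_simple_net",
    "DenseArchitecture",
    "MLP",
    "glorot_uniform_init",
    "Adam",
]


def relu(x):
    """Rectified linear unit: the maximum of 0 and the input."""
    return np.maximum(0.0, x)


def eval_composite(x: float, w1: float, b1: float, w2: float, b2: float) -> float:
    """Single-neuron composite: affine -> ReLU -> affine.

    ``f(x) = w2 * max(0, w1*x + b1) + b2``.  This is the smallest network
    that exhibits the structure of every deeper model in this package.
    """
    return w2 * relu(w1 * x + b1) + b2


@dataclass
class SimpleNet:
    """One-hidden-layer ReLU network: time in, (S, I, R) out.

    Parameters are exposed as a flat registry with stable ordering —
    hidden affine pairs ``(w_i1, b_i1)`` per neuron first, then per output
    channel its ``n_neurons`` weights followed by its bias — so optimizers
    and tests can address them positionally, the way a spreadsheet parameter
    table does.
    """

    hidden_w: np.ndarray  # (K,)
    hidden_b: np.ndarray  # (K,)
    out_w: np.ndarray     # (3, K)
    out_b: np.ndarray     # (3,)

    def __post_init__(self):
        self.hidden_w = np.atleast_1d(np.asarray(self.hidden_w, dtype=float))
        self.hidden_b = np.atleast_1d(np.asarray(self.hidden_b, dtype=float))
        self.out_w = np.asarray(self.out_w, dtype=float).reshape(3, -1)
        self.out_b = np.asarray(self.out_b, dtype=float).reshape(3)
        K = self.n_neurons
        if not (self.hidden_b.shape == (K,) and self.out_w.shape == (3, K)):
            raise ValueError("inconsistent SimpleNet parameter shapes")
        for arr in (self.hidden_w, self.hidden_b, self.out_w, self.out_b):
            if not np.all(np.isfinite(arr)):
                raise ValueError("SimpleNet parameters must be finite")

    @property
    def n_neurons(self) -> int:
        return len(self.hidden_w)

    @property
    def n_params(self) -> int:
        return 2 * self.n_neurons + 3 * (self.n_neurons + 1)

    @classmethod
    def zeros(cls, n_neurons: int) -> "SimpleNet":
        return cls(np.zeros(n_neurons), np.zeros(n_neurons),
                   np.zeros((3, n_neurons)), np.zeros(3))

    def to_flat(self) -> np.ndarray:
        hidden = np.column_stack([self.hidden_w, self.hidden_b]).ravel()
        output = np.concatenate([np.append(self.out_w[c], self.out_b[c]) for c in range(3)])
        return np.concatenate([hidden, output])

    @classmethod
    def from_flat(cls, flat, n_neurons: int) -> "SimpleNet":
        flat = np.asarray(flat, dtype=float)
        K = n_neurons
        if len(flat) != 2 * K + 3 * (K + 1):
            raise ValueError("flat vector length does not match n_neurons")
        hidden = flat[: 2 * K].reshape(K, 2)
        out = flat[2 * K:].reshape(3, K + 1)
        return cls(hidden[:, 0], hidden[:, 1], out[:, :K], out[:, K])

    def param_names(self) -> list[str]:
        names = []
        for i in range(1, self.n_neurons + 1):
            names += [f"w_{i}1", f"b_{i}1"]
        for c, ch in enumerate("SIR"):
            names += [f"w_{i}{ch}" for i in range(1, self.n_neurons + 1)]
            names += [f"b_{ch}"]
        return names

    def to_csv(self, path) -> None:
        """Serialize as name,value rows (the spreadsheet parameter table)."""
        pd.DataFrame({"name": self.param_names(), "value": self.to_flat()}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SimpleNet":
        df = pd.read_csv(path)
        n_neurons = (len(df) - 3) // 5
        return cls.from_flat(df["value"].to_numpy(dtype=float), n_neurons)

    def __call__(self, t) -> np.ndarray:
        return eval_simple_net(self, t)


def eval_simple_net(net: SimpleNet, t) -> np.ndarray:
    """Evaluate a :class:`SimpleNet` at time(s) ``t``.

    Output channel ``c`` is ``sum_i w_ic * max(0, w_i1*t + b_i1) + b_c`` —
    piecewise linear and continuous in ``t``.  Returns shape ``(3,)`` for a
    scalar ``t`` and ``(n, 3)`` for a vector.
    """
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    hidden = relu(t_arr[:, None] * net.hidden_w + net.hidden_b)  # (n, K)
    out = hidden @ net.out_w.T + net.out_b                       # (n, 3)
    return out[0] if np.isscalar(t) or np.ndim(t) == 0 else out


@dataclass(frozen=True)
class DenseArchitecture:
    """Layer widths of a dense network: input (time) is width 1, output is
    width 3 (one node per compartment)."""

    hidden: tuple = (64, 64, 64)
    activation: str = "relu"

    def __post_init__(self):
        object.__setattr__(self, "hidden", tuple(int(w) for w in self.hidden))
        if any(w <= 0 for w in self.hidden):
            raise ValueError("layer widths must be positive")
        if self.activation != "relu":
            raise ValueError("only the ReLU activation is supported")

    @property
    def widths(self) -> tuple:
        return (1, *self.hidden, 3)


def glorot_uniform_init(arch: DenseArchitecture, seed: int) -> list:
    """Glorot (Xavier) Uniform parameters for ``arch``.

    Each layer's weights are drawn uniformly on
    ``±sqrt(6 / (fan_in + fan_out))``; biases start at 0.  Deterministic
    given ``seed``.
    """
    rng = np.random.default_rng(seed)
    widths = arch.widths
    params = []
    for fan_in, fan_out in zip(widths[:-1], widths[1:]):
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        W = rng.uniform(-limit, limit, size=(fan_out, fan_in))
        params.append((W, np.zeros(fan_out)))
    return params


class MLP:
    """Dense ReLU network with analytic time-derivative and gradients.

    ``params`` is a list of ``(W, b)`` per layer, ``W`` of shape
    ``(fan_out, fan_in)``.  The last layer is affine (no activation).
    """

    def __init__(self, arch: DenseArchitecture = DenseArchitecture(), seed: int | None = 0,
                 params: list | None = None):
        self.arch = arch
        if params is None:
            params = glorot_uniform_init(arch, seed if seed is not None else 0)
        self.params = [(np.asarray(W, dtype=float), np.asarray(b, dtype=float)) for W, b in params]

    # -- flat parameter view (used by tests and serialization) ------------
    def get_flat(self) -> np.ndarray:
        return np.concatenate([np.concatenate([W.ravel(), b]) for W, b in self.params])

    def set_flat(self, flat) -> None:
        flat = np.asarray(flat, dtype=float)
        i = 0
        new = []
        for W, b in self.params:
            nW, nb = W.size, b.size
            new.append((flat[i:i + nW].reshape(W.shape), flat[i + nW:i + nW + nb].copy()))
            i += nW + nb
        if i != len(flat):
            raise ValueError("flat vector length mismatch")
        self.params = new

    # -- forward pass ------------------------------------------------------
    def forward(self, t, with_derivative: bool = False):
        """Evaluate the network (and optionally du/dt) at times ``t``.

        Returns ``(u, cache)`` or ``(u, dudt, cache)``; ``u`` and ``dudt``
        have shape ``(n, 3)``.  The cache holds the layer activations and
        ReLU masks needed by :meth:`backprop`.
        """
        t = np.atleast_1d(np.asarray(t, dtype=float))
        h = t[:, None]
        hs = [h]          # h_0 .. h_{L-1}
        masks = []        # m_1 .. m_{L-1}
        for W, b in self.params[:-1]:
            z = h @ W.T + b
            m = (z > 0).astype(float)
            h = z * m
            hs.append(h)
            masks.append(m)
        W_L, b_L = self.params[-1]
        u = h @ W_L.T + b_L
        if not np.all(np.isfinite(u)):
            raise FloatingPointError("non-finite network output")
        cache = {"hs": hs, "masks": masks, "n": len(t)}
        if not with_derivative:
            return u, cache
        # du/dt: propagate the masked product of layer matrices
        W1 = self.params[0][0]                 # (w1, 1)
        p = masks[0] * W1[:, 0]                # (n, w1)
        ps = [p]
        for k in range(1, len(masks)):
            W = self.params[k][0]
            p = masks[k] * (p @ W.T)
            ps.append(p)
        dudt = p @ W_L.T                       # (n, 3)
        cache["ps"] = ps
        return u, dudt, cache

    def __call__(self, t) -> np.ndarray:
        return self.forward(t)[0]

    def backprop(self, cache, dL_du, dL_ddudt=None) -> list:
        """Gradients of a scalar loss w.r.t. all (W, b).

        ``dL_du`` (n, 3) is the loss gradient through the outputs;
        ``dL_ddudt`` (n, 3), if given, the gradient through the time
        derivatives (requires a cache from ``forward(with_derivative=True)``).
        ReLU masks are held fixed, matching reverse-mode autodiff.
        """
        hs, masks = cache["hs"], cache["masks"]
        L = len(self.params)
        grads = [[np.zeros_like(W), np.zeros_like(b)] for W, b in self.params]

        delta = np.asarray(dL_du, dtype=float)
        grads[L - 1][0] += delta.T @ hs[L - 1]
        grads[L - 1][1] += delta.sum(axis=0)
        for k in range(L - 2, -1, -1):
            delta = (delta @ self.params[k + 1][0]) * masks[k]
            grads[k][0] += delta.T @ hs[k]
            grads[k][1] += delta.sum(axis=0)

        if dL_ddudt is not None:
            ps = cache["ps"]
            s = np.asarray(dL_ddudt, dtype=float)
            # output layer: du/dt = W_L p_{L-1}
            grads[L - 1][0] += s.T @ ps[L - 2]
            q = (s @ self.params[L - 1][0]) * masks[L - 2]
            for k in range(L - 2, 0, -1):
                grads[k][0] += q.T @ ps[k - 1]
                q = (q @ self.params[k][0]) * masks[k - 1]
            # first layer: right factor is the constant input weight path
            grads[0][0] += q.sum(axis=0)[:, None]
        return [(gW, gb) for gW, gb in grads]


class Adam:
    """Adam optimizer over a list of parameter arrays (full-batch use)."""

    def __init__(self, shapes, lr: float = 0.001, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros(s) for s in shapes]
        self.v = [np.zeros(s) for s in shapes]
        self.t = 0

    def step(self, params: list, grads: list) -> list:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1 - b1 ** self.t
        bias2 = 1 - b2 ** self.t
        out = []
        for i, (p, g) in enumerate(zip(params, grads)):
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / bias1
            vhat = self.v[i] / bias2
            out.append(p - self.lr * mhat / (np.sqrt(vhat) + self.eps))
        return out
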