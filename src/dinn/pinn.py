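"""Physics-informed neural network for the SIR inverse problem.

A dense ReLU network ``u_hat(t)`` maps time to the three compartments while
the physics parameters ``lambda = (beta, sigma)`` are appended to the
learnable set and updated by the same Adam steps as the weights.  The
composite loss is

    L = L_ode + L_ic + L_data,

where ``L_ode`` penalizes the residuals of the SIR equations evaluated on
the network's own outputs and their exact time derivatives (the network is
piecewise linear, so du/dt is available in closed form — the reverse-mode
equivalent of automatic differentiation), ``L_data`` is the mean squared
mismatch with the observed noisy compartments at the anchor days, and
``L_ic`` pins the initial condition.  Each component carries a
per-compartment weight, all 1 by default so the unweighted composite loss
is the default behaviour.

Training is full-batch: every Adam step sees all observation days, which
double as the residual collocation points.  Compartments are normalized to
proportions of the population before training (the SIR equations, hence
beta and sigma, are invariant under that rescaling); time is fed in raw
days.  ``beta`` and ``sigma`` start at 0 and are unconstrained.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .nets import MLP, Adam, DenseArchitecture
from .sir import Trajectory, normalize

__all__ = [
    "PinnConfig",
    "PinnModel",
    "TrainingTrace",
    "TrainingDivergence",
    "ode_residuals",
    "pinn_loss",
    "train_pinn",
    "relative_error",
]


def relative_error(estimate: float, truth: float) -> float:
    """``|estimate - truth| / |truth|`` — the accuracy metric for recovered
    rates.  Undefined for ``truth == 0``."""
    if truth == 0:
        raise ValueError("relative error is undefined for truth == 0")
    return abs(estimate - truth) / abs(truth)


@dataclass(frozen=True)
class PinnConfig:
    """Training configuration; the defaults are the standard protocol:
    3 hidden layers of 64 ReLU neurons, Adam with learning rate 0.001,
    30,000 full-batch iterations, Glorot Uniform weight initialization and
    (beta, sigma) initialized at zero."""

    architecture: DenseArchitecture = field(default_factory=DenseArchitecture)
    learning_rate: float = 0.001
    iterations: int = 30_000
    init_seed: int = 0
    lambda_init: tuple = (0.0, 0.0)
    w_ode: tuple = (1.0, 1.0, 1.0)
    w_ic: tuple = (1.0, 1.0, 1.0)
    w_data: tuple = (1.0, 1.0, 1.0)
    trace_every: int = 100
    normalize_data: bool = True
    learn_lambda: bool = True  # False freezes (beta, sigma) at lambda_init

    def __post_init__(self):
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        for w in (*self.w_ode, *self.w_ic, *self.w_data):
            if w < 0:
                raise ValueError("loss weights must be non-negative")


@dataclass
class PinnModel:
    """The trained network plus its learnable physics parameters.

    ``lambda_hat = (beta_hat, sigma_hat)`` participates in every gradient
    step exactly like the network weights.  ``N`` is the population scale
    of the data the model was trained on (1 for normalized data).
    """

    mlp: MLP
    lambda_hat: np.ndarray
    N: float = 1.0

    @property
    def beta_hat(self) -> float:
        return float(self.lambda_hat[0])

    @property
    def sigma_hat(self) -> float:
        return float(self.lambda_hat[1])

    def predict(self, t) -> np.ndarray:
        return self.mlp(t)


class TrainingDivergence(RuntimeError):
    """Raised when the loss becomes non-finite; carries the trace so far."""

    def __init__(self, iteration: int, trace: "TrainingTrace"):
        super().__init__(f"non-finite loss at iteration {iteration}")
        self.iteration = iteration
        self.trace = trace


@dataclass
class TrainingTrace:
    """Learning-process record at a fixed period (first record: iteration 0)."""

    records: list = field(default_factory=list)

    def append(self, iteration, beta_hat, sigma_hat, components):
        self.records.append({
            "iteration": iteration, "beta_hat": beta_hat, "sigma_hat": sigma_hat,
            **components,
        })

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def __len__(self):
        return len(self.records)


def _residuals_from_arrays(u, dudt, beta, sigma, N):
    S, I = u[:, 0], u[:, 1]
    infection = beta * S * I / N
    return np.column_stack([
        dudt[:, 0] + infection,
        dudt[:, 1] - infection + sigma * I,
        dudt[:, 2] - sigma * I,
    ])


def ode_residuals(model: PinnModel, t, N: float | None = None) -> np.ndarray:
    """Per-day SIR residuals of the model outputs (pre-squaring).

    ``residual_S = dS/dt + beta*S*I/N``, ``residual_I = dI/dt - beta*S*I/N
    + sigma*I``, ``residual_R = dR/dt - sigma*I``, each evaluated on the
    network's outputs with exact time derivatives.  The three residuals sum
    to ``d(S+I+R)/dt`` at every t (the physics terms telescope).
    """
    if N is None:
        N = model.N
    u, dudt, _ = model.mlp.forward(t, with_derivative=True)
    return _residuals_from_arrays(u, dudt, model.beta_hat, model.sigma_hat, N)


def _loss_components(u, dudt, obs, lam, N, config):
    n = len(obs)
    r = _residuals_from_arrays(u, dudt, lam[0], lam[1], N)
    L_ode_c = np.array(config.w_ode) * np.mean(r ** 2, axis=0)
    err = u - obs
    L_data = float(np.sum(np.array(config.w_data) * np.sum(err ** 2, axis=0) / n))
    L_ic = float(np.sum(np.array(config.w_ic) * err[0] ** 2))
    L_ode = float(L_ode_c.sum())
    comps = {
        "L_ode_S": float(L_ode_c[0]), "L_ode_I": float(L_ode_c[1]),
        "L_ode_R": float(L_ode_c[2]), "L_ode": L_ode, "L_ic": L_ic,
        "L_data": L_data, "total": L_ode + L_ic + L_data,
    }
    return comps, r, err


def pinn_loss(model: PinnModel, data: Trajectory, config: PinnConfig = PinnConfig()):
    """Composite loss on ``data``; returns ``(total, components dict)``.

    The observation days are the residual collocation points.  Components:
    ``L_ode`` (per-compartment weighted mean squared residual), ``L_data``
    (per-compartment weighted mean squared data mismatch), ``L_ic``
    (weighted squared day-0 mismatch); the total is their sum.
    """
    if len(data) == 0:
        raise ValueError("empty trajectory")
    u, dudt, _ = model.mlp.forward(data.times, with_derivative=True)
    comps, _, _ = _loss_components(u, dudt, data.states, model.lambda_hat, data.N, config)
    return comps["total"], comps


def _loss_and_grads(mlp, lam, times, obs, N, config):
    """Loss components plus gradients w.r.t. (net params, lambda)."""
    u, dudt, cache = mlp.forward(times, with_derivative=True)
    comps, r, err = _loss_components(u, dudt, obs, lam, N, config)
    n = len(obs)
    beta, sigma = lam
    w_ode = np.array(config.w_ode)

    a = 2.0 * w_ode * r / n                      # dL/dr, (n, 3)
    dL_dg = a                                     # residuals are linear in du/dt
    S, I = u[:, 0], u[:, 1]
    dL_du = 2.0 * np.array(config.w_data) * err / n
    dL_du[0] += 2.0 * np.array(config.w_ic) * err[0]
    dL_du = dL_du.copy()
    dL_du[:, 0] += (a[:, 0] - a[:, 1]) * beta * I / N
    dL_du[:, 1] += (a[:, 0] - a[:, 1]) * beta * S / N + (a[:, 1] - a[:, 2]) * sigma

    g_beta = float(np.sum((a[:, 0] - a[:, 1]) * S * I / N))
    g_sigma = float(np.sum((a[:, 1] - a[:, 2]) * I))

    net_grads = mlp.backprop(cache, dL_du, dL_dg)
    return comps, net_grads, np.array([g_beta, g_sigma])


def train_pinn(data: Trajectory, config: PinnConfig = PinnConfig()):
    """Joint gradient-descent training of the network and (beta, sigma).

    Runs exactly ``config.iterations`` full-batch Adam steps (no early
    stopping), recording the physics parameters and loss components at
    iteration 0, every ``trace_every`` iterations and the final iteration.
    Deterministic given ``init_seed``.  Returns ``(PinnModel,
    TrainingTrace)``; raises :class:`TrainingDivergence` on non-finite loss.
    """
    if len(data) == 0:
        raise ValueError("empty trajectory")
    if config.normalize_data:
        data = normalize(data)
    times, obs, N = data.times, data.states, data.N

    mlp = MLP(config.architecture, seed=config.init_seed)
    lam = np.asarray(config.lambda_init, dtype=float).copy()
    flat_params = [p for Wb in mlp.params for p in Wb] + [lam]
    opt = Adam([p.shape for p in flat_params], lr=config.learning_rate)

    trace = TrainingTrace()
    for it in range(config.iterations + 1):
        try:
            comps, net_grads, lam_grad = _loss_and_grads(mlp, lam, times, obs, N, config)
        except FloatingPointError:
            raise TrainingDivergence(it, trace)
        if not np.isfinite(comps["total"]):
            raise TrainingDivergence(it, trace)
        if it % config.trace_every == 0 or it == config.iterations:
            trace.append(it, float(lam[0]), float(lam[1]), comps)
        if it == config.iterations:
            break
        if not config.learn_lambda:
            lam_grad = np.zeros_like(lam_grad)
        flat = [p for Wb in mlp.params for p in Wb] + [lam]
        grads = [g for gWb in net_grads for g in gWb] + [lam_grad]
        new = opt.step(flat, grads)
        mlp.params = [(new[2 * i], new[2 * i + 1]) for i in range(len(mlp.params))]
        lam = new[-1]

    return PinnModel(mlp, lam, N=N), trace
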