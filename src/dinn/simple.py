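"""The one-hidden-layer finite-difference "simple-PINN".

This is the spreadsheet method, re-implemented: a :class:`~dinn.nets.SimpleNet`
with 1-5 hidden ReLU neurons is fitted to 60 days of normalized noisy SIR
data by minimizing

    total = w_data * MSE(predictions, observations)
          + w_ode  * mean of squared forward-difference ODE residuals,

over the network weights/biases *and* the physics parameters (beta, sigma)
jointly, with multistart bounded quasi-Newton optimization (the analogue of
a spreadsheet solver's GRG-with-multistart).  Time derivatives are forward
differences with the daily time step; by default the residuals consume the
*network's* predictions, mirroring a worksheet whose residual columns
reference the network columns.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .nets import MLP, DenseArchitecture, SimpleNet
from .sir import PROTOCOL, SIRParameters, Trajectory, normalize

__all__ = [
    "SimpleFitConfig",
    "SimpleFitResult",
    "LossBreakdown",
    "fd_derivative",
    "simple_loss",
    "fit_simple_dinn",
    "error_vs_neurons",
]


def fd_derivative(series) -> np.ndarray:
    """Forward differences of a daily series: ``d_j = x_{j+1} - x_j``.

    With unit spacing this is the first-order derivative estimate used by
    the spreadsheet recurrence; the result has length ``T - 1`` (the final
    day has no forward neighbour).  Works column-wise on 2-D input.
    """
    series = np.asarray(series, dtype=float)
    if series.shape[0] < 2:
        raise ValueError("need at least 2 days for a forward difference")
    return np.diff(series, axis=0)


@dataclass(frozen=True)
class LossBreakdown:
    """Error-log entries: data MSE, mean squared ODE residual, weighted total."""

    mse_data: float
    dinn_residual: float
    total: float


@dataclass(frozen=True)
class SimpleFitConfig:
    """Configuration of the multistart simple-PINN fit.

    Bounds are boxes on the normalized-data scale: weights and biases in
    ``[-weight_bound, weight_bound]``, beta in ``beta_bounds``, sigma in
    ``sigma_bounds``.  Restart starting points are drawn uniformly within
    the boxes, deterministically from ``seed``.
    """

    n_neurons: int = 5
    n_restarts: int = 20
    weight_bound: float = 5.0
    beta_bounds: tuple = (0.0, 2.0)
    sigma_bounds: tuple = (0.0, 1.0)
    tolerance: float = 1e-10
    max_iter: int = 10_000
    seed: int = 0
    loss_weights: tuple = (1.0, 1.0)  # (w_data, w_ode)
    derivative_source: str = "network"

    def __post_init__(self):
        if not 1 <= self.n_neurons:
            raise ValueError("n_neurons must be >= 1")
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")
        w_data, w_ode = self.loss_weights
        if w_data < 0 or w_ode < 0 or (w_data == 0 and w_ode == 0):
            raise ValueError("loss weights must be non-negative and not both zero")
        if self.derivative_source not in ("network", "data"):
            raise ValueError("derivative_source must be 'network' or 'data'")


@dataclass
class SimpleFitResult:
    best_net: SimpleNet
    beta_hat: float
    sigma_hat: float
    loss_breakdown: LossBreakdown
    per_restart_losses: np.ndarray
    config: SimpleFitConfig = None


def _net_to_mlp(net: SimpleNet) -> MLP:
    params = [(net.hidden_w[:, None], net.hidden_b.copy()),
              (net.out_w.copy(), net.out_b.copy())]
    return MLP(DenseArchitecture(hidden=(net.n_neurons,)), params=params)


def _mlp_to_net(mlp: MLP) -> SimpleNet:
    (W1, b1), (W2, b2) = mlp.params
    return SimpleNet(W1[:, 0], b1, W2, b2)


def _loss_terms(u_hat, obs, beta, sigma, N, derivative_source):
    """Return (mse_data, dinn_residual, residual array, states used)."""
    mse_data = float(np.mean((u_hat - obs) ** 2))
    src = u_hat if derivative_source == "network" else obs
    d = fd_derivative(src)                       # (T-1, 3)
    S, I = src[:-1, 0], src[:-1, 1]
    infection = beta * S * I / N
    r = np.column_stack([
        d[:, 0] + infection,
        d[:, 1] - infection + sigma * I,
        d[:, 2] - sigma * I,
    ])
    return mse_data, float(np.mean(r ** 2)), r, src


def simple_loss(net: SimpleNet, beta: float, sigma: float, data: Trajectory,
                weights: tuple = (1.0, 1.0), derivative_source: str = "network") -> LossBreakdown:
    """Data MSE plus finite-difference ODE residual for a candidate fit.

    ``mse_data`` averages squared prediction errors over all days and
    compartments; ``dinn_residual`` averages the squared forward-difference
    residuals of the three SIR equations over the T-1 interior days and the
    compartments.  ``total`` is their weighted sum.
    """
    if len(data) == 0:
        raise ValueError("empty trajectory")
    u_hat = np.atleast_2d(net(data.times))
    if len(data) < 2:
        mse_data = float(np.mean((u_hat - data.states) ** 2))
        w_data, w_ode = weights
        return LossBreakdown(mse_data, 0.0, w_data * mse_data)
    mse, res, _, _ = _loss_terms(u_hat, data.states, beta, sigma, data.N, derivative_source)
    w_data, w_ode = weights
    return LossBreakdown(mse, res, w_data * mse + w_ode * res)


def _value_and_grad(flat, mlp, times, obs, N, weights, derivative_source):
    """Total loss and its gradient w.r.t. [net params..., beta, sigma]."""
    mlp.set_flat(flat[:-2])
    beta, sigma = flat[-2], flat[-1]
    u_hat, cache = mlp.forward(times)
    T = len(times)
    w_data, w_ode = weights
    mse, res, r, src = _loss_terms(u_hat, obs, beta, sigma, N, derivative_source)
    total = w_data * mse + w_ode * res

    # gradient through the data-MSE path
    dL_du = w_data * 2.0 * (u_hat - obs) / obs.size
    # gradient through the residual path
    a = w_ode * 2.0 * r / r.size                 # (T-1, 3) dL/dr
    S, I = src[:-1, 0], src[:-1, 1]
    g_beta = float(np.sum((a[:, 0] - a[:, 1]) * S * I / N))
    g_sigma = float(np.sum((a[:, 1] - a[:, 2]) * I))
    if derivative_source == "network":
        # d_j = u_{j+1} - u_j
        dL_du[1:] += a
        dL_du[:-1] -= a
        # state terms at day j
        dL_du[:-1, 0] += (a[:, 0] - a[:, 1]) * beta * I / N
        dL_du[:-1, 1] += (a[:, 0] - a[:, 1]) * beta * S / N + a[:, 1] * sigma - a[:, 2] * sigma
    grads = mlp.backprop(cache, dL_du)
    g_net = np.concatenate([np.concatenate([gW.ravel(), gb]) for gW, gb in grads])
    return total, np.concatenate([g_net, [g_beta, g_sigma]])


def _draw_start(rng, K, times, wb, beta_bounds, sigma_bounds) -> np.ndarray:
    """Random restart point within the bounds, shaped to be trainable.

    A ReLU unit ``max(0, w*t + b)`` is useful only if its kink ``-b/w``
    falls inside the observation window; a uniform draw over the whole
    ``[-wb, wb]`` box with times spanning tens of days leaves most units
    dead (zero gradient) and traps the local optimizer.  Starts are instead
    drawn with slopes of moderate magnitude and kinks uniform over the
    window, output weights scaled so predictions start at order one on the
    normalized scale, and (beta, sigma) uniform in their boxes.
    """
    t0, t1 = float(times[0]), float(times[-1])
    span = max(t1 - t0, 1.0)
    w = rng.uniform(0.05, 1.0, K) * rng.choice([-1.0, 1.0], K)
    tau = rng.uniform(t0, t1, K)
    b = np.clip(-w * tau, -wb, wb)
    amp = 1.0 / np.maximum(np.abs(w) * span, 1.0)
    out_w = rng.uniform(-1.0, 1.0, (3, K)) * amp
    out_b = rng.uniform(0.0, 1.0, 3)
    return np.concatenate([
        w, b, out_w.ravel(), out_b,
        [rng.uniform(*beta_bounds), rng.uniform(*sigma_bounds)],
    ])


def fit_simple_dinn(data: Trajectory, config: SimpleFitConfig = SimpleFitConfig()) -> SimpleFitResult:
    """Multistart bounded minimization of the simple-PINN loss.

    Runs ``n_restarts`` L-BFGS-B minimizations from random starting points
    within the parameter boxes (see :func:`_draw_start` for the start
    distribution) and returns the restart with the smallest total loss.
    Deterministic given ``config.seed``.  Data with ``N != 1`` are
    normalized internally; beta and sigma are unaffected by that rescaling.
    """
    if len(data) < 2:
        raise ValueError("need at least 2 days of data to fit")
    data = normalize(data)
    times, obs = data.times, data.states
    K = config.n_neurons
    mlp = MLP(DenseArchitecture(hidden=(K,)), seed=0)
    n_net = mlp.get_flat().size

    wb = config.weight_bound
    bounds = [(-wb, wb)] * n_net + [config.beta_bounds, config.sigma_bounds]
    rng = np.random.default_rng(config.seed)

    best = None
    per_restart = np.full(config.n_restarts, np.inf)
    for k in range(config.n_restarts):
        x0 = _draw_start(rng, K, times, wb, config.beta_bounds, config.sigma_bounds)
        try:
            res = minimize(
                _value_and_grad, x0, jac=True, method="L-BFGS-B", bounds=bounds,
                args=(mlp, times, obs, data.N, config.loss_weights, config.derivative_source),
                options={"maxiter": config.max_iter, "ftol": config.tolerance,
                         "gtol": 1e-12, "maxfun": 10 * config.max_iter},
            )
        except FloatingPointError:
            continue
        if not np.isfinite(res.fun):
            continue
        per_restart[k] = res.fun
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        raise RuntimeError(
            f"all {config.n_restarts} restarts failed; per-restart losses: {per_restart}")

    mlp.set_flat(best.x[:-2])
    net = _mlp_to_net(mlp)
    beta_hat, sigma_hat = float(best.x[-2]), float(best.x[-1])
    breakdown = simple_loss(net, beta_hat, sigma_hat, data,
                            config.loss_weights, config.derivative_source)
    return SimpleFitResult(net, beta_hat, sigma_hat, breakdown, per_restart, config)


def error_vs_neurons(data: Trajectory, widths=(1, 2, 3, 4, 5),
                     config: SimpleFitConfig = SimpleFitConfig(),
                     true_params: SIRParameters = PROTOCOL.params) -> pd.DataFrame:
    """Relative parameter errors as a function of hidden width.

    Fits the simple-PINN once per width on the same data with the same seed
    schedule and tabulates the relative errors of beta-hat and sigma-hat
    against the generating parameters.  A failed fit is recorded in its row
    (NaN estimates plus the error message); the sweep continues.
    """
    from .pinn import relative_error

    rows = []
    for K in sorted(widths):
        cfg = replace(config, n_neurons=int(K))
        try:
            fit = fit_simple_dinn(data, cfg)
            rows.append({
                "width": K, "beta_hat": fit.beta_hat, "sigma_hat": fit.sigma_hat,
                "rel_err_beta": relative_error(fit.beta_hat, true_params.beta),
                "rel_err_sigma": relative_error(fit.sigma_hat, true_params.sigma),
                "total_loss": fit.loss_breakdown.total, "error": "",
            })
        except Exception as exc:  # record, do not abort the sweep
            rows.append({"width": K, "beta_hat": np.nan, "sigma_hat": np.nan,
                         "rel_err_beta": np.nan, "rel_err_sigma": np.nan,
                         "total_loss": np.nan, "error": str(exc)})
    return pd.DataFrame(rows)
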