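"""Fit the spreadsheet-style simple-PINN and sweep the hidden width.

A one-hidden-layer ReLU network plus forward-difference ODE residuals,
optimized jointly over weights and (beta, sigma) by multistart L-BFGS-B.
With 5 neurons the recovered rates land within a few percent of the truth;
with 1 neuron the piecewise-linear model is too stiff and the physics
parameters absorb the misfit.
"""

from dinn import SimpleFitConfig, default_protocol_data, fit_simple_dinn, relative_error

data = default_protocol_data(seed=0)

for k in (1, 5):
    fit = fit_simple_dinn(data, SimpleFitConfig(n_neurons=k, n_restarts=20, seed=0))
    bd = fit.loss_breakdown
    print(f"{k} neuron(s): beta_hat = {fit.beta_hat:.4f}  sigma_hat = {fit.sigma_hat:.4f}")
    print(f"   relative errors: beta {relative_error(fit.beta_hat, 0.5):.3f}, "
          f"sigma {relative_error(fit.sigma_hat, 1 / 14):.3f}")
    print(f"   error log: MSE = {bd.mse_data:.2e}  DINN = {bd.dinn_residual:.2e}  "
          f"MSE+DINN = {bd.total:.2e}")

print("\nThe width-5 fit should show relative errors below 0.05 for both "
      "rates; the width-1 fit is capacity-limited and much worse.")
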