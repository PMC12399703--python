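# dinn — disease-informed neural networks for the SIR inverse problem

`dinn` estimates the transmission rate β and recovery rate σ of an SIR
epidemic jointly with the epidemic trajectories, from a noisy daily time
series of the three compartments.  It is aimed at epidemiological
modellers and at teaching settings that want a fully transparent,
dependency-light implementation of physics-informed neural networks for
compartmental models.

The SIR model in a closed population of size N:

    dS/dt = −β S I / N,   dI/dt = β S I / N − σ I,   dR/dt = σ I,

with S + I + R = N.  Given observations {tʲ, (Sʲ, Iʲ, Rʲ)}, a network
û(t; θ̂) is trained under the composite loss

    L(λ̂, θ̂) = L_ode + L_ic + L_data,

where L_data penalizes the mismatch with the observations, L_ic the
initial condition, and L_ode the squared SIR residuals evaluated on the
network's own outputs and time derivatives.  The physics vector
λ̂ = (β̂, σ̂) is appended to the learnable parameters, so minimizing L
solves the inverse problem.

Two estimators are provided:

* **Simple-PINN** (`dinn.simple`): one hidden ReLU layer (1–5 neurons),
  forward-difference residuals on the daily grid, fitted by multistart
  bounded L-BFGS-B over weights and (β, σ) — the method is small enough to
  run in a spreadsheet solver, re-implemented here with analytic gradients.
* **Full PINN** (`dinn.pinn`): a 1→64→64→64→3 ReLU network with exact
  closed-form time derivatives and hand-derived reverse-mode gradients
  (verified against finite differences), trained by Adam (lr 0.001,
  30,000 full-batch iterations) with Glorot-Uniform initialization and
  λ̂ initialized at zero.

Plus a forward simulator with a noisy-data protocol (`dinn.sir`), an
initialization-robustness study with learning-curve confidence bands
(`dinn.experiments`), and a thin CLI (`dinn.cli`).

## Worked example

```python
from dinn import PinnConfig, default_protocol_data, train_pinn

data = default_protocol_data(seed=0)   # RK4 + 1% noise, 60 days
model, trace = train_pinn(data, PinnConfig(iterations=30_000, init_seed=0))
print(model.beta_hat, model.sigma_hat)
```

Running `python examples/03_pinn_inverse.py` (this exact computation)
prints:

```
learning process (every 5000 iterations):
  iter      0: beta_hat =  0.0000  sigma_hat =  0.0000  total loss = 7.640e+00
  iter   5000: beta_hat =  0.4866  sigma_hat =  0.0709  total loss = 6.905e-04
  iter  10000: beta_hat =  0.4990  sigma_hat =  0.0708  total loss = 3.307e-04
  ...
  iter  30000: beta_hat =  0.4922  sigma_hat =  0.0703  total loss = 2.555e-04

final estimates: beta_hat = 0.4922 (true 0.5), sigma_hat = 0.07034 (true 0.07143)
relative errors: 0.0155, 0.0153
```

Both rates start at zero, rise within the first few thousand iterations
and settle near the generating values; with 1% measurement noise the
recovered rates are accurate to ~1–2%.  The other example scripts cover
the simulator (`01`), the simple-PINN and its error-vs-width behaviour
(`02`), and the multi-initialization robustness study (`04`).

The CLI mirrors the library:

```
dinn simulate --seed 0 --out data.csv
dinn fit-simple --data data.csv --neurons 5 --report fit.csv
dinn fit-pinn --data data.csv --iters 30000 --trace trace.csv
dinn robustness --runs 30 --iters 30000
```

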