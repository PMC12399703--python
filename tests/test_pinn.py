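"""PINN inverse problem: residuals, composite loss, training behaviour."""

import numpy as np
import pytest

from dinn import (
    DenseArchitecture,
    MLP,
    PinnConfig,
    PinnModel,
    Trajectory,
    integrate_sir,
    normalize,
    ode_residuals,
    pinn_loss,
    relative_error,
    train_pinn,
)
from dinn.pinn import TrainingDivergence, _residuals_from_arrays
from dinn.sir import PROTOCOL, SIRParameters, sir_rhs

SHORT = PinnConfig(architecture=DenseArchitecture(hidden=(16, 16)),
                   iterations=300, trace_every=100)


class TestRelativeError:
    @pytest.mark.parametrize("est,truth,expected", [
        (0.4971, 0.5, 0.0058),
        (0.607, 0.5, 0.214),
        (0.3, 0.3, 0.0),
        (-0.1, 0.5, 1.2),
    ])
    def test_values(self, est, truth, expected):
        assert relative_error(est, truth) == pytest.approx(expected)

    def test_zero_truth_rejected(self):
        with pytest.raises(ValueError):
            relative_error(0.1, 0.0)


class TestResiduals:
    def test_constant_outputs_with_zero_rates(self):
        mlp = MLP(DenseArchitecture(hidden=(8,)), seed=0)
        mlp.set_flat(np.zeros(mlp.get_flat().size))
        model = PinnModel(mlp, np.array([0.0, 0.0]), N=1.0)
        r = ode_residuals(model, np.arange(10.0))
        np.testing.assert_array_equal(r, np.zeros((10, 3)))

    def test_sum_identity(self, rng):
        # residuals sum to d(S+I+R)/dt: the physics terms telescope
        mlp = MLP(DenseArchitecture(hidden=(12, 12)), seed=4)
        mlp.set_flat(rng.uniform(-0.5, 0.5, mlp.get_flat().size))
        model = PinnModel(mlp, np.array([0.37, 0.11]), N=1.0)
        t = rng.uniform(0, 59, 10)
        r = ode_residuals(model, t)
        _, dudt, _ = mlp.forward(t, with_derivative=True)
        np.testing.assert_allclose(r.sum(axis=1), dudt.sum(axis=1), atol=1e-12)

    def test_true_solution_annihilates_residuals(self):
        # evaluate the residual formulas on a finely resolved clean
        # trajectory with central-difference derivatives and true rates
        p = PROTOCOL.params
        t = np.arange(0, 59.0, 0.01)
        traj = integrate_sir(p, PROTOCOL.initial, times=t, substeps=1)
        u = traj.states
        dudt = np.gradient(u, 0.01, axis=0)
        r = _residuals_from_arrays(u, dudt, p.beta, p.sigma, p.N)
        assert np.abs(r[1:-1]).max() < 1e-2  # counts/day on the N=1000 scale

    def test_exact_rhs_derivatives_give_zero(self):
        p = PROTOCOL.params
        traj = integrate_sir(p, PROTOCOL.initial, days=60)
        dudt = sir_rhs(traj.states, p)
        r = _residuals_from_arrays(traj.states, dudt, p.beta, p.sigma, p.N)
        np.testing.assert_allclose(r, 0.0, atol=1e-12)


class TestLoss:
    def test_all_weights_zero(self, protocol_noisy):
        model = PinnModel(MLP(seed=0), np.array([0.3, 0.1]), N=1.0)
        cfg = PinnConfig(w_ode=(0, 0, 0), w_ic=(0, 0, 0), w_data=(0, 0, 0))
        total, comps = pinn_loss(model, normalize(protocol_noisy), cfg)
        assert total == 0.0

    def test_single_day_single_compartment_hand_value(self):
        # constant model output 3 vs observation 1 in S only, one day,
        # data weight 1: L_data = (3-1)^2 / 1 = 4
        mlp = MLP(DenseArchitecture(hidden=(4,)), seed=0)
        mlp.set_flat(np.zeros(mlp.get_flat().size))
        W, b = mlp.params[-1]
        b[:] = [3.0, 0.0, 0.0]
        model = PinnModel(mlp, np.array([0.0, 0.0]), N=1.0)
        data = Trajectory(times=[0.0], states=[[1.0, 0.0, 0.0]], N=1.0)
        cfg = PinnConfig(w_ic=(0, 0, 0), w_ode=(0, 0, 0))
        total, comps = pinn_loss(model, data, cfg)
        assert comps["L_data"] == pytest.approx(4.0)
        assert total == pytest.approx(4.0)
        # with the initial-condition weight on, day 0 is counted again
        total_ic, comps_ic = pinn_loss(model, data, PinnConfig(w_ode=(0, 0, 0)))
        assert comps_ic["L_ic"] == pytest.approx(4.0)
        assert total_ic == pytest.approx(8.0)

    def test_components_nonnegative_and_sum(self, protocol_noisy, rng):
        mlp = MLP(DenseArchitecture(hidden=(8,)), seed=1)
        mlp.set_flat(rng.uniform(-0.5, 0.5, mlp.get_flat().size))
        model = PinnModel(mlp, np.array([0.4, 0.1]), N=1.0)
        total, comps = pinn_loss(model, normalize(protocol_noisy))
        for key in ("L_ode", "L_ic", "L_data"):
            assert comps[key] >= 0
        assert total == pytest.approx(comps["L_ode"] + comps["L_ic"] + comps["L_data"])
        assert comps["L_ode"] == pytest.approx(
            comps["L_ode_S"] + comps["L_ode_I"] + comps["L_ode_R"])

    def test_empty_data_rejected(self):
        model = PinnModel(MLP(seed=0), np.zeros(2), N=1.0)
        empty = Trajectory(times=np.empty(0), states=np.empty((0, 3)), N=1.0)
        with pytest.raises(ValueError):
            pinn_loss(model, empty)


class TestTraining:
    def test_trace_starts_at_zero_and_covers_endpoints(self, protocol_noisy):
        model, trace = train_pinn(protocol_noisy, SHORT)
        df = trace.to_frame()
        assert df.iloc[0]["iteration"] == 0
        assert df.iloc[0]["beta_hat"] == 0.0 and df.iloc[0]["sigma_hat"] == 0.0
        assert df.iloc[-1]["iteration"] == SHORT.iterations
        np.testing.assert_allclose(
            df["total"], df["L_ode"] + df["L_ic"] + df["L_data"], rtol=1e-12)

    def test_loss_decreases(self, protocol_noisy):
        _, trace = train_pinn(protocol_noisy, SHORT)
        df = trace.to_frame()
        assert df.iloc[-1]["total"] < df.iloc[0]["total"]

    def test_deterministic_given_seed(self, protocol_noisy):
        cfg = PinnConfig(architecture=DenseArchitecture(hidden=(16,)),
                         iterations=200, init_seed=7)
        m1, t1 = train_pinn(protocol_noisy, cfg)
        m2, t2 = train_pinn(protocol_noisy, cfg)
        assert m1.beta_hat == m2.beta_hat and m1.sigma_hat == m2.sigma_hat
        np.testing.assert_array_equal(t1.to_frame().to_numpy(), t2.to_frame().to_numpy())

    def test_different_seeds_differ(self, protocol_noisy):
        cfg1 = PinnConfig(architecture=DenseArchitecture(hidden=(16,)), iterations=200)
        cfg2 = PinnConfig(architecture=DenseArchitecture(hidden=(16,)), iterations=200,
                          init_seed=1)
        m1, _ = train_pinn(protocol_noisy, cfg1)
        m2, _ = train_pinn(protocol_noisy, cfg2)
        assert m1.beta_hat != m2.beta_hat

    def test_frozen_lambda_clean_data_converges(self, protocol_clean):
        # with (beta, sigma) frozen at the truth, 5000 iterations drive
        # L_ode + L_data at least an order of magnitude below the start
        cfg = PinnConfig(iterations=5000, lambda_init=(0.5, 1 / 14),
                         learn_lambda=False)
        model, trace = train_pinn(protocol_clean, cfg)
        df = trace.to_frame()
        start = df.iloc[0]["L_ode"] + df.iloc[0]["L_data"]
        end = df.iloc[-1]["L_ode"] + df.iloc[-1]["L_data"]
        assert end < start / 10
        assert model.beta_hat == 0.5 and model.sigma_hat == 1 / 14

    def test_nonfinite_loss_raises_with_trace(self):
        # data far beyond float range overflows the squared error: training
        # must stop with a training-failure error that carries the trace
        bad = Trajectory(times=np.arange(4.0),
                         states=np.full((4, 3), 1e200), N=1.0)
        cfg = PinnConfig(architecture=DenseArchitecture(hidden=(8,)),
                         iterations=50, trace_every=1, normalize_data=False)
        with np.errstate(all="ignore"), pytest.raises(TrainingDivergence) as exc:
            train_pinn(bad, cfg)
        assert exc.value.trace is not None

    def test_empty_data_rejected(self):
        empty = Trajectory(times=np.empty(0), states=np.empty((0, 3)), N=1.0)
        with pytest.raises(ValueError):
            train_pinn(empty, SHORT)

    def test_clean_data_recovers_better_than_noisy(self):
        """Averaged over seeds, noise-free data yields smaller errors."""
        from dinn import add_white_noise, NoiseSpec
        clean = integrate_sir(PROTOCOL.params, PROTOCOL.initial, days=60)
        errs = {"clean": [], "noisy": []}
        for seed in range(5):
            noisy = add_white_noise(clean, NoiseSpec(level=0.01, seed=seed))
            for tag, data in (("clean", clean), ("noisy", noisy)):
                m, _ = train_pinn(data, PinnConfig(iterations=20_000, init_seed=seed))
                errs[tag].append(max(relative_error(m.beta_hat, 0.5),
                                     relative_error(m.sigma_hat, 1 / 14)))
        assert np.mean(errs["clean"]) < np.mean(errs["noisy"])
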