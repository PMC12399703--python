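"""Initialization-robustness study and reporting artifacts.

The headline experiment: train the PINN repeatedly on one fixed noisy
dataset, varying only the network weight initialization (run ``k`` uses
seed ``seed_base + k``), and summarize the spread of the recovered
``(beta, sigma)`` — per-run estimates and relative errors, cross-run mean,
standard deviation, median and quartiles, and cross-run learning curves
with a normal-approximation 95% confidence band on the mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .pinn import PinnConfig, TrainingTrace, relative_error, train_pinn
from .sir import PROTOCOL, Trajectory

__all__ = [
    "RobustnessConfig",
    "RunSummary",
    "run_robustness",
    "summarize_learning_curves",
    "render_reports",
]

TRUE_BETA = PROTOCOL.params.beta
TRUE_SIGMA = PROTOCOL.params.sigma


@dataclass(frozen=True)
class RobustnessConfig:
    """Repeated-training configuration: ``n_runs`` trainings on shared data,
    weight-init seed ``seed_base + k`` for run ``k``."""

    n_runs: int = 30
    seed_base: int = 0
    pinn: PinnConfig = field(default_factory=PinnConfig)
    true_beta: float = TRUE_BETA
    true_sigma: float = TRUE_SIGMA

    def __post_init__(self):
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")


@dataclass
class RunSummary:
    """Per-run results plus cross-run aggregates of the robustness study."""

    runs: pd.DataFrame          # one row per run (failed runs flagged)
    aggregates: pd.DataFrame    # mean/sd/median/quartiles per statistic
    traces: list                # TrainingTrace per successful run
    n_requested: int
    n_completed: int

    @property
    def complete(self) -> bool:
        return self.n_completed == self.n_requested


_AGG_COLUMNS = ["beta_hat", "sigma_hat", "rel_err_beta", "rel_err_sigma", "final_total_loss"]


def _aggregate(runs: pd.DataFrame) -> pd.DataFrame:
    ok = runs[runs["status"] == "ok"]
    rows = []
    for col in _AGG_COLUMNS:
        x = ok[col].to_numpy(dtype=float)
        rows.append({
            "statistic": col,
            "n": len(x),
            "mean": float(np.mean(x)) if len(x) else np.nan,
            # sample sd (n-1); undefined for a single run
            "sd": float(np.std(x, ddof=1)) if len(x) > 1 else np.nan,
            "median": float(np.median(x)) if len(x) else np.nan,
            "q1": float(np.quantile(x, 0.25)) if len(x) else np.nan,
            "q3": float(np.quantile(x, 0.75)) if len(x) else np.nan,
        })
    return pd.DataFrame(rows)


def run_robustness(data: Trajectory, config: RobustnessConfig = RobustnessConfig()) -> RunSummary:
    """Train the PINN ``n_runs`` times on ``data``, varying only the weight
    initialization, and aggregate the recovered parameters.

    Every run is recorded before aggregation — a run whose training diverges
    appears with ``status='failed'`` rather than being silently dropped, and
    the summary flags the incomplete count.  Deterministic given
    ``seed_base`` (runs are independent, so their order is immaterial).
    """
    rows, traces = [], []
    for k in range(config.n_runs):
        seed = config.seed_base + k
        cfg = replace(config.pinn, init_seed=seed)
        row = {"run": k, "init_seed": seed}
        try:
            model, trace = train_pinn(data, cfg)
            final = trace.records[-1]
            row.update({
                "status": "ok",
                "beta_hat": model.beta_hat, "sigma_hat": model.sigma_hat,
                "rel_err_beta": relative_error(model.beta_hat, config.true_beta),
                "rel_err_sigma": relative_error(model.sigma_hat, config.true_sigma),
                "final_total_loss": final["total"], "final_L_ode": final["L_ode"],
                "final_L_ic": final["L_ic"], "final_L_data": final["L_data"],
            })
            traces.append(trace)
        except Exception as exc:
            row.update({"status": "failed", "message": str(exc),
                        "beta_hat": np.nan, "sigma_hat": np.nan,
                        "rel_err_beta": np.nan, "rel_err_sigma": np.nan,
                        "final_total_loss": np.nan})
        rows.append(row)
    runs = pd.DataFrame(rows)
    n_completed = int((runs["status"] == "ok").sum())
    return RunSummary(runs, _aggregate(runs), traces, config.n_runs, n_completed)


def summarize_learning_curves(traces: list, confidence: float = 0.95) -> pd.DataFrame:
    """Cross-run mean learning curves of beta-hat and sigma-hat with a
    normal-approximation confidence band (mean ± z * sd / sqrt(n)).

    All traces must share the same recording grid.  With identical traces
    the band has zero width; at iteration 0 it is centred on the common
    initialization.
    """
    from scipy.stats import norm

    if not traces:
        raise ValueError("no traces to summarize")
    frames = [t.to_frame() if isinstance(t, TrainingTrace) else t for t in traces]
    grid = frames[0]["iteration"].to_numpy()
    for f in frames[1:]:
        if not np.array_equal(f["iteration"].to_numpy(), grid):
            raise ValueError("traces do not share a recording grid")
    z = norm.ppf(0.5 + confidence / 2.0)
    n = len(frames)
    out = {"iteration": grid}
    for param in ("beta_hat", "sigma_hat"):
        stack = np.stack([f[param].to_numpy(dtype=float) for f in frames])
        mean = stack.mean(axis=0)
        sd = stack.std(axis=0, ddof=1) if n > 1 else np.zeros_like(mean)
        half = z * sd / np.sqrt(n)
        out[f"{param}_mean"] = mean
        out[f"{param}_lo"] = mean - half
        out[f"{param}_hi"] = mean + half
    return pd.DataFrame(out)


def render_reports(summary: RunSummary, outdir) -> dict:
    """Write the study artifacts: a relative-error box/violin figure, a
    learning-curve figure with confidence bands, and CSV tables of the
    per-run results and aggregates.  Returns the written paths."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if summary.n_completed == 0 or len(summary.runs) == 0:
        raise ValueError("empty summary: no completed runs to report")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    runs_csv = outdir / "runs.csv"
    summary_csv = outdir / "summary.csv"
    summary.runs.to_csv(runs_csv, index=False)
    summary.aggregates.to_csv(summary_csv, index=False)

    ok = summary.runs[summary.runs["status"] == "ok"]
    errs = [ok["rel_err_beta"].to_numpy(), ok["rel_err_sigma"].to_numpy()]
    fig, axes = plt.subplots(1, 2, figsize=(9, 4))
    axes[0].boxplot(errs, tick_labels=[r"$\beta$", r"$\sigma$"])
    axes[0].set_ylabel("relative error")
    axes[0].set_title(f"Parameter recovery spread ({summary.n_completed} runs)")
    axes[1].violinplot(errs, showmedians=True)
    axes[1].set_xticks([1, 2], [r"$\beta$", r"$\sigma$"])
    axes[1].set_title("Violin view")
    fig.tight_layout()
    errors_png = outdir / "relative_errors.png"
    fig.savefig(errors_png, dpi=120)
    plt.close(fig)

    curves = summarize_learning_curves(summary.traces)
    fig, axes = plt.subplots(2, 1, figsize=(7, 6), sharex=True)
    for ax, param, truth in zip(axes, ("beta_hat", "sigma_hat"),
                                (TRUE_BETA, TRUE_SIGMA)):
        it = curves["iteration"]
        ax.plot(it, curves[f"{param}_mean"], label="mean estimate")
        ax.fill_between(it, curves[f"{param}_lo"], curves[f"{param}_hi"], alpha=0.3,
                        label="95% CI of mean")
        ax.axhline(truth, color="tab:orange", ls="--", label="true value")
        ax.set_ylabel(param.replace("_hat", " estimate"))
        ax.legend(loc="lower right", fontsize=8)
    axes[-1].set_xlabel("iteration")
    fig.tight_layout()
    curves_png = outdir / "learning_curves.png"
    fig.savefig(curves_png, dpi=120)
    plt.close(fig)

    return {"runs_csv": runs_csv, "summary_csv": summary_csv,
            "errors_png": errors_png, "curves_png": curves_png}
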