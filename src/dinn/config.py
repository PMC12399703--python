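"""Run configuration: dataclasses with protocol defaults + YAML round-trip.

An empty configuration file reproduces the standard protocol end-to-end:
beta=0.5, sigma=1/14, N=1000, (999, 1, 0) initial condition, 60 days, 1%
noise; 3x64 ReLU PINN, Adam lr 0.001, 30,000 iterations; 30-run robustness
study.  Unknown keys are rejected by name, so typos fail loudly instead of
silently falling back to defaults.
"""

from __future__ import annotations

from dataclasses import MISSING, asdict, dataclass, field, fields, is_dataclass
from pathlib import Path

import yaml


class ConfigError(ValueError):
    pass


@dataclass
class SimulateConfig:
    beta: float = 0.5
    sigma: float = 1.0 / 14.0
    N: float = 1000.0
    S0: float = 999.0
    I0: float = 1.0
    R0: float = 0.0
    days: int = 60
    noise: float = 0.01
    seed: int = 0
    out: str = "data.csv"


@dataclass
class SimpleFitRun:
    neurons: int = 5
    restarts: int = 20
    seed: int = 0
    report: str = "simple_fit.csv"


@dataclass
class PinnRun:
    layers: tuple = (64, 64, 64)
    lr: float = 0.001
    iterations: int = 30_000
    seed: int = 0
    trace: str = "trace.csv"


@dataclass
class RobustnessRun:
    runs: int = 30
    seed_base: int = 0
    iterations: int = 30_000


@dataclass
class RunConfig:
    command: str = ""
    outdir: str = "results"
    log_level: str = "INFO"
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    fit_simple: SimpleFitRun = field(default_factory=SimpleFitRun)
    fit_pinn: PinnRun = field(default_factory=PinnRun)
    robustness: RobustnessRun = field(default_factory=RobustnessRun)


def _build(cls, mapping, path="config"):
    if mapping is None:
        mapping = {}
    if not isinstance(mapping, dict):
        raise ConfigError(f"{path}: expected a mapping, got {type(mapping).__name__}")
    known = {f.name: f for f in fields(cls)}
    unknown = set(mapping) - set(known)
    if unknown:
        raise ConfigError(f"{path}: unknown key(s): {', '.join(sorted(unknown))}")
    kwargs = {}
    for name, value in mapping.items():
        f = known[name]
        if f.default_factory is not MISSING and is_dataclass(f.default_factory):
            kwargs[name] = _build(f.default_factory, value, f"{path}.{name}")
        elif name == "layers":
            kwargs[name] = tuple(value)
        else:
            kwargs[name] = value
    return cls(**kwargs)


def load_config(path) -> RunConfig:
    """Load a YAML run configuration; absent keys take protocol defaults."""
    text = Path(path).read_text()
    try:
        mapping = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    return _build(RunConfig, mapping)


def save_config(cfg: RunConfig, path) -> None:
    d = asdict(cfg)
    d["fit_pinn"]["layers"] = list(d["fit_pinn"]["layers"])
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))
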