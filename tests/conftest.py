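import numpy as np
import pytest

from dinn import (
    PinnConfig,
    RobustnessConfig,
    SIRParameters,
    default_protocol_data,
    integrate_sir,
    run_robustness,
)
from dinn.sir import PROTOCOL

TRUE_BETA = PROTOCOL.params.beta
TRUE_SIGMA = PROTOCOL.params.sigma


@pytest.fixture(scope="session")
def protocol_clean():
    """Clean 60-day trajectory under the standard generating parameters."""
    return integrate_sir(PROTOCOL.params, PROTOCOL.initial, days=PROTOCOL.days)


@pytest.fixture(scope="session")
def protocol_noisy():
    """The standard 60-day dataset with 1% additive noise, seed 0."""
    return default_protocol_data(seed=0)


@pytest.fixture(scope="session")
def robustness5(protocol_noisy):
    """Five full PINN trainings (30,000 iterations each) on shared data.

    Session-scoped because it takes a couple of minutes; it backs both the
    parameter-recovery and convergence-behaviour checks.  Run 0 uses the
    default configuration (init seed 0).
    """
    return run_robustness(
        protocol_noisy, RobustnessConfig(n_runs=5, seed_base=0, pinn=PinnConfig())
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
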