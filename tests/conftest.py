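import math

import numpy as np
import pytest

from cloneclock import EvolutionParams, SimulationConfig

LAM = math.log(1.6)  # net growth rate at the benchmark death rate 0.2


@pytest.fixture(scope="session")
def benchmark_config():
    """The reference simulation conditions (depth 120x, death rate 0.2)."""
    return SimulationConfig()


@pytest.fixture(scope="session")
def small_config():
    """Down-scaled exact phase for tests that need many replicates."""
    return SimulationConfig(cutover_size=800)


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)


def random_valid_params(rng, n=1):
    """Random fully-specified parameter vectors with te closed through the
    clone-ratio identity (so the logit identity holds by construction)."""
    from cloneclock import solve_sampling_time

    out = []
    for _ in range(n):
        s = float(rng.uniform(0.125, 1.625))
        tf = float(rng.uniform(1.0, 14.0))
        P = float(rng.uniform(0.02, 0.98))
        lam = float(rng.uniform(0.2, 0.7))
        te = solve_sampling_time(P, s, tf, lam)
        if te <= tf:
            continue
        out.append(
            EvolutionParams(mu=16.0, s=s, tf=tf, te=te, lambda_beta=lam, P=P)
        )
    return out
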