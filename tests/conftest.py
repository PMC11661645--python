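import numpy as np
import pytest

from rrtvar import (
    PopulationSpec,
    ScramblingParams,
    builtin_specs,
    generate_population,
    population_moments,
    scramble,
)
from rrtvar.synthpop import FIXTURE_SIGMA2_S, FIXTURE_SIGMA2_T

# printed scrambling variances of the table-style fixture runs
S2S, S2T = FIXTURE_SIGMA2_S, FIXTURE_SIGMA2_T


@pytest.fixture(scope="session")
def pop1():
    """One seeded draw of built-in Population I (no scrambling)."""
    return generate_population(builtin_specs()[0], seed=101)


@pytest.fixture(scope="session")
def diana_params():
    return ScramblingParams("diana_perri", S2S, S2T)


@pytest.fixture(scope="session")
def genh_params():
    """Mixture model at h = 0: numerically the same scramble as diana."""
    return ScramblingParams("generalized_h", S2S, S2T, alpha=1.0, mix=0.0)


@pytest.fixture(scope="session")
def pop1_scrambled(pop1, diana_params):
    return scramble(pop1, diana_params, seed=102)


@pytest.fixture(scope="session")
def pm1(pop1_scrambled):
    return population_moments(pop1_scrambled)


def random_admissible(rng, model="diana_perri", N=200):
    """A random positive-definite population with a random scramble."""
    A = rng.normal(size=(3, 3))
    cov = A @ A.T + 0.5 * np.eye(3)
    mean = rng.uniform(3.0, 8.0, size=3)
    spec = PopulationSpec(
        "random", tuple(mean), tuple(tuple(r) for r in cov), N
    )
    params = ScramblingParams(
        model,
        sigma2_S=float(rng.uniform(0.05, 0.6)),
        sigma2_T=float(rng.uniform(0.05, 0.6)),
        alpha=1.0,
        mix=float(rng.uniform(0.0, 1.0)) if model != "diana_perri" else 0.0,
    )
    pop = generate_population(spec, int(rng.integers(2**31)))
    pop = scramble(pop, params, int(rng.integers(2**31)))
    return params, population_moments(pop)


def rel_diff(a, b):
    return abs(a - b) / max(abs(a), abs(b), 1e-12)
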