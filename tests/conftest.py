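import dataclasses

import numpy as np
import pytest

from steatomics.config import SignalPheno, SignalProtein, SimulationConfig


def small_config(seed: int = 0, **overrides) -> SimulationConfig:
    """A shrunken cohort (fast to generate and fit) with the same structure."""
    base = dict(
        n_total=300,
        discovery_n=220,
        genotype_missing_n=15,
        n_proteins=60,
        signal_proteins=(
            SignalProtein(2, +1),
            SignalProtein(19, +1),
            SignalProtein(35, +1),
            SignalProtein(8, -1),
            SignalProtein(24, -1),
            SignalProtein(40, -1),
            SignalProtein(48, -1),
            SignalProtein(56, -1),
        ),
        seed=seed,
    )
    base.update(overrides)
    return dataclasses.replace(SimulationConfig(), **base)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_cohort():
    from steatomics.simulate import generate_cohort

    return generate_cohort(small_config(seed=11))


def logistic_sample(rng, n, beta, intercept=0.0):
    """Draw (X, y) from a logistic model with standard-normal predictors."""
    from scipy.special import expit

    p = len(beta)
    X = rng.standard_normal((n, p))
    y = (rng.random(n) < expit(intercept + X @ np.asarray(beta))).astype(float)
    return X, y
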