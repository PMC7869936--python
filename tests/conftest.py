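import dataclasses

import numpy as np
import pytest

from germkin import (
    MassSeries,
    SampleSet,
    generate_cohort,
    random_ground_truth,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_series(rng, diaspore_id="d0", n=12, m0=0.2):
    """A random but well-behaved increasing-ish mass series."""
    times = np.arange(0.0, float(n), 1.0)
    increments = rng.uniform(0.0, 0.01, size=n - 1)
    masses = m0 + np.concatenate([[0.0], np.cumsum(increments)])
    masses = masses + rng.normal(0.0, 1e-4, size=n)
    masses = np.maximum(masses, 1e-4)
    return MassSeries(diaspore_id=diaspore_id, times=times, masses=masses)


@pytest.fixture
def small_sample(rng):
    series = tuple(make_series(rng, f"d{i}") for i in range(6))
    return SampleSet(label="toy", series=series)


@pytest.fixture
def default_gt():
    return random_ground_truth(11)


@pytest.fixture
def cohort(default_gt):
    sample, report = generate_cohort(default_gt)
    return sample


@pytest.fixture
def noiseless_gt():
    """A 4-phase truth with every stochastic/oscillatory component off."""
    gt = random_ground_truth(7, n_phases=4)
    return dataclasses.replace(
        gt, noise_sd=0.0, fluctuation_amplitude=0.0,
        ripple_amplitude=0.0, spike_amplitude=0.0, m0_cv=0.0,
    )
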