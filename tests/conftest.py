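"""Shared fixtures: the CPU-scale reference experiments are expensive
(seconds to a minute each), so they run once per session and are shared
between the property tests that probe different facets of each run."""

import numpy as np
import pytest

from devevent import experiments


@pytest.fixture(scope="session")
def temporal_results():
    return experiments.temporal_information_experiment(seed=1)


@pytest.fixture(scope="session")
def timing_results():
    return experiments.timing_recovery_experiment(seed=1)


@pytest.fixture(scope="session")
def triplet_results():
    return experiments.triplet_separation_experiment(seed=1)


@pytest.fixture(scope="session")
def stride_results():
    return experiments.stride_sweep_experiment(seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
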