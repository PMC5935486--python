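"""Shared fixtures: small synthetic cohorts reused across test modules."""

import numpy as np
import pytest

from gastrosync.simulate import EggSimParams, make_cohort, make_truth


@pytest.fixture(scope="session")
def tiny_truth():
    """8^3 grid, two planted 2^3 clusters at delays 0 and pi/2."""
    return make_truth(
        shape=(8, 8, 8), cluster_size=2, delays=(0.0, np.pi / 2), snr=2.5
    )


@pytest.fixture(scope="session")
def tiny_cohort(tiny_truth):
    """Six participants on the tiny grid; full 450-volume acquisitions.

    Six is the smallest cohort whose 2^6 sign-flip patterns allow a cluster
    p below the 0.025 per-tail retention level.
    """
    return make_cohort(6, truth=tiny_truth, seed=11)


@pytest.fixture(scope="session")
def one_egg():
    """A single default EGG recording (0.05 Hz base, 960 s at 10 Hz)."""
    from gastrosync.simulate import simulate_egg

    return simulate_egg(EggSimParams(seed=5))
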