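import numpy as np
import pytest

from synscreen import HillFit, hill


@pytest.fixture
def unit_fit():
    """Full-efficacy unit Hill curve: emax=1, EC50=1 µM, H=1."""
    return HillFit(emax=1.0, ec50_rel=1.0, hill_slope=1.0)


@pytest.fixture
def half_log_doses():
    """8 half-log doses spanning 0.0316-100 µM."""
    return 10.0 ** (np.arange(8) / 2.0 - 1.5)


def make_points(doses, emax, ec50, h, sd=0.0, seed=None):
    """Noisy points from a known Hill curve (test-local generator,
    independent of the package's simulators)."""
    y = hill(np.asarray(doses, float), emax, ec50, h)
    if sd:
        y = y + np.random.default_rng(seed).normal(0.0, sd, size=len(y))
    return list(zip(doses, y))
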