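import numpy as np
import pytest

import mdrc


@pytest.fixture(scope="session")
def protocol():
    """150-row ex vivo style protocol shared by recovery tests."""
    return mdrc.make_protocol("minimal", n_rows=150, seed=1)


@pytest.fixture(scope="session")
def limits():
    return mdrc.InversionLimits.ex_vivo_rat()


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def random_components(n, rng, d_range=(5e-12, 5e-9), gamma_range=(0.1, 1e5),
                      r1_range=(0.1, 4.0), r2_range=(1.0, 150.0)):
    """Log-uniform random component matrices for property tests."""
    lim = mdrc.InversionLimits(d_min=d_range[0], d_max=d_range[1],
                               gamma_min=gamma_range[0],
                               gamma_max=gamma_range[1],
                               r1_min=r1_range[0], r1_max=r1_range[1],
                               r2_min=r2_range[0], r2_max=r2_range[1])
    return mdrc.sample_components(lim, n, rng)


@pytest.fixture(scope="session")
def single_component_truth():
    """A mid-range anisotropic component and its noiseless signals."""
    params = np.array([[0.6e-9, 0.1e-9, 1.0, 0.5, 0.7e-9, 5e4, 5e4,
                        1.2, 35.0]])
    weights = np.array([1.0])
    return params, weights


def weighted_median(values, weights):
    order = np.argsort(values)
    cum = np.cumsum(weights[order]) / weights.sum()
    return values[order][np.searchsorted(cum, 0.5)]
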