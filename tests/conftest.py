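import numpy as np
import pytest

from mogobserver import MoGPrior, TwoAFCObserver


@pytest.fixture
def sg_prior():
    """Single-Gaussian prior, zero mean, SD 1.5 (the worked-example observer)."""
    return MoGPrior([1.0], [0.0], [1.5])


@pytest.fixture
def heavy_prior():
    """Two-component zero-mean heavy-tailed prior (broad + narrow)."""
    return MoGPrior([0.5, 0.5], [0.0, 0.0], [2.0, 0.6])


@pytest.fixture
def bimodal_prior():
    return MoGPrior([0.5, 0.5], [-2.0, 2.0], [1.0, 1.0])


@pytest.fixture
def worked_observer(sg_prior):
    """x1 = x2 = 3 with noise variances (0.75, 0.5): the worked 2AFC example."""
    return TwoAFCObserver(sg_prior, np.sqrt(0.75), np.sqrt(0.5))


def random_prior(rng, max_components=4):
    """A random valid mixture prior for property tests."""
    c = int(rng.integers(1, max_components + 1))
    w = rng.uniform(0.1, 1.0, size=c)
    w = w / w.sum()
    means = rng.uniform(-3.0, 3.0, size=c)
    sds = rng.uniform(0.3, 3.0, size=c)
    return MoGPrior(w, means, sds)
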