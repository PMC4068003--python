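import numpy as np
import pytest

from melange import make_poisson_raster


@pytest.fixture(scope="session")
def poisson_raster():
    """50 independent Poisson units at 5 Hz for 400 s (R = 250 Hz)."""
    return make_poisson_raster(n_units=50, rate_hz=5.0, duration_ms=400_000.0,
                               seed=20240)


def poisson_sigma_star(lam: float) -> float:
    """Closed form sigma* for independent Poisson bins of mean lam.

    Successive bins are independent, so E[n_i / n_{i-1} | n_{i-1} > 0]
    = lam * E[1/n | n > 0]; the expectation is summed to convergence.
    """
    n = np.arange(1, 400)
    logp = n * np.log(lam) - lam - np.cumsum(np.log(n))
    return lam * float(np.sum(np.exp(logp) / n)) / (1.0 - np.exp(-lam))


def poisson_mean_size(lam: float) -> float:
    """Closed form <s>: R*bs spikes per bin over avalanche starts per bin."""
    return lam / (np.exp(-lam) * (1.0 - np.exp(-lam)))
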