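import numpy as np
import pytest
from hypothesis import settings

import reverbkit as rk

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


def ess_se_of_mean(counts: np.ndarray, m: float) -> float:
    """Standard error of the sample mean of an AR(1)-correlated series.

    Uses the effective sample size n*(1-m)/(1+m) implied by the m**k
    autocorrelation of the driven branching process.
    """
    n = counts.size
    ess = n * (1 - m) / (1 + m) if m < 1 else n
    return float(counts.std(ddof=1) / np.sqrt(max(ess, 2)))


@pytest.fixture(scope="session")
def trace_m09():
    """Stationary m=0.9 trace, 1e5 bins, h=1 (mean 10 spikes/bin)."""
    return rk.simulate_branching(rk.ProcessParams(m=0.9, h=1.0, n_bins=100_000, seed=11))


@pytest.fixture(scope="session")
def trace_m098():
    """Stationary reverberating-regime trace: m=0.98, h=2, 1e5 bins."""
    return rk.simulate_branching(rk.ProcessParams(m=0.98, h=2.0, n_bins=100_000, seed=12))


@pytest.fixture(scope="session")
def trace_m098_thinned(trace_m098):
    """The m=0.98 trace observed through 5% binomial thinning."""
    return rk.subsample(trace_m098, rk.SubsampleSpec(mode="binomial_thinning",
                                                     fraction=0.05, seed=13))


@pytest.fixture(scope="session")
def iid_trace():
    """m=0: pure Poisson input, no recurrence."""
    return rk.simulate_branching(rk.ProcessParams(m=0.0, h=10.0, n_bins=50_000, seed=14))
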