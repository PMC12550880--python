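import numpy as np
import pandas as pd
import pytest

from thermotrait import synthetic_data as sd
from thermotrait import tpc_traits as tp
from thermotrait._mcmc import SamplerConfig

EXPERIMENT_TEMPS = np.array(sd.DEFAULT_TEMPERATURES)


@pytest.fixture(scope="session")
def reduced_sampler() -> SamplerConfig:
    """Fast chain settings (4 x 2000) for fit tests."""
    return SamplerConfig().reduced()


def make_monod_rates(mu_max, Ks, m, noise_sd, seed,
                     levels=sd.RESOURCE_LEVELS["nitrogen"], reps=4):
    """Replicated growth-rate table from a known Monod surface."""
    rng = np.random.default_rng(seed)
    R = np.repeat(levels, reps)
    mu = mu_max * R / (Ks + R) - m + rng.normal(0, noise_sd, len(R))
    return pd.DataFrame({"resource_level": R, "mu": mu})


def make_tpc_rates(b1, b2, d0, d2, topt, noise_sd, seed,
                   temps=EXPERIMENT_TEMPS, reps=4):
    """Replicated growth-rate table from a known thermal performance curve."""
    rng = np.random.default_rng(seed)
    T = np.repeat(temps, reps)
    mu = tp.tpc_mu(T, b1, b2, d0, d2, topt) + rng.normal(0, noise_sd, len(T))
    return pd.DataFrame({"temperature": T, "mu": mu})
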