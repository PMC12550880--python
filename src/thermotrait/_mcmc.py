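"""Shared posterior-sampling machinery for the Monod and TPC fits.

An affine-invariant ensemble sampler (emcee) is run with its walkers
partitioned into a fixed number of chain groups; the first half of every
chain is discarded as burn-in, the retained draws are pooled (optionally
thinned to a target count) and a split-R̂ convergence diagnostic is computed
over the chain groups.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, replace

import emcee
import numpy as np

__all__ = ["SamplerConfig", "PosteriorSample", "sample_posterior", "derive_seed"]


@dataclass(frozen=True)
class SamplerConfig:
    """Chain/draw contract for one posterior fit.

    Defaults follow the study protocol: 4 chains of 10,000 iterations with
    the first half discarded and 20,000 pooled post-burn draws. Tests and
    the acceptance checks use ``reduced()`` (4 x 2,000).
    """

    chains: int = 4
    iterations: int = 10_000
    target_draws: int = 20_000
    rhat_threshold: float = 1.05

    def reduced(self) -> "SamplerConfig":
        return replace(self, iterations=2_000, target_draws=4_000)


@dataclass(frozen=True)
class PosteriorSample:
    """Pooled posterior draws with convergence metadata."""

    draws: np.ndarray  # (n_draws, ndim)
    rhat: np.ndarray  # per-parameter split-R̂ over chain groups
    converged: bool
    n_chains: int
    acceptance_fraction: float


def derive_seed(master_seed: int, *unit: object) -> int:
    """Stable per-fit seed below 2**31 from a master seed and identifiers."""
    tag = "|".join(str(u) for u in unit)
    return int((int(master_seed) ^ zlib.crc32(tag.encode())) % (2**31 - 1))


def _split_rhat(chains: np.ndarray) -> np.ndarray:
    """Gelman–Rubin split-R̂ per parameter; ``chains`` is (m, n, ndim)."""
    m, n, ndim = chains.shape
    half = n // 2
    split = np.concatenate([chains[:, :half], chains[:, half : 2 * half]], axis=0)
    mm, nn, _ = split.shape
    mean_c = split.mean(axis=1)  # (mm, ndim)
    var_c = split.var(axis=1, ddof=1)  # (mm, ndim)
    W = var_c.mean(axis=0)
    B = nn * mean_c.var(axis=0, ddof=1)
    var_plus = (nn - 1) / nn * W + B / nn
    with np.errstate(divide="ignore", invalid="ignore"):
        rhat = np.sqrt(var_plus / W)
    return np.where(W > 0, rhat, 1.0)


def sample_posterior(
    log_prob,
    init_center: np.ndarray,
    init_scale: np.ndarray,
    seed: int,
    config: SamplerConfig = SamplerConfig(),
) -> PosteriorSample:
    """Sample a posterior with the ensemble sampler.

    ``log_prob`` must return -inf outside the support; walkers are
    initialised by jittering ``init_center`` until every starting point has
    finite posterior density.
    """
    ndim = len(init_center)
    walkers_per_chain = max(3, int(np.ceil(2 * ndim / config.chains)))
    nwalkers = config.chains * walkers_per_chain
    rng = np.random.default_rng(seed)

    p0 = np.empty((nwalkers, ndim))
    for i in range(nwalkers):
        for _ in range(1000):
            cand = init_center + init_scale * rng.standard_normal(ndim)
            if np.isfinite(log_prob(cand)):
                p0[i] = cand
                break
        else:
            raise RuntimeError("could not initialise walkers in the support")

    moves = [(emcee.moves.DEMove(), 0.8), (emcee.moves.DESnookerMove(), 0.2)]
    sampler = emcee.EnsembleSampler(nwalkers, ndim, log_prob, moves=moves)
    sampler.random_state = np.random.RandomState(
        int(rng.integers(2**31 - 1))
    ).get_state()
    sampler.run_mcmc(p0, config.iterations, progress=False)

    chain = sampler.get_chain()  # (iterations, nwalkers, ndim)
    burn = config.iterations // 2
    post = chain[burn:]  # (n, nwalkers, ndim)
    # walkers grouped into chains for the split diagnostic
    grouped = post.transpose(1, 0, 2).reshape(
        config.chains, walkers_per_chain, -1, ndim
    )
    per_chain = grouped.reshape(config.chains, -1, ndim)
    rhat = _split_rhat(per_chain)

    pooled = post.reshape(-1, ndim)
    if config.target_draws and len(pooled) > config.target_draws:
        idx = np.linspace(0, len(pooled) - 1, config.target_draws).astype(int)
        pooled = pooled[idx]
    return PosteriorSample(
        draws=pooled,
        rhat=rhat,
        converged=bool(np.all(rhat < config.rhat_threshold)),
        n_chains=config.chains,
        acceptance_fraction=float(np.mean(sampler.acceptance_fraction)),
    )


def truncnorm_logpdf(x: np.ndarray, mean: np.ndarray, sd: np.ndarray) -> float:
    """Unnormalised log-density of independent normals truncated at 0.

    The truncation constant does not depend on the parameters being
    sampled, so it is dropped. Support checks live in the caller.
    """
    z = (np.asarray(x) - np.asarray(mean)) / np.asarray(sd)
    return float(-0.5 * np.sum(z * z))
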