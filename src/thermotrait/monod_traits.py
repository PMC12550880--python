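"""Bayesian Monod fits and derived resource-competition traits.

For each population x temperature x resource type, growth rate as a
function of resource availability is modelled as

    mu(R) = mu_max * R / (Ks + R) - m

with mu_max the gross maximum specific growth rate (d^-1), Ks the
half-saturation constant (resource units) and m the intrinsic loss rate
(d^-1). Posteriors are sampled with truncated-normal priors (all parameters
bounded below at 0) and a Gaussian likelihood whose residual sd carries a
half-normal prior. Derived per-draw traits:

* affinity alpha = mu_max / Ks — the initial slope of the Monod curve;
* R* = m_tot * Ks / (mu_max - m_tot) with m_tot = m + m_ext — the resource
  level at which net growth balances total losses (equilibrium competitive
  ability, lower wins);
* net-mu_max = mu_max - m — the loss-corrected maximum growth rate.

m_ext is an externally imposed, system-specific loss rate (dilution or
sinking), fixed at 0.1 d^-1 by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._mcmc import SamplerConfig, sample_posterior, truncnorm_logpdf

__all__ = [
    "M_EXT_DEFAULT",
    "MonodPriorSet",
    "MonodFit",
    "monod_mu",
    "fit_monod",
    "affinity",
    "r_star",
    "net_mu_max",
    "monod_retention",
    "default_priors",
]

M_EXT_DEFAULT: float = 0.1

#: Resource-specific prior (mean, sd) pairs for Ks; mu_max and m priors are
#: shared across resources.
KS_PRIORS: dict[str, tuple[float, float]] = {
    "light": (2.5, 0.7),
    "nitrogen": (2.5, 0.9),
    "phosphorus": (0.001, 0.8),
}
MU_MAX_PRIOR: tuple[float, float] = (1.0, 0.9)
M_PRIOR: tuple[float, float] = (0.0, 0.7)


@dataclass(frozen=True)
class MonodPriorSet:
    """Truncated-normal prior (mean, sd) for each Monod parameter."""

    mu_max: tuple[float, float] = MU_MAX_PRIOR
    Ks: tuple[float, float] = KS_PRIORS["nitrogen"]
    m: tuple[float, float] = M_PRIOR
    sigma_sd: float = 1.0  # half-normal prior sd on the residual sd

    def __post_init__(self) -> None:
        for name in ("mu_max", "Ks", "m"):
            if getattr(self, name)[1] <= 0:
                raise ValueError(f"{name} prior sd must be positive")


def default_priors(resource_type: str) -> MonodPriorSet:
    """Study-protocol priors; Ks is resource-specific."""
    if resource_type not in KS_PRIORS:
        raise ValueError(f"unknown resource_type {resource_type!r}")
    return MonodPriorSet(Ks=KS_PRIORS[resource_type])


@dataclass
class MonodFit:
    """Posterior summary of one Monod fit with derived trait draws."""

    draws: pd.DataFrame  # columns mu_max, Ks, m, sigma, alpha, r_star, net_mu_max
    medians: dict[str, float]
    ci_lower: dict[str, float]
    ci_upper: dict[str, float]
    m_ext: float
    retained: bool
    rhat: dict[str, float]
    converged: bool
    meta: dict = field(default_factory=dict)


def monod_mu(R, mu_max, Ks, m):
    """Monod growth rate ``mu_max * R/(Ks + R) - m``; vectorised."""
    R = np.asarray(R, dtype=float)
    Ks = np.asarray(Ks, dtype=float)
    if np.any(Ks <= 0):
        raise ValueError("Ks must be positive")
    if np.any(R < 0):
        raise ValueError("R must be non-negative")
    out = np.asarray(mu_max) * R / (Ks + R) - np.asarray(m)
    return float(out) if out.ndim == 0 else out


def affinity(mu_max, Ks):
    """Initial slope of the Monod curve, alpha = mu_max / Ks."""
    Ks = np.asarray(Ks, dtype=float)
    if np.any(Ks <= 0):
        raise ValueError("Ks must be positive")
    out = np.asarray(mu_max) / Ks
    return float(out) if out.ndim == 0 else out


def r_star(mu_max, Ks, m, m_ext: float = M_EXT_DEFAULT):
    """Minimum resource requirement R* = m_tot*Ks/(mu_max - m_tot).

    When total losses m_tot = m + m_ext meet or exceed mu_max, no resource
    level allows net positive growth and the sentinel +inf is returned.
    """
    mu_max = np.asarray(mu_max, dtype=float)
    Ks = np.asarray(Ks, dtype=float)
    m = np.asarray(m, dtype=float)
    if np.any(Ks <= 0):
        raise ValueError("Ks must be positive")
    m_tot = m + m_ext
    if np.any(m_tot < 0):
        raise ValueError("total loss m + m_ext must be non-negative")
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(mu_max > m_tot, m_tot * Ks / (mu_max - m_tot), np.inf)
    return float(out) if out.ndim == 0 else out


def net_mu_max(mu_max, m):
    """Loss-corrected maximum growth rate, mu_max - m."""
    out = np.asarray(mu_max, dtype=float) - np.asarray(m, dtype=float)
    return float(out) if out.ndim == 0 else out


def monod_retention(rates: pd.DataFrame, m_ext: float = M_EXT_DEFAULT) -> bool:
    """Retention rule: at least 3 resource levels whose mean observed mu
    exceeds m_ext."""
    means = rates.groupby("resource_level")["mu"].mean()
    return int((means > m_ext).sum()) >= 3


def _summaries(draws: pd.DataFrame):
    finite = draws.replace([np.inf, -np.inf], np.nan)
    med = finite.median().to_dict()
    lo = finite.quantile(0.025).to_dict()
    hi = finite.quantile(0.975).to_dict()
    return med, lo, hi


def fit_monod(
    rates: pd.DataFrame,
    priors: MonodPriorSet | None = None,
    config: SamplerConfig = SamplerConfig(),
    m_ext: float = M_EXT_DEFAULT,
    seed: int = 0,
) -> MonodFit:
    """Sample the Monod posterior for one population x temperature.

    ``rates`` needs columns ``resource_level`` and ``mu``; replicates enter
    as independent observations. Requires data at >= 3 distinct levels.
    """
    priors = priors or MonodPriorSet()
    rates = rates.dropna(subset=["mu"])
    levels = rates["resource_level"].to_numpy(float)
    mu_obs = rates["mu"].to_numpy(float)
    if len(np.unique(levels)) < 3:
        raise ValueError("need data at >= 3 distinct resource levels")

    means = np.array([priors.mu_max[0], priors.Ks[0], priors.m[0]])
    sds = np.array([priors.mu_max[1], priors.Ks[1], priors.m[1]])
    n = len(mu_obs)

    def log_prob(theta: np.ndarray) -> float:
        mu_max_, Ks_, m_, sigma = theta
        if mu_max_ < 0 or Ks_ <= 0 or m_ < 0 or sigma <= 0:
            return -np.inf
        lp = truncnorm_logpdf(theta[:3], means, sds)
        lp += -0.5 * (sigma / priors.sigma_sd) ** 2  # half-normal on sigma
        pred = mu_max_ * levels / (Ks_ + levels) - m_
        resid = mu_obs - pred
        lp += -0.5 * np.sum(resid * resid) / sigma**2 - n * np.log(sigma)
        return float(lp)

    center = np.array(
        [max(means[0], 0.5), max(means[1], 0.05), max(means[2], 0.05), 0.1]
    )
    scale = np.array([0.2, 0.2 * center[1] + 0.02, 0.05, 0.03])
    post = sample_posterior(log_prob, center, scale, seed=seed, config=config)

    draws = pd.DataFrame(post.draws, columns=["mu_max", "Ks", "m", "sigma"])
    draws["alpha"] = affinity(draws["mu_max"].to_numpy(), draws["Ks"].to_numpy())
    draws["r_star"] = r_star(
        draws["mu_max"].to_numpy(), draws["Ks"].to_numpy(), draws["m"].to_numpy(), m_ext
    )
    draws["net_mu_max"] = net_mu_max(draws["mu_max"].to_numpy(), draws["m"].to_numpy())
    med, lo, hi = _summaries(draws)
    return MonodFit(
        draws=draws,
        medians=med,
        ci_lower=lo,
        ci_upper=hi,
        m_ext=m_ext,
        retained=monod_retention(rates, m_ext),
        rhat=dict(zip(["mu_max", "Ks", "m", "sigma"], post.rhat)),
        converged=post.converged,
    )
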