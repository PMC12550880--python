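"""Double-exponential thermal performance curves and derived thermal traits.

Growth rate as a function of temperature is modelled as birth minus death,

    mu(T) = b1 * exp(b2*T) * g - [d0 + (b1*b2/d2) * exp((b2-d2)*Topt) * exp(d2*T)]

where b1 is the birth rate at 0 °C, b2 the exponential increase of birth
with temperature, d0 a temperature-independent loss, d2 the exponential
increase of death with temperature, and g in (0, 1] a resource-limitation
factor on birth (fixed to 1 within a resource level — level-specific
limitation is absorbed into b1). The death coefficient is written so that
for g = 1 the curve's interior maximum sits exactly at Topt, which makes
Topt a directly sampled, identifiable parameter.

Sampling uses the reparameterisation (w, b2, d0, d2, Topt) with
w = b1 * exp(b2*Topt), the birth rate at the optimum, which decorrelates
the birth amplitude from Topt.

Derived traits per posterior draw, by bracketed root-finding on mu(T):

* Tmax / Tmin — upper/lower zero crossings of the curve;
* Tbr — thermal breadth, the width of {T : mu(T) >= 0.8 * mu(Topt)}.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from ._mcmc import SamplerConfig, sample_posterior, truncnorm_logpdf
from .monod_traits import M_EXT_DEFAULT

__all__ = [
    "TPCPriorSet",
    "TPCFit",
    "tpc_mu",
    "fit_tpc",
    "derive_tmax_tmin",
    "derive_tbr",
    "apply_tpc_exclusions",
    "EXCLUSION_BOUNDS",
]

#: Inclusive retention bounds for posterior-median thermal traits:
#: Topt within the measured 15–35 °C; Tmax at most 5 °C above the highest
#: measured temperature; Tmin at most 15 °C below the lowest; Tbr at most
#: the 20 °C measured range. Medians strictly beyond a bound are flagged.
EXCLUSION_BOUNDS: dict[str, tuple[float, float]] = {
    "Topt": (15.0, 35.0),
    "Tmax": (-np.inf, 40.0),
    "Tmin": (0.0, np.inf),
    "Tbr": (-np.inf, 20.0),
}


@dataclass(frozen=True)
class TPCPriorSet:
    """Weakly informative truncated-normal priors (mean, sd) on the
    reparameterised curve; all bounded below at 0, Topt bounded to [0, 50]."""

    w: tuple[float, float] = (1.0, 1.0)
    b2: tuple[float, float] = (0.1, 0.1)
    d0: tuple[float, float] = (0.1, 0.5)
    d2: tuple[float, float] = (0.3, 0.3)
    Topt: tuple[float, float] = (27.0, 8.0)
    sigma_sd: float = 1.0


@dataclass
class TPCFit:
    """Posterior summary of one thermal-performance-curve fit."""

    draws: pd.DataFrame  # b1, b2, d0, d2, Topt, sigma, Tmax, Tmin, Tbr
    medians: dict[str, float]
    ci_lower: dict[str, float]
    ci_upper: dict[str, float]
    retained: bool
    excluded: dict[str, bool]
    rhat: dict[str, float]
    converged: bool
    meta: dict = field(default_factory=dict)


def tpc_mu(T, b1, b2, d0, d2, Topt, g: float = 1.0):
    """Evaluate the double-exponential thermal performance curve."""
    if np.any(np.asarray(d2) <= 0):
        raise ValueError("d2 must be positive")
    if not (0 < g <= 1):
        raise ValueError("g must lie in (0, 1]")
    T = np.asarray(T, dtype=float)
    birth = b1 * np.exp(b2 * T) * g
    death = d0 + (b1 * b2 / d2) * np.exp((b2 - d2) * Topt) * np.exp(d2 * T)
    out = birth - death
    return float(out) if out.ndim == 0 else out


def _root(f, lo: float, hi: float, n_scan: int = 64) -> float:
    """First sign change of ``f`` scanning from ``lo`` to ``hi``; nan if none."""
    ts = np.linspace(lo, hi, n_scan)
    vals = f(ts)
    sign = np.sign(vals)
    for i in range(len(ts) - 1):
        if sign[i] == 0:
            return float(ts[i])
        if sign[i] * sign[i + 1] < 0:
            return float(brentq(f, ts[i], ts[i + 1], xtol=1e-9))
    return float("nan")


def derive_tmax_tmin(draw) -> tuple[float, float]:
    """Zero crossings of the curve above and below Topt.

    ``draw`` is a mapping with keys b1, b2, d0, d2, Topt. Tmax is the root
    bracketed in (Topt, Topt + 100]; Tmin in [Topt - 150, Topt). A missing
    sign change yields nan for that side; mu(Topt) <= 0 yields (nan, nan).
    """
    b1, b2, d0, d2, topt = (draw[k] for k in ("b1", "b2", "d0", "d2", "Topt"))
    f = lambda T: tpc_mu(T, b1, b2, d0, d2, topt)
    if f(topt) <= 0:
        return float("nan"), float("nan")
    tmax = _root(f, topt, topt + 100.0, n_scan=256)
    tmin = _root(f, topt, topt - 150.0, n_scan=256)  # scan downward
    return tmax, tmin


def derive_tbr(draw) -> float:
    """Thermal breadth: width of the interval where mu >= 80% of mu(Topt)."""
    b1, b2, d0, d2, topt = (draw[k] for k in ("b1", "b2", "d0", "d2", "Topt"))
    mu_opt = tpc_mu(topt, b1, b2, d0, d2, topt)
    if mu_opt <= 0:
        return float("nan")
    level = 0.8 * mu_opt
    f = lambda T: tpc_mu(T, b1, b2, d0, d2, topt) - level
    t_hi = _root(f, topt, topt + 200.0, n_scan=512)
    t_lo = _root(f, topt, topt - 300.0, n_scan=512)
    if np.isnan(t_hi) or np.isnan(t_lo):
        return float("nan")
    return float(t_hi - t_lo)


def fit_tpc(
    rates: pd.DataFrame,
    priors: TPCPriorSet | None = None,
    config: SamplerConfig = SamplerConfig(),
    m_ext: float = M_EXT_DEFAULT,
    seed: int = 0,
) -> TPCFit:
    """Sample the thermal-performance-curve posterior for one population x
    resource level.

    ``rates`` needs columns ``temperature`` and ``mu``. The fit requires
    mean observed mu above m_ext at >= 3 temperatures (growth must be
    demonstrable over enough of the gradient to anchor the curve);
    otherwise a ValueError is raised so batch callers can log the skip.
    """
    priors = priors or TPCPriorSet()
    rates = rates.dropna(subset=["mu"])
    temps = rates["temperature"].to_numpy(float)
    mu_obs = rates["mu"].to_numpy(float)
    qualifying = (rates.groupby("temperature")["mu"].mean() > m_ext).sum()
    if qualifying < 3:
        raise ValueError(
            f"only {int(qualifying)} temperatures with mean mu above m_ext; need 3"
        )

    means = np.array([priors.w[0], priors.b2[0], priors.d0[0], priors.d2[0],
                      priors.Topt[0]])
    sds = np.array([priors.w[1], priors.b2[1], priors.d0[1], priors.d2[1],
                    priors.Topt[1]])
    n = len(mu_obs)

    def log_prob(theta: np.ndarray) -> float:
        w, b2, d0, d2, topt, sigma = theta
        if (w < 0 or b2 < 0 or d0 < 0 or d2 <= 0 or sigma <= 0
                or not (0.0 <= topt <= 50.0) or b2 >= d2):
            return -np.inf
        lp = truncnorm_logpdf(theta[:5], means, sds)
        lp += -0.5 * (sigma / priors.sigma_sd) ** 2
        b1 = w * np.exp(-b2 * topt)
        pred = tpc_mu(temps, b1, b2, d0, d2, topt)
        resid = mu_obs - pred
        lp += -0.5 * np.sum(resid * resid) / sigma**2 - n * np.log(sigma)
        return float(lp)

    mu_peak = max(float(np.max(mu_obs)), 0.3)
    t_peak = float(temps[np.argmax(mu_obs)])
    center = np.array([mu_peak + 0.2, 0.08, 0.1, 0.25, t_peak, 0.1])
    scale = np.array([0.2, 0.02, 0.05, 0.05, 2.0, 0.03])
    post = sample_posterior(log_prob, center, scale, seed=seed, config=config)

    draws = pd.DataFrame(
        post.draws, columns=["w", "b2", "d0", "d2", "Topt", "sigma"]
    )
    draws["b1"] = draws["w"] * np.exp(-draws["b2"] * draws["Topt"])
    tmax = np.empty(len(draws))
    tmin = np.empty(len(draws))
    tbr = np.empty(len(draws))
    for i, row in enumerate(draws.itertuples(index=False)):
        d = {"b1": row.b1, "b2": row.b2, "d0": row.d0, "d2": row.d2,
             "Topt": row.Topt}
        tmax[i], tmin[i] = derive_tmax_tmin(d)
        tbr[i] = derive_tbr(d)
    draws["Tmax"], draws["Tmin"], draws["Tbr"] = tmax, tmin, tbr

    # draws with missing roots drop out of that trait's summary only
    med = draws.median(skipna=True).to_dict()
    lo = draws.quantile(0.025).to_dict()
    hi = draws.quantile(0.975).to_dict()
    fit = TPCFit(
        draws=draws,
        medians=med,
        ci_lower=lo,
        ci_upper=hi,
        retained=True,
        excluded={},
        rhat=dict(zip(["w", "b2", "d0", "d2", "Topt", "sigma"], post.rhat)),
        converged=post.converged,
    )
    fit.excluded = _exclusion_flags(fit.medians)
    return fit


def _exclusion_flags(medians: dict[str, float]) -> dict[str, bool]:
    flags = {}
    for trait, (lo, hi) in EXCLUSION_BOUNDS.items():
        v = medians.get(trait, float("nan"))
        flags[trait] = bool(np.isnan(v) or v < lo or v > hi)
    return flags


def apply_tpc_exclusions(fits) -> None:
    """Flag posterior-median traits outside the retention bounds.

    Bounds are inclusive for retention (a median exactly on the bound is
    kept; only values strictly beyond are excluded). Fits are flagged in
    place, never deleted.
    """
    for fit in fits:
        fit.excluded = _exclusion_flags(fit.medians)
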