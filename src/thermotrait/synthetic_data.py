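"""Synthetic experimental design and growth simulation.

Emulates a batch-culture growth-rate study in which 19 freshwater
phytoplankton populations are grown along three separate resource gradients
(light, nitrogen, phosphorus; 8 levels each) crossed with six temperatures
(15–35 °C) in 4 replicates, for 48 unique treatments per resource and 3648
time series per resource experiment (10,944 wells over the three resources).

Ground truth is a double-exponential thermal performance curve (birth rate
rising exponentially with temperature, death rate rising faster) whose birth
term is scaled by a Monod resource-limitation factor ``g(R) = R/(Ks + R)``.
This makes the simulated growth surface self-consistent with both downstream
fitted models: at fixed temperature the surface is exactly Monod in ``R``,
and at saturating resource it is exactly the replete thermal performance
curve.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RESOURCE_LEVELS",
    "REPLETE_CONDITIONS",
    "DEFAULT_TEMPERATURES",
    "DEFAULT_SCHEDULE_DAYS",
    "RFU_FLOOR",
    "DesignGrid",
    "TruePopulationTraits",
    "GrowthTimeSeries",
    "make_design",
    "true_growth_rate",
    "true_monod_params",
    "sample_true_traits",
    "simulate_rate_table",
    "simulate_timeseries",
    "write_truth_sidecar",
]

#: Resource levels of the limitation experiments. Light in
#: umol photons m^-2 s^-1 (PAR); nitrogen and phosphorus in umol L^-1.
RESOURCE_LEVELS: dict[str, tuple[float, ...]] = {
    "light": (1.0, 8.0, 18.0, 40.0, 70.0, 108.0, 164.0, 240.0),
    "nitrogen": (0.5, 1.0, 2.0, 5.0, 20.0, 80.0, 400.0, 800.0),
    "phosphorus": (0.01, 0.1, 0.5, 1.5, 5.0, 10.0, 35.0, 50.0),
}

#: Levels of each resource when it is *not* the manipulated one.
REPLETE_CONDITIONS: dict[str, float] = {
    "light": 110.0,
    "nitrogen": 800.0,
    "phosphorus": 50.0,
}

DEFAULT_TEMPERATURES: tuple[float, ...] = (15.0, 20.0, 24.0, 28.0, 32.0, 35.0)

#: Plate-reader schedule in days since inoculation: twice daily (readings
#: ~9 h apart) for the first five calendar days, then once per day to day 7.
DEFAULT_SCHEDULE_DAYS: tuple[float, ...] = tuple(
    float(t) for d in range(5) for t in (d, d + 9.0 / 24.0)
) + (5.0, 6.0, 7.0)

#: Detection floor applied to simulated RFU so logs are always defined.
RFU_FLOOR: float = 0.1

INOCULUM_RFU: float = 20.0

PHYLA = ("Chlorophyta", "Bacillariophyta", "Cyanobacteria")


@dataclass(frozen=True)
class DesignGrid:
    """One resource experiment's factorial design."""

    resource_type: str
    resource_levels: tuple[float, ...]
    temperatures_C: tuple[float, ...]
    populations: tuple[str, ...]
    phyla: tuple[str, ...]
    replicates: int = 4
    background: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        lv = np.asarray(self.resource_levels, dtype=float)
        if lv.ndim != 1 or len(lv) < 2 or np.any(lv <= 0) or np.any(np.diff(lv) <= 0):
            raise ValueError("resource levels must be positive and strictly increasing")
        tc = np.asarray(self.temperatures_C, dtype=float)
        if np.any(np.diff(tc) <= 0):
            raise ValueError("temperatures must be strictly increasing")
        if len(self.populations) != len(self.phyla):
            raise ValueError("populations and phyla must align")

    @property
    def n_treatments(self) -> int:
        """Unique temperature x level combinations (48 by default)."""
        return len(self.resource_levels) * len(self.temperatures_C)

    @property
    def n_wells(self) -> int:
        return self.n_treatments * len(self.populations) * self.replicates

    def rows(self) -> pd.DataFrame:
        """Enumerate the design as one row per well."""
        pop_idx = np.arange(len(self.populations))
        grid = np.array(
            np.meshgrid(
                pop_idx,
                self.temperatures_C,
                self.resource_levels,
                np.arange(1, self.replicates + 1),
                indexing="ij",
            )
        ).reshape(4, -1)
        pi = grid[0].astype(int)
        return pd.DataFrame(
            {
                "population": np.asarray(self.populations)[pi],
                "phylum": np.asarray(self.phyla)[pi],
                "resource_type": self.resource_type,
                "resource_level": grid[2],
                "temperature": grid[1],
                "replicate": grid[3].astype(int),
            }
        )


@dataclass(frozen=True)
class TruePopulationTraits:
    """Generative parameters for one population on one resource.

    ``b1`` is the birth rate at 0 °C (d^-1), ``b2`` the exponential increase
    of birth with temperature (°C^-1), ``d0`` a temperature-independent loss
    (d^-1) and ``d2`` the exponential increase of death with temperature
    (°C^-1); ``d2 > b2`` guarantees a hump-shaped thermal performance curve
    peaking at ``Topt_true``. ``Ks_true`` is the Monod half-saturation in
    resource units and ``m_true`` the intrinsic loss reported as ground
    truth for the Monod view of the surface (equal to ``d0`` by default).
    """

    b1: float
    b2: float
    d0: float
    d2: float
    Topt_true: float
    Ks_true: float
    m_true: float
    K_cap: float = 2000.0
    lag_days: float = 0.0

    def __post_init__(self) -> None:
        if self.b1 <= 0 or self.d2 <= 0:
            raise ValueError("b1 and d2 must be positive")
        if self.d2 <= self.b2:
            raise ValueError("d2 must exceed b2 (hump-shaped curve)")
        if self.Ks_true <= 0:
            raise ValueError("Ks_true must be positive")
        if self.K_cap <= INOCULUM_RFU:
            raise ValueError("carrying capacity must exceed the inoculum")


@dataclass(frozen=True)
class GrowthTimeSeries:
    """One replicate well's fluorescence trajectory with its metadata."""

    population: str
    phylum: str
    resource_type: str
    resource_level: float
    temperature_C: float
    replicate: int
    times: np.ndarray
    rfu: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.rfu, dtype=float)
        if t.shape != y.shape:
            raise ValueError("times and rfu must have the same length")
        if t[0] != 0 or np.any(np.diff(t) <= 0):
            raise ValueError("times must start at 0 and strictly increase")
        if np.any(y <= 0):
            raise ValueError("rfu must be positive")


def make_design(
    resource_type: str,
    n_populations: int = 19,
    overrides: Mapping[str, Sequence] | None = None,
) -> DesignGrid:
    """Build the default factorial design for one resource experiment.

    Parameters
    ----------
    resource_type
        One of ``light``, ``nitrogen``, ``phosphorus``.
    n_populations
        Number of populations to enumerate (default 19). Identifiers are
        ``pop01`` ... and phyla are assigned round-robin.
    overrides
        Optional replacements for ``resource_levels``, ``temperatures_C``,
        ``populations``, ``phyla`` or ``replicates``.
    """
    if resource_type not in RESOURCE_LEVELS:
        raise ValueError(
            f"unknown resource_type {resource_type!r}; "
            f"expected one of {sorted(RESOURCE_LEVELS)}"
        )
    if n_populations < 1:
        raise ValueError("need at least one population")
    overrides = dict(overrides or {})
    pops = tuple(overrides.pop("populations", ()) or
                 (f"pop{i + 1:02d}" for i in range(n_populations)))
    phyla = tuple(overrides.pop("phyla", ()) or
                  (PHYLA[i % len(PHYLA)] for i in range(len(pops))))
    background = {k: v for k, v in REPLETE_CONDITIONS.items() if k != resource_type}
    kwargs = dict(
        resource_type=resource_type,
        resource_levels=tuple(RESOURCE_LEVELS[resource_type]),
        temperatures_C=DEFAULT_TEMPERATURES,
        populations=pops,
        phyla=phyla,
        replicates=4,
        background=background,
    )
    for key, value in overrides.items():
        if key not in kwargs:
            raise ValueError(f"unknown design override {key!r}")
        kwargs[key] = tuple(value) if isinstance(value, (list, tuple)) else value
    return DesignGrid(**kwargs)


def true_growth_rate(
    traits: TruePopulationTraits,
    T: float | np.ndarray,
    R: float | np.ndarray,
) -> float | np.ndarray:
    """Ground-truth specific growth rate (d^-1) at temperature ``T`` and
    resource amount ``R``.

    Birth ``b1 * exp(b2*T) * g(R)`` with Monod limitation
    ``g(R) = R/(Ks + R)``, minus death
    ``d0 + (b1*b2/d2) * exp((b2 - d2)*Topt) * exp(d2*T)``.
    Negative rates are valid (death exceeding birth).
    """
    T = np.asarray(T, dtype=float)
    R = np.asarray(R, dtype=float)
    if np.any(R < 0):
        raise ValueError("resource amount must be non-negative")
    g = R / (traits.Ks_true + R)
    birth = traits.b1 * np.exp(traits.b2 * T) * g
    death = traits.d0 + (traits.b1 * traits.b2 / traits.d2) * np.exp(
        (traits.b2 - traits.d2) * traits.Topt_true
    ) * np.exp(traits.d2 * T)
    out = birth - death
    return float(out) if out.ndim == 0 else out


def true_monod_params(traits: TruePopulationTraits, T: float) -> tuple[float, float, float]:
    """The exact Monod-view parameters (mu_max, Ks, m) of the surface at
    fixed temperature ``T`` — useful as a recovery target for fitted values."""
    mu_max = traits.b1 * np.exp(traits.b2 * T)
    m = traits.d0 + (traits.b1 * traits.b2 / traits.d2) * np.exp(
        (traits.b2 - traits.d2) * traits.Topt_true
    ) * np.exp(traits.d2 * T)
    return float(mu_max), traits.Ks_true, float(m)


def sample_true_traits(
    populations: Sequence[str],
    resource_type: str,
    seed: int | np.random.Generator,
) -> dict[str, TruePopulationTraits]:
    """Draw ground-truth traits for a population pool on one resource.

    Ranges span the trait diversity a multi-lake phytoplankton pool shows:
    thermal optima 18–33 °C, replete growth at the optimum 0.5–2.2 d^-1,
    and half-saturation constants spanning roughly the order-of-magnitude
    range of each resource's experimental gradient.
    """
    rng = np.random.default_rng(seed)
    ks_range = {
        "light": (2.0, 40.0),
        "nitrogen": (0.2, 20.0),
        "phosphorus": (0.01, 2.0),
    }[resource_type]
    out: dict[str, TruePopulationTraits] = {}
    for pop in populations:
        topt = rng.uniform(18.0, 33.0)
        b2 = rng.uniform(0.05, 0.12)
        d2 = b2 + rng.uniform(0.08, 0.20)
        d0 = rng.uniform(0.05, 0.30)
        mu_opt = rng.uniform(0.5, 2.2)  # replete net rate at Topt
        # mu(Topt; g=1) = b1*exp(b2*Topt)*(1 - b2/d2) - d0  =>  solve for b1
        b1 = (mu_opt + d0) / (np.exp(b2 * topt) * (1.0 - b2 / d2))
        ks = float(np.exp(rng.uniform(np.log(ks_range[0]), np.log(ks_range[1]))))
        out[pop] = TruePopulationTraits(
            b1=float(b1),
            b2=float(b2),
            d0=float(d0),
            d2=float(d2),
            Topt_true=float(topt),
            Ks_true=ks,
            m_true=float(d0),
            K_cap=float(rng.uniform(800.0, 3000.0)),
            lag_days=float(rng.uniform(0.0, 0.5)),
        )
    return out


def simulate_rate_table(
    grid: DesignGrid,
    traits: Mapping[str, TruePopulationTraits],
    noise_sd: float = 0.05,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Per-well growth rates: the true surface plus additive Gaussian noise.

    Fast path that bypasses time-series simulation and growth-rate
    estimation; returns the long-format rate table with columns
    (population, phylum, resource_type, resource_level, temperature,
    replicate, mu, mu_true).
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    rows = grid.rows()
    mu_true = np.empty(len(rows))
    for pop, sub in rows.groupby("population", sort=False):
        tr = traits[pop]
        mu_true[sub.index] = true_growth_rate(
            tr, sub["temperature"].to_numpy(), sub["resource_level"].to_numpy()
        )
    rows["mu_true"] = mu_true
    rows["mu"] = mu_true + rng.normal(0.0, noise_sd, size=len(rows))
    return rows


def simulate_timeseries(
    grid: DesignGrid,
    traits: Mapping[str, TruePopulationTraits],
    noise_cv: float = 0.05,
    seed: int | np.random.Generator = 0,
    schedule_days: Sequence[float] = DEFAULT_SCHEDULE_DAYS,
) -> list[GrowthTimeSeries]:
    """Simulate fluorescence trajectories for every well of the design.

    Dynamics are piecewise: flat at the inoculum for ``lag_days``, then
    exponential growth at the true rate, capped at the carrying capacity
    ``K_cap`` (for positive rates). Multiplicative lognormal measurement
    noise with coefficient of variation ``noise_cv``; readings are floored
    at ``RFU_FLOOR`` so the log-transform is always defined.
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be non-negative")
    rng = np.random.default_rng(seed)
    t = np.asarray(schedule_days, dtype=float)
    sigma = np.sqrt(np.log1p(noise_cv**2))  # lognormal sd for the given CV
    out: list[GrowthTimeSeries] = []
    rows = grid.rows()
    for row in rows.itertuples(index=False):
        tr = traits[row.population]
        mu = true_growth_rate(tr, row.temperature, row.resource_level)
        te = np.clip(t - tr.lag_days, 0.0, None)  # effective growth time
        with np.errstate(over="ignore"):
            y = np.minimum(INOCULUM_RFU * np.exp(mu * te), tr.K_cap)
        if noise_cv > 0:
            y = y * rng.lognormal(-0.5 * sigma**2, sigma, size=len(t))
        y = np.maximum(y, RFU_FLOOR)
        out.append(
            GrowthTimeSeries(
                population=row.population,
                phylum=row.phylum,
                resource_type=row.resource_type,
                resource_level=row.resource_level,
                temperature_C=row.temperature,
                replicate=row.replicate,
                times=t.copy(),
                rfu=y,
            )
        )
    return out


def timeseries_to_frame(series: Sequence[GrowthTimeSeries]) -> pd.DataFrame:
    """Long-format table (population, phylum, resource_type, resource_level,
    temperature, replicate, day, rfu) for a collection of trajectories."""
    frames = []
    for s in series:
        frames.append(
            pd.DataFrame(
                {
                    "population": s.population,
                    "phylum": s.phylum,
                    "resource_type": s.resource_type,
                    "resource_level": s.resource_level,
                    "temperature": s.temperature_C,
                    "replicate": s.replicate,
                    "day": s.times,
                    "rfu": s.rfu,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def write_truth_sidecar(
    traits: Mapping[str, Mapping[str, TruePopulationTraits]] | Mapping[str, TruePopulationTraits],
    path: str | Path,
) -> None:
    """Write ground-truth traits to a JSON sidecar next to the data tables."""

    def encode(obj):
        if isinstance(obj, TruePopulationTraits):
            return asdict(obj)
        return {k: encode(v) for k, v in obj.items()}

    Path(path).write_text(json.dumps(encode(traits), indent=2, sort_keys=True))
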