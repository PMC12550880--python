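"""Double-exponential thermal performance curves and derived thermal traits."""

import numpy as np
import pandas as pd
import pytest

from thermotrait import tpc_traits as tp
from conftest import make_tpc_rates


def _random_draw(rng):
    """A curve with a positive interior optimum."""
    b2 = rng.uniform(0.04, 0.12)
    d2 = b2 + rng.uniform(0.08, 0.25)
    topt = rng.uniform(18.0, 33.0)
    d0 = rng.uniform(0.02, 0.3)
    mu_opt = rng.uniform(0.3, 2.0)
    b1 = (mu_opt + d0) / (np.exp(b2 * topt) * (1 - b2 / d2))
    return {"b1": b1, "b2": b2, "d0": d0, "d2": d2, "Topt": topt}


class TestCurve:
    def test_independent_hand_coding_agrees(self):
        b1, b2, d0, d2, topt, T = 0.2, 0.08, 0.1, 0.25, 28.0, 28.0
        direct = (b1 * np.exp(b2 * T)
                  - (d0 + (b1 * b2 / d2) * np.exp((b2 - d2) * topt)
                     * np.exp(d2 * T)))
        assert tp.tpc_mu(T, b1, b2, d0, d2, topt) == pytest.approx(
            direct, abs=1e-12)

    def test_derivative_zero_at_topt(self):
        rng = np.random.default_rng(17)
        h = 1e-4
        for _ in range(20):
            d = _random_draw(rng)
            up = tp.tpc_mu(d["Topt"] + h, **{k: d[k] for k in
                                             ("b1", "b2", "d0", "d2")},
                           Topt=d["Topt"])
            dn = tp.tpc_mu(d["Topt"] - h, **{k: d[k] for k in
                                             ("b1", "b2", "d0", "d2")},
                           Topt=d["Topt"])
            assert abs((up - dn) / (2 * h)) < 1e-6

    def test_death_dominates_at_high_temperature(self):
        assert tp.tpc_mu(500.0, 0.2, 0.08, 0.1, 0.25, 28.0) < -1e10

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            tp.tpc_mu(20.0, 0.2, 0.08, 0.1, 0.0, 28.0)  # d2 = 0
        with pytest.raises(ValueError):
            tp.tpc_mu(20.0, 0.2, 0.08, 0.1, 0.25, 28.0, g=0.0)


class TestDerivedRoots:
    def test_symmetric_construction_recovers_known_zeros(self):
        """Choose d0 so that the curve crosses zero exactly at 20 °C, then
        verify both roots straddle Topt and the found crossings are zeros."""
        b1, b2, d2, topt = 0.3, 0.08, 0.28, 28.0
        # solve mu(20) = 0 for d0
        d0 = (b1 * np.exp(b2 * 20.0)
              - (b1 * b2 / d2) * np.exp((b2 - d2) * topt) * np.exp(d2 * 20.0))
        draw = {"b1": b1, "b2": b2, "d0": d0, "d2": d2, "Topt": topt}
        tmax, tmin = tp.derive_tmax_tmin(draw)
        assert tmin == pytest.approx(20.0, abs=1e-6)
        assert tmax > topt
        assert tp.tpc_mu(tmax, b1, b2, d0, d2, topt) == pytest.approx(0, abs=1e-6)

    def test_roots_match_grid_scan_oracle(self):
        """Bisection-derived Tmax/Tmin/Tbr agree with a 0.001 °C grid scan
        across 200 seeded draws."""
        rng = np.random.default_rng(99)
        checked = 0
        for _ in range(200):
            d = _random_draw(rng)
            f = lambda T: tp.tpc_mu(T, d["b1"], d["b2"], d["d0"], d["d2"],
                                    d["Topt"])
            tmax, tmin = tp.derive_tmax_tmin(d)
            # grid spans the full root brackets on both sides of the optimum
            grid = np.arange(d["Topt"] - 160.0, d["Topt"] + 100.0, 0.001)
            mu = f(grid)
            pos = mu > 0
            if not pos.any():
                assert np.isnan(tmax) and np.isnan(tmin)
                continue
            crossings = np.nonzero(np.diff(pos.astype(int)))[0]
            if not np.isnan(tmax):
                up = grid[crossings[pos[crossings]]]  # + -> - crossings
                assert np.min(np.abs(up - tmax)) < 0.01
            if not np.isnan(tmin):
                down = grid[crossings[~pos[crossings]]]
                assert np.min(np.abs(down - tmin)) < 0.01
            tbr = tp.derive_tbr(d)
            mu_opt = f(d["Topt"])
            measure = 0.001 * np.sum(mu >= 0.8 * mu_opt)
            # compare only when the 80% interval is inside the scanned grid
            if not np.isnan(tbr) and not np.isnan(tmin):
                assert tbr == pytest.approx(measure, abs=0.01)
            checked += 1
        assert checked >= 150

    def test_breadth_inside_zero_crossings(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            d = _random_draw(rng)
            tmax, tmin = tp.derive_tmax_tmin(d)
            tbr = tp.derive_tbr(d)
            if np.isnan([tmax, tmin, tbr]).any():
                continue
            assert tmin < d["Topt"] < tmax
            assert tbr < tmax - tmin

    def test_everywhere_negative_curve_has_no_roots(self):
        draw = {"b1": 0.01, "b2": 0.05, "d0": 2.0, "d2": 0.3, "Topt": 25.0}
        tmax, tmin = tp.derive_tmax_tmin(draw)
        assert np.isnan(tmax) and np.isnan(tmin)
        assert np.isnan(tp.derive_tbr(draw))


class TestExclusions:
    @pytest.mark.parametrize("trait,value,excluded", [
        ("Topt", 14.9, True), ("Topt", 15.0, False), ("Topt", 35.0, False),
        ("Topt", 35.1, True),
        ("Tmax", 40.0, False), ("Tmax", 40.1, True),
        ("Tmin", 0.0, False), ("Tmin", -0.1, True),
        ("Tbr", 20.0, False), ("Tbr", 20.1, True),
    ])
    def test_boundary_conventions(self, trait, value, excluded):
        medians = {"Topt": 25.0, "Tmax": 35.0, "Tmin": 10.0, "Tbr": 10.0}
        medians[trait] = value
        flags = tp._exclusion_flags(medians)
        assert flags[trait] is excluded

    def test_fits_flagged_in_place_never_deleted(self):
        class Dummy:
            medians = {"Topt": 50.0, "Tmax": 55.0, "Tmin": 5.0, "Tbr": 3.0}
            excluded = {}
        fits = [Dummy()]
        tp.apply_tpc_exclusions(fits)
        assert len(fits) == 1
        assert fits[0].excluded["Topt"] and fits[0].excluded["Tmax"]
        assert not fits[0].excluded["Tbr"]


class TestFitTPC:
    def test_recovers_topt_from_replete_data(self, reduced_sampler):
        rates = make_tpc_rates(0.2, 0.08, 0.1, 0.25, 28.0, noise_sd=0.02,
                               seed=61)
        fit = tp.fit_tpc(rates, config=reduced_sampler, seed=62)
        assert abs(fit.medians["Topt"] - 28.0) < 1.0
        assert fit.converged or max(fit.rhat.values()) < 1.2

    def test_insufficient_qualifying_temperatures_skipped(self, reduced_sampler):
        rates = pd.DataFrame({
            "temperature": np.repeat([15.0, 20.0, 24.0, 28.0], 2),
            "mu": [0.02, 0.03, 0.5, 0.52, 0.05, 0.04, 0.06, 0.02],
        })
        with pytest.raises(ValueError, match="need 3"):
            tp.fit_tpc(rates, config=reduced_sampler, seed=1)

    def test_same_seed_identical_medians(self, reduced_sampler):
        rates = make_tpc_rates(0.2, 0.08, 0.1, 0.25, 26.0, 0.05, seed=71)
        a = tp.fit_tpc(rates, config=reduced_sampler, seed=72)
        b = tp.fit_tpc(rates, config=reduced_sampler, seed=72)
        assert a.medians == b.medians

    def test_ordered_thresholds_within_retained_draws(self, reduced_sampler):
        rates = make_tpc_rates(0.25, 0.09, 0.1, 0.3, 27.0, 0.03, seed=81)
        fit = tp.fit_tpc(rates, config=reduced_sampler, seed=82)
        d = fit.draws.dropna(subset=["Tmax", "Tmin", "Tbr"])
        assert (d["Tmin"] < d["Topt"]).all()
        assert (d["Topt"] < d["Tmax"]).all()
        assert (d["Tbr"] <= d["Tmax"] - d["Tmin"]).all()
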