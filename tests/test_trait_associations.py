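"""Cross-population summaries and association statistics."""

import numpy as np
import pandas as pd
import pytest
from itertools import combinations
from scipy.stats import t as t_dist

from thermotrait import trait_associations as ta

TEMPS = [15.0, 20.0, 24.0, 28.0, 32.0, 35.0]


def make_monod_table(rstar_by_pop, net_by_pop=None, resource="light"):
    rows = []
    for pop, rstars in rstar_by_pop.items():
        for T, rs in zip(TEMPS, rstars):
            rows.append({
                "population": pop, "resource_type": resource, "temperature": T,
                "phylum": "Chlorophyta", "r_star": rs,
                "net_mu_max": (net_by_pop or {}).get(pop, 1.0),
                "retained": True,
            })
    return pd.DataFrame(rows)


def make_tpc_table(pops, resource="light"):
    rows = []
    for i, pop in enumerate(pops):
        for lvl in (1.0, 10.0, 100.0):
            rows.append({
                "population": pop, "resource_type": resource,
                "resource_level": lvl, "Topt": 25.0 + i, "Tmax": 35.0 + i,
                "Tbr": 10.0 + i, "Topt_excluded": False,
                "Tmax_excluded": False, "Tbr_excluded": False,
            })
    return pd.DataFrame(rows)


class TestSummaries:
    def test_trstar_min_is_argmin_temperature(self):
        monod = make_monod_table({"a": [0.2, 0.1, 0.4, 0.3, 0.5, 0.9],
                                  "b": [1.0, 0.9, 0.8, 0.7, 0.9, 1.0],
                                  "c": [3, 2, 1, 2, 3, 4]})
        out = ta.summarize_traits(monod, make_tpc_table(["a", "b", "c"]))
        row = out.set_index("population")
        assert row.loc["a", "TRstar_min"] == 20.0
        assert row.loc["b", "TRstar_min"] == 28.0
        assert row.loc["c", "TRstar_min"] == 24.0

    def test_scaled_log_rstar_matches_hand_zscore(self):
        monod = make_monod_table({"a": [1.0] * 6, "b": [10.0] * 6,
                                  "c": [100.0] * 6})
        out = ta.summarize_traits(monod, make_tpc_table(["a", "b", "c"]))
        vals = out.set_index("population")["scaled_logRstar_min"]
        logs = np.log([1.0, 10.0, 100.0])
        expect = (logs - logs.mean()) / logs.std(ddof=1)
        assert np.allclose(vals[["a", "b", "c"]], expect)

    def test_single_population_scaled_value_missing(self):
        monod = make_monod_table({"a": [0.5] * 6})
        out = ta.summarize_traits(monod, make_tpc_table(["a"]))
        assert out["scaled_logRstar_min"].isna().all()

    def test_excluded_estimates_not_summarized(self):
        tpc = make_tpc_table(["a", "b", "c"])
        tpc.loc[(tpc["population"] == "a") & (tpc["resource_level"] == 100.0),
                ["Tmax", "Tmax_excluded"]] = [99.0, True]
        monod = make_monod_table({p: [0.5] * 6 for p in "abc"})
        out = ta.summarize_traits(monod, tpc).set_index("population")
        assert out.loc["a", "Tmax_max"] == 35.0  # flagged 99 ignored

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            ta.summarize_traits(pd.DataFrame(), pd.DataFrame())


class TestPCA:
    def test_variance_explained_matches_eigen_oracle(self):
        rng = np.random.default_rng(8)
        df = pd.DataFrame(rng.normal(size=(8, 6)), columns=ta.SUMMARY_TRAITS)
        res = ta.run_pca(df)
        Z = (df - df.mean()) / df.std(ddof=1)
        eigvals = np.linalg.eigvalsh(np.cov(Z.to_numpy().T))[::-1]
        assert np.allclose(res["variance_explained_pct"],
                           100 * eigvals / eigvals.sum(), atol=1e-8)
        assert res["variance_explained_pct"].sum() == pytest.approx(100.0)

    def test_scores_reproduce_scaled_data_with_all_components(self):
        rng = np.random.default_rng(9)
        df = pd.DataFrame(rng.normal(size=(10, 6)), columns=ta.SUMMARY_TRAITS)
        res = ta.run_pca(df)
        Z = ((df - df.mean()) / df.std(ddof=1)).to_numpy()
        recon = res["scores"].to_numpy() @ res["loadings"].to_numpy().T
        assert np.allclose(recon, Z, atol=1e-8)

    def test_perfectly_correlated_columns_load_together(self):
        rng = np.random.default_rng(10)
        x = rng.normal(size=12)
        df = pd.DataFrame({"scaled_logRstar_min": x, "TRstar_min": 2 * x + 1,
                           "net_mu_max_max": rng.normal(size=12),
                           "Topt_max": rng.normal(size=12),
                           "Tmax_max": rng.normal(size=12),
                           "Tbr_max": rng.normal(size=12)})
        res = ta.run_pca(df)
        # z-scored duplicates share their dominant-axis loading exactly
        l1 = res["loadings"].loc["scaled_logRstar_min", "PC1"]
        l2 = res["loadings"].loc["TRstar_min", "PC1"]
        assert l1 == pytest.approx(l2, abs=1e-8)

    def test_constant_column_rejected(self):
        df = pd.DataFrame({c: np.arange(5.0) for c in ta.SUMMARY_TRAITS})
        df["Tbr_max"] = 1.0
        with pytest.raises(ValueError, match="constant"):
            ta.run_pca(df)


class TestAnosim:
    def test_separated_clouds_give_high_r(self):
        rng = np.random.default_rng(21)
        X = np.vstack([rng.normal(0, 0.3, (8, 2)), rng.normal(8, 0.3, (8, 2))])
        labels = ["a"] * 8 + ["b"] * 8
        r, p = ta.anosim(X, labels, n_perm=499, seed=1)
        assert r > 0.9
        assert p < 0.01

    def test_random_labels_give_near_zero_r(self):
        rng = np.random.default_rng(22)
        rs = []
        for s in range(20):
            X = rng.normal(size=(12, 3))
            labels = ["a"] * 6 + ["b"] * 6
            r, _ = ta.anosim(X, labels, n_perm=99, seed=s)
            rs.append(r)
        assert abs(np.mean(rs)) < 0.1

    def test_identical_points_give_zero_r(self):
        X = np.ones((8, 2))
        r, _ = ta.anosim(X, ["a"] * 4 + ["b"] * 4, n_perm=99, seed=0)
        assert r == 0.0

    def test_rank_basis_invariant_to_monotone_distance_transform(self):
        """Squaring coordinates' distances (a monotone map on Euclidean
        distances via scaling) leaves R unchanged — R is rank-based."""
        rng = np.random.default_rng(23)
        X = rng.normal(size=(10, 2))
        labels = ["a"] * 5 + ["b"] * 5
        r1, _ = ta.anosim(X, labels, n_perm=9, seed=1)
        r2, _ = ta.anosim(X * 37.0, labels, n_perm=9, seed=1)
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_against_reference_implementation(self):
        from skbio.stats.distance import anosim as skbio_anosim, DistanceMatrix
        from scipy.spatial.distance import squareform, pdist
        rng = np.random.default_rng(24)
        X = np.vstack([rng.normal(0, 1, (6, 3)), rng.normal(1.5, 1, (7, 3))])
        labels = ["a"] * 6 + ["b"] * 7
        r, _ = ta.anosim(X, labels, n_perm=99, seed=2)
        dm = DistanceMatrix(squareform(pdist(X)))
        ref = skbio_anosim(dm, grouping=labels, permutations=99)
        assert r == pytest.approx(ref["test statistic"], abs=1e-10)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="2 groups"):
            ta.anosim(np.ones((4, 2)), ["a"] * 4)


class TestWelchGamesHowell:
    def test_identical_groups_not_significant(self):
        y = np.tile([1.0, 2.0, 3.0, 4.0], 3)
        g = np.repeat(["a", "b", "c"], 4)
        res = ta.welch_games_howell(y, g)
        assert res["welch_p"] > 0.9

    def test_two_groups_matches_closed_form_welch_t(self):
        rng = np.random.default_rng(31)
        a = rng.normal(0, 1, 10)
        b = rng.normal(10, 2, 12)
        res = ta.welch_games_howell(np.r_[a, b], ["a"] * 10 + ["b"] * 12)
        se2 = a.var(ddof=1) / 10 + b.var(ddof=1) / 12
        t = (a.mean() - b.mean()) / np.sqrt(se2)
        df = se2**2 / ((a.var(ddof=1) / 10) ** 2 / 9
                       + (b.var(ddof=1) / 12) ** 2 / 11)
        p = 2 * t_dist.sf(abs(t), df)
        assert res["welch_p"] == pytest.approx(p, rel=1e-6)
        assert res["welch_p"] < 1e-4

    def test_only_shifted_pairs_significant(self):
        rng = np.random.default_rng(32)
        y = np.r_[rng.normal(0, 1, 10), rng.normal(0, 1, 10),
                  rng.normal(8, 1, 10)]
        g = np.repeat(["a", "b", "c"], 10)
        res = ta.welch_games_howell(y, g)
        pw = res["pairwise"].set_index(["A", "B"])["pval"]
        assert pw.loc[("a", "c")] < 0.05 and pw.loc[("b", "c")] < 0.05
        assert pw.loc[("a", "b")] > 0.05

    def test_degenerate_group_size_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            ta.welch_games_howell([1.0, 2.0, 3.0], ["a", "a", "b"])


def brute_force_tau_b(x, y):
    """O(n^2) concordant/discordant pair count with tie correction."""
    nc = nd = tx = ty = 0
    for (xi, yi), (xj, yj) in combinations(zip(x, y), 2):
        if xi == xj and yi == yj:
            continue
        elif xi == xj:
            tx += 1
        elif yi == yj:
            ty += 1
        elif (xi - xj) * (yi - yj) > 0:
            nc += 1
        else:
            nd += 1
    return (nc - nd) / np.sqrt((nc + nd + tx) * (nc + nd + ty))


class TestKendall:
    def test_concordant_and_reversed(self):
        df = pd.DataFrame({"Topt_max": [1, 2, 3, 4], "Tmax_max": [2, 4, 6, 8],
                           "Tbr_max": [4, 3, 2, 1]})
        tau, _ = ta.kendall_matrix(df, columns=df.columns)
        assert tau.loc["Topt_max", "Tmax_max"] == pytest.approx(1.0)
        assert tau.loc["Topt_max", "Tbr_max"] == pytest.approx(-1.0)

    def test_tau_b_with_ties_matches_brute_force(self):
        rng = np.random.default_rng(41)
        for n in (5, 10, 25, 50):
            x = rng.integers(0, 6, n).astype(float)
            y = rng.integers(0, 6, n).astype(float)
            df = pd.DataFrame({"Topt_max": x, "Tmax_max": y,
                               "Tbr_max": rng.normal(size=n)})
            tau, _ = ta.kendall_matrix(df, columns=df.columns)
            assert tau.loc["Topt_max", "Tmax_max"] == pytest.approx(
                brute_force_tau_b(x, y), abs=1e-10)

    def test_constant_column_reported_missing(self):
        df = pd.DataFrame({"Topt_max": [1.0, 2, 3, 4], "Tmax_max": [5.0] * 4,
                           "Tbr_max": [1.0, 3, 2, 4]})
        tau, _ = ta.kendall_matrix(df, columns=df.columns)
        assert np.isnan(tau.loc["Topt_max", "Tmax_max"])
        assert not np.isnan(tau.loc["Topt_max", "Tbr_max"])


class TestInteraction:
    def test_common_slope_pools_exactly(self):
        x = np.tile(np.arange(10.0), 3)
        res_labels = np.repeat(["light", "nitrogen", "phosphorus"], 10)
        y = 2.0 * x + np.repeat([0.0, 1.0, 2.0], 10)
        res = ta.interaction_test(y, x, res_labels)
        assert res["interaction_p"] > 0.99
        assert res["pooled_slope"] == pytest.approx(2.0, abs=1e-8)

    def test_opposite_slopes_detected(self):
        rng = np.random.default_rng(51)
        x = np.tile(np.arange(10.0), 2)
        res_labels = np.repeat(["light", "nitrogen"], 10)
        y = np.r_[x[:10], -x[:10]] + rng.normal(0, 0.1, 20)
        res = ta.interaction_test(y, x, res_labels)
        assert res["interaction_p"] < 0.01
        assert "pooled_slope" not in res

    def test_single_resource_rejected(self):
        with pytest.raises(ValueError, match="2 resource"):
            ta.interaction_test([1.0, 2.0], [1.0, 2.0], ["light", "light"])


class TestNullTau:
    def test_shared_bounds_center_null_at_zero(self):
        tmax = np.full(20, 38.0)
        res = ta.null_tau_distribution(tmax + np.random.default_rng(0).normal(
            0, 1e-9, 20), 15.0, observed_tau=0.0, n_sims=1000, seed=3)
        assert abs(res["null_mean"]) < 0.05

    def test_heterogeneous_upper_bounds_bias_null_positive(self):
        rng = np.random.default_rng(61)
        tmax = rng.uniform(25.0, 40.0, 20)
        res = ta.null_tau_distribution(tmax, 15.0, observed_tau=0.5,
                                       n_sims=500, seed=4)
        assert res["null_mean"] > 0.0

    def test_observed_above_null_has_percentile_one(self):
        tmax = np.random.default_rng(62).uniform(25, 40, 15)
        res = ta.null_tau_distribution(tmax, 15.0, observed_tau=0.9999,
                                       n_sims=200, seed=5)
        assert res["percentile"] > 0.99

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError, match="lower bound"):
            ta.null_tau_distribution(np.array([20.0, 30.0]), 25.0, 0.0,
                                     n_sims=100, seed=0)

    def test_percentile_uniform_under_the_null(self):
        """When the observed tau itself comes from the null mechanism, its
        percentile is uniform (KS test over repeated seeded runs)."""
        from scipy.stats import kstest
        from scipy.stats import kendalltau
        rng = np.random.default_rng(63)
        tmax = rng.uniform(25.0, 40.0, 15)
        pctls = []
        for s in range(200):
            obs = kendalltau(rng.uniform(15.0, tmax), tmax)[0]
            res = ta.null_tau_distribution(tmax, 15.0, obs, n_sims=150,
                                           seed=1000 + s)
            pctls.append(res["percentile"])
        assert kstest(pctls, "uniform").pvalue > 0.01


class TestExclusionCounts:
    def test_counts_deterministic_and_boundary_consistent(self):
        est = pd.DataFrame({
            "Topt": [14.9, 15.0, 30.0, 35.1, np.nan],
            "Tmax": [39.0, 40.0, 40.1, 65.0, 41.0],
            "Tmin": [-0.1, 0.0, 5.0, -85.0, 2.0],
            "Tbr": [20.0, 20.1, 47.0, 2.0, 19.9],
        })
        out = ta.exclusion_counts(est)
        assert out["Topt_excluded"] == 2 and out["Topt_total"] == 4
        assert out["Tmax_excluded"] == 3
        assert out["Tmin_excluded"] == 2
        assert out["Tbr_excluded"] == 2
        assert out == ta.exclusion_counts(est)
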