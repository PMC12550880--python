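"""Cross-population trait summaries and association analyses.

Six summary traits per population x resource type condense the fitted
surfaces: the (log, z-scored within resource) lowest R* across temperatures
and the temperature at which it occurs, the largest net maximum growth
rate, and the largest Topt, Tmax and Tbr across resource levels. These feed
a PCA, rank-based group tests (ANOSIM), Welch ANOVA with Games-Howell post
hocs, a Kendall tau-b correlation matrix, per-pair resource-interaction
tests, and a constrained-resampling null for correlations that involve
Tmax_max (a trait bounded above by Tmax is apt to correlate with it even at
random, so the observed tau is compared against that sampling artifact).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pingouin as pg
from scipy.spatial.distance import pdist
from scipy.stats import kendalltau, rankdata
from sklearn.decomposition import PCA
import statsmodels.formula.api as smf

__all__ = [
    "SUMMARY_TRAITS",
    "summarize_traits",
    "run_pca",
    "anosim",
    "welch_games_howell",
    "kendall_matrix",
    "interaction_test",
    "null_tau_distribution",
    "exclusion_counts",
]

SUMMARY_TRAITS = (
    "scaled_logRstar_min",
    "TRstar_min",
    "net_mu_max_max",
    "Topt_max",
    "Tmax_max",
    "Tbr_max",
)


def summarize_traits(
    monod_table: pd.DataFrame,
    tpc_table: pd.DataFrame,
) -> pd.DataFrame:
    """Six summary traits per population x resource type.

    Parameters
    ----------
    monod_table
        One row per population x resource_type x temperature with posterior
        medians ``r_star`` and ``net_mu_max`` plus a boolean ``retained``.
    tpc_table
        One row per population x resource_type x resource_level with
        medians ``Topt``, ``Tmax``, ``Tbr`` and boolean exclusion flags
        ``Topt_excluded``, ``Tmax_excluded``, ``Tbr_excluded``.

    Minima/maxima are taken only over retained, non-excluded estimates;
    R*_min is natural-log transformed then z-scored across populations
    within each resource type.
    """
    if len(monod_table) == 0 or len(tpc_table) == 0:
        raise ValueError("empty input")
    mt = monod_table[monod_table.get("retained", True) == True]  # noqa: E712
    mt = mt[np.isfinite(mt["r_star"])]
    records = []
    for (pop, res), sub in mt.groupby(["population", "resource_type"]):
        i = sub["r_star"].idxmin()
        rec = {
            "population": pop,
            "resource_type": res,
            "Rstar_min": float(sub.loc[i, "r_star"]),
            "TRstar_min": float(sub.loc[i, "temperature"]),
            "net_mu_max_max": float(sub["net_mu_max"].max()),
        }
        if "phylum" in sub.columns:
            rec["phylum"] = sub["phylum"].iloc[0]
        records.append(rec)
    out = pd.DataFrame.from_records(records)

    tpc_parts = []
    for trait in ("Topt", "Tmax", "Tbr"):
        flag = f"{trait}_excluded"
        tt = tpc_table
        if flag in tt.columns:
            tt = tt[tt[flag] == False]  # noqa: E712
        agg = (
            tt.dropna(subset=[trait])
            .groupby(["population", "resource_type"])[trait]
            .max()
            .rename(f"{trait}_max")
        )
        tpc_parts.append(agg)
    tpc_summary = pd.concat(tpc_parts, axis=1).reset_index()
    out = out.merge(tpc_summary, on=["population", "resource_type"], how="outer")

    # z-score of ln R*_min within each resource type
    def scale(group: pd.Series) -> pd.Series:
        logs = np.log(group)
        sd = logs.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            return pd.Series(np.nan, index=group.index)
        return (logs - logs.mean()) / sd

    out["scaled_logRstar_min"] = (
        out.groupby("resource_type")["Rstar_min"].transform(scale)
    )
    return out


def run_pca(summary: pd.DataFrame, columns=SUMMARY_TRAITS) -> dict:
    """PCA on centered-and-scaled summary traits.

    Rows with missing values are dropped (listwise) and reported. Returns
    scores, loadings and per-axis variance explained (percent, summing to
    100 over all axes).
    """
    cols = [c for c in columns if c in summary.columns]
    data = summary.dropna(subset=cols)
    if len(data) < 3:
        raise ValueError("need >= 3 complete rows for a PCA")
    X = data[cols].to_numpy(float)
    sds = X.std(axis=0, ddof=1)
    if np.any(sds == 0):
        bad = [c for c, s in zip(cols, sds) if s == 0]
        raise ValueError(f"constant columns: {bad}")
    Z = (X - X.mean(axis=0)) / sds
    pca = PCA()
    scores = pca.fit_transform(Z)
    return {
        "scores": pd.DataFrame(
            scores, index=data.index,
            columns=[f"PC{i + 1}" for i in range(scores.shape[1])],
        ),
        "loadings": pd.DataFrame(
            pca.components_.T, index=cols,
            columns=[f"PC{i + 1}" for i in range(scores.shape[1])],
        ),
        "variance_explained_pct": pca.explained_variance_ratio_ * 100.0,
        "n_used": len(data),
        "n_dropped": len(summary) - len(data),
        "index": data.index,
    }


def anosim(
    X: np.ndarray | pd.DataFrame,
    grouping,
    n_perm: int = 999,
    seed: int = 0,
) -> tuple[float, float]:
    """Analysis of similarities on Euclidean distances.

    R = (mean between-group rank distance - mean within-group rank
    distance) / (M/2) with M = n(n-1)/2; the p-value comes from label
    permutation. ``X`` is an observations-by-features matrix (PCA scores by
    default in this pipeline).
    """
    X = np.asarray(X, float)
    labels = np.asarray(grouping)
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2 or np.any(counts < 2):
        raise ValueError("need >= 2 groups with >= 2 members each")
    d = pdist(X)
    ranks = rankdata(d)
    n = len(labels)
    ii, jj = np.triu_indices(n, k=1)
    within = labels[ii] == labels[jj]
    M = n * (n - 1) / 2

    def stat(w: np.ndarray) -> float:
        return float((ranks[~w].mean() - ranks[w].mean()) / (M / 2))

    if within.all() or (~within).all():
        return 0.0, 1.0
    r_obs = stat(within)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        w = perm[ii] == perm[jj]
        if stat(w) >= r_obs:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return r_obs, float(p)


def welch_games_howell(values, grouping) -> dict:
    """Welch's ANOVA plus Games-Howell pairwise comparisons."""
    df = pd.DataFrame({"y": np.asarray(values, float),
                       "g": np.asarray(grouping)})
    counts = df.groupby("g")["y"].count()
    if len(counts) < 2 or counts.min() < 2:
        raise ValueError("need >= 2 groups with >= 2 values each")
    aov = pg.welch_anova(data=df, dv="y", between="g")
    gh = pg.pairwise_gameshowell(data=df, dv="y", between="g")
    return {
        "welch_F": float(aov["F"].iloc[0]),
        "welch_p": float(aov["p_unc"].iloc[0]),
        "pairwise": gh,
    }


def kendall_matrix(summary: pd.DataFrame, columns=SUMMARY_TRAITS):
    """Pairwise Kendall tau-b (tie-corrected) with two-sided p-values."""
    cols = [c for c in columns if c in summary.columns]
    if len(summary) < 3:
        raise ValueError("need >= 3 rows")
    tau = pd.DataFrame(np.nan, index=cols, columns=cols)
    pval = pd.DataFrame(np.nan, index=cols, columns=cols)
    for i, a in enumerate(cols):
        for b in cols[i:]:
            pair = summary[[a, b]].dropna()
            xa, xb = pair[a].to_numpy(), pair[b].to_numpy()
            if len(pair) < 3 or np.all(xa == xa[0]) or np.all(xb == xb[0]):
                continue  # constant column: tau undefined, left missing
            t, p = kendalltau(xa, xb)
            tau.loc[a, b] = tau.loc[b, a] = t
            pval.loc[a, b] = pval.loc[b, a] = p
    return tau, pval


def interaction_test(
    trait_y,
    trait_x,
    resource_labels,
) -> dict:
    """F-test for a trait_x-by-resource interaction on trait_y.

    Fits ``y ~ x * resource`` by least squares and tests the interaction
    block with a partial F-test against ``y ~ x + resource``. When the
    interaction is not significant (p > 0.05), the pooled regression across
    resources is reported.
    """
    df = pd.DataFrame({
        "y": np.asarray(trait_y, float),
        "x": np.asarray(trait_x, float),
        "resource": np.asarray(resource_labels),
    }).dropna()
    if df["resource"].nunique() < 2:
        raise ValueError("need >= 2 resource types")
    full = smf.ols("y ~ x * C(resource)", data=df).fit()
    reduced = smf.ols("y ~ x + C(resource)", data=df).fit()
    f, p, _ = full.compare_f_test(reduced)
    out = {"interaction_F": float(f), "interaction_p": float(p), "n": len(df)}
    if p > 0.05:
        pooled = smf.ols("y ~ x", data=df).fit()
        out["pooled_slope"] = float(pooled.params["x"])
        out["pooled_intercept"] = float(pooled.params["Intercept"])
        out["pooled_p"] = float(pooled.pvalues["x"])
    return out


def null_tau_distribution(
    tmax_max: np.ndarray,
    lower_bounds: np.ndarray | float,
    observed_tau: float,
    n_sims: int = 1000,
    seed: int = 0,
) -> dict:
    """Random expectation of Kendall's tau for traits constrained by Tmax.

    For each simulation, a surrogate trait (standing in for TRstar_min or
    Topt_max) is drawn uniformly between each population's lower bound and
    its Tmax_max, and tau against Tmax_max is computed. Heterogeneous upper
    bounds alone tend to generate positive correlations — the sampling
    artifact this null quantifies. Returns the null distribution and the
    observed tau's two-sided percentile within it.
    """
    if n_sims < 100:
        raise ValueError("n_sims must be >= 100")
    tmax_max = np.asarray(tmax_max, float)
    lower = np.broadcast_to(np.asarray(lower_bounds, float), tmax_max.shape)
    if np.any(lower >= tmax_max):
        raise ValueError("every lower bound must be below its Tmax_max")
    rng = np.random.default_rng(seed)
    null = np.empty(n_sims)
    for s in range(n_sims):
        surrogate = rng.uniform(lower, tmax_max)
        null[s], _ = kendalltau(surrogate, tmax_max)
    frac_below = float(np.mean(null < observed_tau))
    return {
        "null_tau": null,
        "null_mean": float(null.mean()),
        "observed_tau": float(observed_tau),
        "percentile": frac_below,
        "two_sided_p": float(
            2 * min(np.mean(null >= observed_tau), np.mean(null <= observed_tau))
        ),
    }


def exclusion_counts(estimates: pd.DataFrame) -> dict[str, int]:
    """Count posterior-median thermal-trait estimates removed by the
    retention bounds, per trait, from a parameter-estimate table with
    columns among Topt, Tmax, Tmin, Tbr (one row per population x resource
    level). Deterministic given the table — the same bookkeeping applied to
    published estimate tables or to this package's own output."""
    from .tpc_traits import EXCLUSION_BOUNDS

    out = {}
    for trait, (lo, hi) in EXCLUSION_BOUNDS.items():
        if trait not in estimates.columns:
            continue
        v = estimates[trait].dropna().to_numpy(float)
        out[f"{trait}_total"] = int(len(v))
        out[f"{trait}_excluded"] = int(np.sum((v < lo) | (v > hi)))
    return out
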