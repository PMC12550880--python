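#!/usr/bin/env python
"""Classify how each population's competition traits vary with temperature.

For every population x resource from 03_fit_monod.py, builds the
posterior-bootstrap ensemble for R*, affinity (both gamma-family, bounded
by zero) and net-mu_max (Gaussian) against temperature, applies the EDF
linearity gate and the 60%/70% probability rules, and also fits the
unweighted mean-species curve per trait and resource.

Run: python analysis/05_classify_shapes.py [--seed 1] [--outdir results]
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from thermotrait import gradient_shapes as gs
from thermotrait import pipeline_io as pio
from thermotrait._mcmc import derive_seed

TRAITS = (("r_star", "gamma"), ("alpha", "gamma"), ("net_mu_max", "gaussian"))


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    ap.add_argument("--n-boot", type=int, default=500)
    args = ap.parse_args()

    fits = pd.read_csv(args.outdir / "monod_fits.csv")
    records = []
    for (pop, res), sub in fits.groupby(["population", "resource_type"]):
        sub = sub.sort_values("temperature")
        for trait, family in TRAITS:
            vals = sub[trait].to_numpy(float)
            half = 0.25 * (sub[f"{trait}_hi"] - sub[f"{trait}_lo"]).to_numpy(float)
            ok = np.isfinite(vals) & np.isfinite(half)
            if ok.sum() < 4:
                continue
            rng = np.random.default_rng(
                derive_seed(args.seed, "draws", pop, res, trait))
            draws = vals[ok] + half[ok] * rng.standard_normal((400, int(ok.sum())))
            if family == "gamma":
                draws = np.maximum(draws, 1e-9)
            series = gs.GradientSeries(
                sub["temperature"].to_numpy(float)[ok], draws, family)
            verdict = gs.classify_shape(gs.bootstrap_fits(
                series, args.n_boot,
                seed=derive_seed(args.seed, "boot", pop, res, trait)))
            records.append({
                "population": pop, "resource_type": res, "trait": trait,
                "label": verdict.label, "probability": verdict.probability,
                "pathway": verdict.pathway, "frac_linear": verdict.frac_linear,
                "critical_point": verdict.critical_point})
    out = pd.DataFrame.from_records(records)
    pio.write_table(out, args.outdir / "shape_verdicts.csv")
    print("shape labels by trait:")
    print(out.groupby(["trait", "label"]).size().to_string())

    # mean-species expectation per trait and resource
    mean_rows = []
    for (res, trait_family) in [(r, tf) for r in fits["resource_type"].unique()
                                for tf in TRAITS]:
        trait, family = trait_family
        sub = fits[fits["resource_type"] == res]
        means = sub.groupby("temperature")[trait].agg(["mean", "count"])
        means = means[np.isfinite(means["mean"])]
        if len(means) < 4 or (means["count"] < 2).any():
            continue
        v = gs.mean_species_curve(means.index.to_numpy(float),
                                  means["mean"].to_numpy(),
                                  means["count"].to_numpy(), family)
        mean_rows.append({"resource_type": res, "trait": trait,
                          "label": v.label, "pathway": v.pathway,
                          "critical_point": v.critical_point})
    mean_out = pd.DataFrame.from_records(mean_rows)
    pio.write_table(mean_out, args.outdir / "mean_species_shapes.csv")
    print("\nmean-species curves:")
    print(mean_out.to_string(index=False))


if __name__ == "__main__":
    main()
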