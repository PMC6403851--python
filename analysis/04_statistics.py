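#!/usr/bin/env python
"""Statistics over agent dose series.

Simulates short dose series for all six emulated agents, then computes
the attribute correlation matrix, a standardized PCA, and an
exponential-decay fit of average protein length against end-point rate.
Writes tables under results/stats/ and prints the headline numbers:
the branching/width and end-point/length correlations should be
negative, and the first two principal components should carry most of
the variance.
"""

import argparse
import json
import os

import numpy as np
import pandas as pd

from glutenpna import PipelineConfig, generate_dose_series, process_micrograph
from glutenpna.stats import fit_exponential_decay, pca, pearson_matrix
from glutenpna.synthetic import AGENTS

ATTRS = ["lacunarity", "branching_rate", "endpoint_rate",
         "avg_protein_length_um", "protein_width_um"]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--seeds-per-sample", type=int, default=3)
    parser.add_argument("--out-dir", default="results/stats")
    args = parser.parse_args()
    os.makedirs(args.out_dir, exist_ok=True)

    config = PipelineConfig()
    rows = []
    for agent in AGENTS:
        for k in range(args.seeds_per_sample):
            for conc, micro, _ in generate_dose_series(
                    agent, [0.0, 1.0, 2.0, 3.0], seed=args.seed + k):
                p = process_micrograph(micro, config)
                rows.append({"sample": f"{agent}_c{conc:g}", "agent": agent,
                             "concentration": conc,
                             **{a: getattr(p, a) for a in ATTRS}})
    table = pd.DataFrame(rows)
    table.to_csv(os.path.join(args.out_dir, "dose_series_attributes.csv"),
                 index=False)

    corr = pearson_matrix(table, ATTRS, by="sample")
    pd.DataFrame(corr.r, index=corr.names, columns=corr.names).to_csv(
        os.path.join(args.out_dir, "correlation.csv"))
    print("Pearson r (per-sample means):")
    print(f"  branching vs width     r = {corr.get('branching_rate', 'protein_width_um'):+.2f}")
    print(f"  end-point vs length    r = {corr.get('endpoint_rate', 'avg_protein_length_um'):+.2f}")

    means = table.groupby("sample")[ATTRS].mean()
    res = pca(means, ATTRS)
    pd.DataFrame(res.loadings, index=ATTRS,
                 columns=[f"PC{i+1}" for i in range(res.loadings.shape[1])]
                 ).to_csv(os.path.join(args.out_dir, "pca_loadings.csv"))
    fractions = res.explained_fractions
    print(f"PCA explained variance: PC1 {fractions[0]:.0%}, PC2 {fractions[1]:.0%} "
          f"(first two: {fractions[:2].sum():.0%})")

    x = means["endpoint_rate"].to_numpy()
    y = means["avg_protein_length_um"].to_numpy()
    order = np.argsort(x)
    fit = fit_exponential_decay(x[order], y[order])
    print(f"length vs end-point rate, y = a·exp(-b·x)+c: "
          f"a={fit.a:.0f}, b={fit.b:.3f}, c={fit.c:.0f}, R² = {fit.r_squared:.2f}")
    with open(os.path.join(args.out_dir, "exp_fit.json"), "w") as fh:
        json.dump({"a": fit.a, "b": fit.b, "c": fit.c,
                   "r_squared": fit.r_squared,
                   "explained_fractions": fractions.tolist()}, fh, indent=2)


if __name__ == "__main__":
    main()
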