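"""Condition-level statistics on the quantified cells.

Computes the summary metrics (percent SG-positive cells, SGs per positive
cell, SG intensity), fits the negative-binomial model to per-cell counts with
condition as covariate, and runs the replicate-level Welch t-test with BH FDR
control at 1%.

Run from the repository root:  python analysis/03_condition_statistics.py
"""

from pathlib import Path

import numpy as np
import pandas as pd

from sgquant.stats import fit_negative_binomial, replicate_ttest_fdr, summarize_condition

QUANT = Path("results/quantification")
OUT = Path("results/statistics")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cells = pd.read_csv(QUANT / "cells.csv")
    sgs = pd.read_csv(QUANT / "stress_granules.csv")

    rows = []
    for cond, grp in cells.groupby("condition"):
        s = summarize_condition(grp, str(cond),
                                sg_intensity=sgs.loc[sgs["condition"] == cond, "integrated_intensity"])
        rows.append(
            {
                "condition": s.condition,
                "n_fields": s.n_fields,
                "n_cells": s.n_cells,
                "pct_cells_with_sgs": round(s.pct_cells_with_sgs, 2),
                "sem_pct": round(s.sem_pct, 3),
                "mean_sgs_per_positive_cell": None if s.mean_sgs_per_positive_cell is None
                else round(s.mean_sgs_per_positive_cell, 3),
                "mean_sg_intensity": None if s.mean_sg_intensity is None
                else round(s.mean_sg_intensity, 1),
            }
        )
    summary = pd.DataFrame(rows)
    summary.to_csv(OUT / "condition_summary.csv", index=False)
    print(summary.to_string(index=False))

    fit = fit_negative_binomial(cells["sg_count"].to_numpy(), cells["condition"].to_numpy())
    nb = pd.DataFrame(
        {
            "contrast": list(fit.beta),
            "beta": [fit.beta[n] for n in fit.beta],
            "se": [fit.se[n] for n in fit.beta],
            "wald_z": [fit.wald_z[n] for n in fit.beta],
            "p": [fit.p_value[n] for n in fit.beta],
        }
    )
    nb.to_csv(OUT / "nb_contrasts.csv", index=False)
    print(f"\nNB dispersion k = {fit.k:.2f}; condition means "
          + ", ".join(f"{c}: {m:.2f}" for c, m in fit.mu.items()))
    print(nb.to_string(index=False))

    # replicate-level percent-positive comparison between the two conditions
    pct = cells.groupby(["condition", "replicate"]).apply(
        lambda g: 100.0 * g["sg_positive"].mean(), include_groups=False
    )
    conds = sorted(cells["condition"].unique())
    comparisons = {
        f"{a}_vs_{b}": (pct[a].to_numpy(), pct[b].to_numpy())
        for i, a in enumerate(conds)
        for b in conds[i + 1:]
    }
    tt = replicate_ttest_fdr(comparisons, q_star=0.01)
    tt.to_csv(OUT / "replicate_ttests.csv", index=False)
    print("\n" + tt.to_string(index=False))


if __name__ == "__main__":
    main()
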