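#!/usr/bin/env python
"""Stratify the cohort by regulator activity and compare survival.

Projects every sample onto the principal component of the causal
regulator's target genes (the predicted activation state), splits the
cohort in two by 1-D k-means, and compares the groups' survival by
Kaplan-Meier curves and the two-sided log-rank test. Also tests the
association between activity group and amplification status with a
chi-square contingency test.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from malignet import io, stratify, survstats

COHORT = Path("results/cohort")
UPSTREAM = Path("results/upstream")
OUT = Path("results/stratify")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    expr = io.read_expression(COHORT / "expression.tsv")
    truth = json.loads((COHORT / "truth.json").read_text())
    network = pd.read_csv(UPSTREAM / "network.tsv", sep="\t")
    surv = pd.read_csv(COHORT / "survival.csv").set_index("sample_id")

    targets = sorted(set(network.loc[network["regulator"] == "REG_TRUE", "target"]))
    act = stratify.activity_score(expr, targets)
    groups = stratify.kmeans_two_groups(act, seed=13)
    pd.DataFrame({"activity_score": act.scores, "group": groups}).to_csv(
        OUT / "groups.csv", index_label="sample_id"
    )

    truth_act = pd.Series(truth["activity"])
    cor = np.corrcoef(act.scores, truth_act[act.scores.index])[0, 1]

    chi2, p = survstats.logrank_test(
        surv["time"], surv["event"], groups.loc[surv.index]
    )
    km = {
        g: survstats.km_curve(surv.loc[groups == g, "time"], surv.loc[groups == g, "event"])
        for g in ("Group1", "Group2")
    }
    median_surv = {
        g: float(km[g].times[np.searchsorted(-km[g].survival, -0.5)])
        if (km[g].survival <= 0.5).any() else float("inf")
        for g in km
    }

    amplified = set(truth["amplified_samples"])
    table = pd.crosstab(
        groups, pd.Series({s: s in amplified for s in groups.index}, name="amplified")
    )
    chi2_amp, df_amp, p_amp = survstats.contingency_chisq(table.to_numpy())

    (OUT / "survival_tests.json").write_text(
        json.dumps(
            {
                "activity_truth_correlation": float(cor),
                "logrank_chi_square": chi2,
                "logrank_p": p,
                "median_survival": {k: (v if np.isfinite(v) else None) for k, v in median_surv.items()},
                "group_vs_amplification_chi2": chi2_amp,
                "group_vs_amplification_p": p_amp,
            },
            indent=1,
        )
    )
    n1 = int((groups == "Group1").sum())
    print(f"activity score vs planted activity: r = {cor:.3f} "
          f"(explained variance {act.explained_variance_fraction:.2f})")
    print(f"groups: Group1 (high activity) n={n1}, Group2 n={len(groups) - n1}")
    print(f"log-rank: chi2 = {chi2:.2f}, p = {p:.2e} "
          f"(median survival {median_surv})")
    print(f"group vs amplification: chi2 = {chi2_amp:.2f}, p = {p_amp:.3f}")


if __name__ == "__main__":
    main()
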