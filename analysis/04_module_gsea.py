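#!/usr/bin/env python
"""Test the malignancy module for coordinated regulation by GSEA.

Contrasts high- versus low-activity samples (split on the module
eigengene), ranks the transcriptome by log2 ratio, and computes the
weighted enrichment score of the module gene set with gene-label
permutation NES, nominal p, and FDR q.
"""

import json
from pathlib import Path

import pandas as pd

from malignet import gsea, io

COHORT = Path("results/cohort")
MODULES = Path("results/modules")
OUT = Path("results/gsea")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    expr = io.read_expression(COHORT / "expression.tsv")
    table = pd.read_csv(MODULES / "module_assignment.tsv", sep="\t", index_col=0)
    eigengenes = pd.read_csv(MODULES / "eigengenes.tsv", sep="\t", index_col=0)
    truth = json.loads((COHORT / "truth.json").read_text())

    planted = {g for g, m in truth["module_labels"].items() if m == 1}
    module_id = max(
        set(table["module"]) - {0},
        key=lambda m: len(planted & set(table.index[table["module"] == m])),
    )
    module_genes = set(table.index[table["module"] == module_id])
    eg = eigengenes.loc[module_id]
    high = list(eg.index[eg > eg.median()])
    low = [s for s in eg.index if s not in high]

    ranked = gsea.rank_genes(expr, high, low)
    result = gsea.normalize_and_test(ranked, module_genes, n_perm=1000, seed=11)

    (OUT / "gsea_result.json").write_text(
        json.dumps(
            {
                "module": int(module_id),
                "es": result.es,
                "nes": result.nes,
                "nominal_p": result.nominal_p,
                "fdr_q": result.fdr_q,
                "leading_edge_size": len(result.leading_edge),
            },
            indent=1,
        )
    )
    print(f"module {module_id} ({len(module_genes)} genes) vs "
          f"high/low activity contrast ({len(high)}/{len(low)} samples)")
    print(f"ES = {result.es:.3f}, NES = {result.nes:.3f}, "
          f"nominal p = {result.nominal_p:.4f}, FDR q = {result.fdr_q:.4f}")
    print(f"leading edge: {len(result.leading_edge)} genes")


if __name__ == "__main__":
    main()
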