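# malignet

Malignancy gene-module discovery from tumor transcriptomes, built as a
tested, reusable pipeline. The package is aimed at computational
biologists who want to go from a bulk expression cohort to a ranked list
of candidate master regulators and their clinical associations:

1. **Co-expression modules** — a weighted gene network from soft-thresholded
   Pearson correlations, `a_ij = |cor(x_i, x_j)|^β`, summarized by the
   topological overlap matrix
   `TOM_ij = (Σ_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 − a_ij)`,
   clustered on `1 − TOM` (average linkage, static tree cut). Modules get
   eigengenes (first principal component) and per-gene membership
   `kME_i = cor(x_i, eigengene)`; hub genes are the high-connectivity
   nodes of the TOM > 0.13 sub-network.
2. **Upstream regulators** — for a signed regulator→target network, each
   regulator's direction-aware activation z-score
   `z = Σ w_i x_i / √(Σ w_i²)` (weights = |kME|, `x_i = ±1` for
   agreement between observed kME sign and the sign expected under
   activation), a Fisher overlap p, and a summary score = sum of
   activation z-scores over linked annotation terms.
3. **GSEA** — weighted Kolmogorov–Smirnov running-sum enrichment score,
   gene-label permutation `NES = ES / mean(same-sign permuted ES)`,
   nominal p, FDR q.
4. **Enrichment ordering** — Fisher exact p plus a rank-deviation z and
   the combined score `c = ln(P) · z`; promoter-window calling of direct
   targets from binding peaks (−5 kb/+1 kb around the TSS, strand-aware).
5. **Stratification & survival** — PCA activity score over regulator
   targets, two-group 1-D k-means, Kaplan–Meier curves, two-sided
   log-rank test, chi-square contingency tests, Spearman correlation;
   DE filtering at |log2FC| > 0.263 and paired-t P < 0.05 (strict).
6. **Copy number** — penalized binary segmentation of log-ratio probe
   tracks; a locus is amplification-positive iff the covering segment's
   median log-ratio (smoothing value) is strictly > 0.
7. **Drug synergy** — median-effect fits `fa/fu = (D/Dm)^m` and the
   Chou–Talalay combination index `CI = D₁/Dx₁ + D₂/Dx₂`
   (1 additive, < 1 synergistic, > 1 antagonistic).
8. **Assay formulas** — T7E1 mutation frequency, IHC H-index, 2^−ΔΔCt
   fold change, caliper tumor volume.

A synthetic-cohort generator (`malignet.synthio`) provides expression,
survival, copy-number, and dose-response data with recorded ground
truth, so every stage is testable without external data.

## Worked example

The numbered drivers under `analysis/` run the full study on the
reference synthetic cohort (run them in order from the repository root;
outputs land under `results/`):

```sh
python analysis/01_simulate_cohort.py
python analysis/02_coexpression_modules.py
python analysis/03_upstream_regulators.py
```

`02` prints

```
network built at soft power 6; modules (size): {3: 51, 2: 51, 1: 51}
adjusted Rand index vs planted modules: 0.986
```

— the three planted 50-gene modules are recovered nearly perfectly
(ARI close to 1) from the 1000-gene, 60-sample cohort. `03` then prints

```
           n_targets      fisher_p  module_z  summary_score  rank
REG_TRUE          50  5.390858e-84  7.068916      15.807015     1
DECOY_07          50  5.390858e-84  1.143236       2.550727     2
top-ranked regulator: REG_TRUE (the planted driver)
```

— every regulator targets the same module genes (identical Fisher p),
but only the causal one has consistent edge signs, so the activation
z-score separates it sharply (z ≈ 7 ≈ √50 versus ≈ 0 for sign-shuffled
decoys). The remaining drivers add GSEA of the module (NES ≈ 2.7,
nominal p < 0.001), activity stratification with a strong survival
split (log-rank p ≈ 8e−5), amplification calling (≈ 97% label
accuracy), and combination-index round trips (CI = 1.000 on the
additive design, 0.500 on the configured-synergy design).

The same flow is available programmatically:

```python
from malignet import PipelineConfig, run_pipeline
results = run_pipeline(PipelineConfig(out_dir="results/pipeline"))
print(results["upstream"].head())
```

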