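# Methods

This note documents the models and procedures implemented in
`malignet`, the defaults and why they were chosen, what the synthetic
data does and does not emulate, and the numerical choices that matter
for reproducing results.

## Co-expression network and module detection

Genes are nodes; the unsigned adjacency is `a_ij = |cor(x_i, x_j)|^β`
with Pearson correlation across samples (a signed variant
`((1+cor)/2)^β` is available). The diagonal is excluded from
connectivity `k_i = Σ_j a_ij`. The topological overlap

    TOM_ij = (Σ_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 − a_ij)

rewards shared neighborhoods; its diagonal is fixed at 1 and `1 − TOM`
is the clustering dissimilarity. Modules come from average-linkage
hierarchical clustering with a **static tree cut**: clusters formed
below the cut height survive, anything smaller than `min_module_size`
(default 30) is left unassigned (label 0), and labels are assigned in
decreasing size order.

Two defaults deserve explanation:

* **Cut height 0.95.** On `1 − TOM`, within-module merge heights for a
  realistically noisy module (pairwise r ≈ 0.8, β = 6) sit around
  0.7–0.8 while between-module and background merges concentrate near
  1.0, so the informative cut range is high. A low cut (e.g. 0.25),
  natural for eigengene-merging heights, produces only singletons here.
* **Fixed soft power β = 6 in the pipeline.** `pick_soft_threshold`
  implements the scale-free topology criterion (bin log k, regress
  log frequency on log k, smallest power with R² ≥ 0.8, else the
  R²-maximizing power; degenerate fits — all k equal — are flagged and
  fall back to the smallest candidate). On latent-factor cohorts the
  criterion is noisy: the chosen power varies widely between replicate
  cohorts generated under identical conditions, and no single static
  cut height serves powers from 4 to 12. The pipeline therefore uses
  the conventional unsigned-network default β = 6, which together with
  the 0.95 cut recovers planted modules with ARI ≥ 0.97 across dozens
  of replicate cohorts; set `PipelineConfig.soft_power = None` to use
  the scale-free choice instead.

Eigengenes are first right-singular vectors of the per-gene
standardized module submatrix, sign-oriented to correlate positively
with the module's mean standardized profile and stored with unit norm;
`kME_i` is the correlation of gene i's expression with its module
eigengene. Genes with missing values or zero variance are dropped with
a logged count before network construction.

## Upstream regulator ranking

Given a signed regulator→target network, a regulator's activation
z-score over a target set is `z = Σ w_i x_i / √(Σ w_i²)` with
`x_i = +1` when the observed direction of target i matches the sign
expected under regulator activation, −1 otherwise. For module-level
scoring the observed direction of a module gene is the sign of its kME
and its weight is |kME| — module membership is the natural per-gene
confidence available from the network stage. Regulators need ≥ 3
in-module targets to be scored (a stability floor; z over one or two
targets is meaningless). The ranking key is the summary score — the sum
of activation z-scores over the annotation terms the regulator is
linked to — with ties broken by Fisher overlap p, then lexical ID. The
Fisher universe is the set of genes in the expression matrix after
filtering, not the genome: enrichment should be judged against what
could have been observed.

## GSEA

The enrichment score is the maximum-magnitude deviation of the weighted
Kolmogorov–Smirnov running sum (hits step by `|metric|^p` normalized to
the in-set total, p = 1 by default; misses step by `−1/(N − N_hit)`).
The profile starts and ends at exactly 0; ES ∈ [−1, 1]. Ranking uses a
log2 ratio of group means after a positive shift of `|global min| + 1`
when nonpositive values are present; ties are broken lexically by gene
ID so results are deterministic.

Significance uses **gene-label permutations** (random same-size gene
sets): the three-replicate contrasts this pipeline targets leave
phenotype permutation undefined. `NES = ES / mean(|same-sign permuted
ES|)`; the nominal p is the same-sign tail fraction; the FDR q compares
the observed NES with the sign-matched permuted-NES distribution (each
permuted ES normalized by its own sign-class mean). When no same-sign
permutation exists, q is reported as 0 with a warning. Null calibration
is verified by simulation: nominal p is uniform within
Kolmogorov–Smirnov tolerance over 200 null draws.

## Enrichment ordering and promoter windows

Fisher enrichment is the upper-tail hypergeometric probability of the
observed-or-greater overlap, term intersected with the universe first.
The combined score is `c = ln(P) · z` (natural log, reported signed)
where z is the deviation of the term's p-value rank from its mean rank
over 100 seeded random queries of the same size, divided by the null
rank standard deviation. Direct-target calling treats BED peaks as
0-based half-open intervals and tests overlap with the strand-aware
closed window [TSS − 5000, TSS + 1000] (mirrored on the − strand),
gated on membership in the differentially expressed set.

## Stratification and survival

The DE filter is strict on both thresholds: |log2FC| > 0.263 and
paired-t P < 0.05; boundary values fail. The activity score is the
first principal component of the z-scored target-gene submatrix,
oriented to correlate nonnegatively with mean target expression; if
that orientation check falls below |r| = 0.3 the top-correlating
component is used instead (the component that "represents" the
activation state need not be PC1 when targets carry mixed signals).
Patients are split by 1-D k-means (k-means++ with 10 seeded restarts);
Group1 is the higher-score cluster.

Kaplan–Meier estimation and the two-group log-rank test are direct
numpy implementations of the product-limit estimator and the
`U²/V ~ χ²₁` statistic — kept in-package so that 2000-replicate
calibration simulations run in seconds — and are cross-checked against
lifelines in the test-suite. Ties at an event time use the
simultaneous-event convention; censoring at an event time is placed
after the event. P-values are two-sided. Chi-square contingency tests
(no continuity correction by default) and Spearman correlation
(mid-ranks, t-approximation p) delegate to scipy.

## Copy-number segmentation

Tracks are segmented by penalized binary segmentation: recursive
splitting at the SSE-minimizing change-point while the SSE reduction
exceeds `4 σ̂² log n`, with σ̂ estimated from the median absolute first
difference (robust to the sparse change-points). The factor 4 — rather
than the BIC-like 2 — absorbs the scan-maximum inflation of the best
spurious gain under pure noise; with 2 the segmenter over-splits about
one track in ten at probe noise σ = 0.1, while 4 recovers breakpoints
within ±1 probe in ≥ 95% of replicates and still sits an order of
magnitude below the gain from the smallest step of interest
(|Δmean| = 0.4 over 20 probes). Each segment records the median
log-ratio of its probes — the smoothing value — and a locus is
amplification-positive iff its covering segment's median is strictly
greater than 0 (a median of exactly 0 is negative).

## Drug synergy

Single-agent (m, Dm) come from ordinary least squares on the
linearized median-effect plot `log(fa/fu) = m log D − m log Dm`; points
with fa ∉ (0, 1) or dose ≤ 0 carry no information and are excluded with
a logged count. Viability should be normalized to untreated control
first (`normalize_to_control`). The combination index at a combo
point's observed fa is `CI = D₁/Dx₁(fa) + D₂/Dx₂(fa)` with
`Dx = Dm (fa/fu)^(1/m)`; points are classified per CI = 1 / < 1 / > 1
(a 1e−9 tolerance absorbs floating-point noise only) and never averaged
unless the caller does so. The sham combination — one drug paired with
itself at half doses — yields CI = 1 to machine precision, the method's
internal consistency check.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes,
with the defaults as the reference study conditions:

* **Expression**: 60 samples, 1000 genes; three planted modules of 50
  genes, each following `x_ij = β a_j + ε_ij` with its own centered
  standard-normal latent activity, β = 1 and residual σ = 0.5 (within-
  module pairwise r = β²/(β² + σ²) = 0.8, a strongly co-expressed
  module); 850 pure-noise background genes. Module 1's activity is the
  recorded regulator activation state.
* **Survival**: exponential proportional hazards
  `h_j = 0.1 · exp(1.0 · a_j)` with 20% independent censoring. The
  exponential null makes log-rank type-I calibration analytically
  clean.
* **Copy number**: four 25-probe segments with means (0, 0.5, 0, −0.3)
  and probe noise σ = 0.1; the second segment is amplified (+0.5) in
  half the samples and sits at the neutral mean −0.1 in the rest — a
  slightly negative neutral baseline, as tumor-vs-reference
  normalization of an unstable genome leaves two-copy loci just below
  zero; it also keeps the strict >0 label well defined under noise.
* **Dose–response**: two median-effect drugs (m, Dm) = (1.5, 1.0) and
  (2.0, 0.5), eight geometric doses; combination points place each drug
  at half its equi-effective dose scaled by the configured true CI, so
  the generated design has a known per-point CI (1 = Loewe additive).
* **Regulator network**: one causal regulator activating every
  module-1 gene (sign +1, matching the positive loadings) and nine
  decoys with independently shuffled signs; annotation terms partition
  the module genes into five blocks.

A single global seed fans out to per-stage substreams
(`SeedSequence.spawn`), so identical seeds reproduce every artifact
bit-identically and stages can be regenerated independently.

What the generator does **not** emulate: probe-level microarray
artifacts, batch effects, correlated censoring, overlapping or nested
modules, regulator cascades, or real chondrosarcoma-like mutation
spectra. Passing recovery tests therefore demonstrates correctness of
the estimators under the stated generative model, not robustness to
real-data violations of it.

## Problem sizes and determinism

The test-suite and the acceptance script size their simulations for
desk-scale runs: 1000-gene cohorts for module recovery, 100 replicate
cohorts for regulator top-rank rates, 2000 null replicates for log-rank
calibration (n = 50 per arm), 200 null draws × 200 permutations for
GSEA calibration, and 100 replicates for segmentation and median-effect
noise recovery. All randomness flows from explicit seeds; every
reported number is recomputed at run time.

## Known limitations

* The static tree cut trades the adaptivity of dynamic dendrogram
  cutting for determinism; cohorts with modules of very unequal
  tightness may need a hand-chosen cut height.
* FDR q for a single gene set degenerates toward the nominal p; it is
  most meaningful when many sets are tested against a shared
  permutation ensemble.
* The upstream summary score depends on the annotation collection
  supplied; terms that share targets are double-counted by design
  (matching the "sum over linked nodes" reading).
* Binary segmentation is greedy; closely spaced opposite-sign
  change-points below the penalty scale can be merged.
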