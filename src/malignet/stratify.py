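"""Differential-expression filtering and activity-based patient grouping.

The DE filter applies the strict cut-offs |log2FC| > 0.263 and paired-t
P < 0.05. Patient stratification projects each sample onto the principal
component of a regulator's target-gene expression (the predicted
activation state) and splits the cohort in two by 1-D k-means; Group1 is
the higher-activity cluster.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from .errors import InputError

__all__ = [
    "DEFAULT_LOG2FC_CUTOFF",
    "DEFAULT_P_CUTOFF",
    "ActivityScores",
    "paired_de",
    "de_filter",
    "activity_score",
    "kmeans_two_groups",
]

log = logging.getLogger(__name__)

DEFAULT_LOG2FC_CUTOFF = 0.263
DEFAULT_P_CUTOFF = 0.05


def paired_de(expr_a: pd.DataFrame, expr_b: pd.DataFrame) -> pd.DataFrame:
    """Per-gene paired differential expression between two conditions.

    Expression is assumed log2-scale; replicate pairing follows column
    order. Returns a DataFrame with columns gene, log2_fold_change,
    p_value (paired two-sample t test).
    """
    if expr_a.shape != expr_b.shape:
        raise InputError("paired conditions must have identical shape")
    if not expr_a.index.equals(expr_b.index):
        raise InputError("gene indices differ between conditions")
    a = expr_a.to_numpy(dtype=float)
    b = expr_b.to_numpy(dtype=float)
    log2fc = a.mean(axis=1) - b.mean(axis=1)
    _, p = stats.ttest_rel(a, b, axis=1)
    return pd.DataFrame(
        {"gene": expr_a.index, "log2_fold_change": log2fc, "p_value": p}
    )


def de_filter(
    records: pd.DataFrame,
    log2fc_cutoff: float = DEFAULT_LOG2FC_CUTOFF,
    p_cutoff: float = DEFAULT_P_CUTOFF,
) -> tuple[list[str], list[str]]:
    """Strict-inequality DE filter; returns (up_genes, down_genes).

    A record passes iff |log2FC| > cutoff AND p < cutoff, both strict.
    Records with a missing p-value are skipped with a log entry.
    """
    required = {"gene", "log2_fold_change", "p_value"}
    if required - set(records.columns):
        raise InputError(f"records need columns {sorted(required)}")
    n_missing = int(records["p_value"].isna().sum())
    if n_missing:
        log.info("skipping %d records with missing p-value", n_missing)
    rec = records.dropna(subset=["p_value"])
    passes = (rec["log2_fold_change"].abs() > log2fc_cutoff) & (
        rec["p_value"] < p_cutoff
    )
    passed = rec[passes]
    up = sorted(passed.loc[passed["log2_fold_change"] > 0, "gene"])
    down = sorted(passed.loc[passed["log2_fold_change"] < 0, "gene"])
    return up, down


@dataclass
class ActivityScores:
    """Per-sample predicted regulator activity from target-gene expression."""

    scores: pd.Series
    explained_variance_fraction: float
    orientation_sign: int
    component: int = 0  # which principal component represents the activity


def activity_score(
    expr: pd.DataFrame,
    target_genes: list[str],
    min_orientation_cor: float = 0.3,
) -> ActivityScores:
    """Principal-component activity score over a regulator's target genes.

    Target genes are z-scored across samples; samples are projected onto
    the first principal component of the sample x target submatrix. The
    axis is sign-oriented so the score correlates nonnegatively with the
    mean target-gene expression. If PC1's orientation-checked correlation
    with the mean target profile falls below ``min_orientation_cor`` in
    magnitude, the top-correlating component is used instead.
    """
    present = [g for g in target_genes if g in expr.index]
    missing = sorted(set(target_genes) - set(present))
    if len(present) < 2:
        raise InputError(f"fewer than 2 target genes found; missing: {missing}")
    X = expr.loc[present].to_numpy(dtype=float)
    sd = X.std(axis=1, keepdims=True)
    if np.any(sd == 0):
        flat = [g for g, s in zip(present, sd.ravel()) if s == 0]
        raise InputError(f"zero-variance target genes: {flat}")
    Z = (X - X.mean(axis=1, keepdims=True)) / sd  # targets x samples
    mean_profile = Z.mean(axis=0)

    # SVD of the centered sample x target matrix; right singular vectors
    # give per-sample component scores
    u, s, vt = np.linalg.svd(Z, full_matrices=False)
    var_frac = (s**2) / np.sum(s**2)

    def oriented(comp: int) -> tuple[np.ndarray, int, float]:
        score = s[comp] * vt[comp]
        cor = float(np.corrcoef(score, mean_profile)[0, 1])
        sign = -1 if cor < 0 else 1
        return sign * score, sign, abs(cor)

    score, sign, cor = oriented(0)
    comp = 0
    if cor < min_orientation_cor:
        cors = [oriented(c)[2] for c in range(len(s))]
        comp = int(np.argmax(cors))
        score, sign, cor = oriented(comp)
        log.info("PC1 poorly oriented (|r|=%.2f); using PC%d", cors[0], comp + 1)
    score = score - score.mean()
    return ActivityScores(
        scores=pd.Series(score, index=expr.columns, name="activity_score"),
        explained_variance_fraction=float(var_frac[comp]),
        orientation_sign=sign,
        component=comp,
    )


def kmeans_two_groups(scores: ActivityScores | pd.Series, seed: int = 0) -> pd.Series:
    """Split samples into two groups by 1-D k-means on the activity score.

    Uses k-means++ with 10 seeded restarts; Group1 is the cluster with
    the higher mean score (higher predicted regulator activity).
    """
    values = scores.scores if isinstance(scores, ActivityScores) else scores
    if len(values) < 4:
        raise InputError("need >= 4 samples for two-group clustering")
    x = values.to_numpy(dtype=float).reshape(-1, 1)
    if np.allclose(x, x[0]):
        raise InputError("degenerate clustering: all scores identical")
    km = KMeans(n_clusters=2, n_init=10, random_state=seed)
    raw = km.fit_predict(x)
    mean0 = x[raw == 0].mean()
    mean1 = x[raw == 1].mean()
    high = 0 if mean0 >= mean1 else 1
    labels = np.where(raw == high, "Group1", "Group2")
    return pd.Series(labels, index=values.index, name="group")
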