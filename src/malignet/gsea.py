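"""Gene set enrichment analysis: weighted running-sum ES, permutation NES.

The enrichment score (ES) is the maximum-magnitude deviation of a
weighted Kolmogorov-Smirnov running sum over a ranked gene list: hits
increment by |metric|^p normalized to the in-set total, misses decrement
by 1/(N - N_hit). Significance uses gene-label permutations: the
normalized enrichment score is NES = ES / mean(same-sign permuted ES),
the nominal p-value the fraction of same-sign permuted ES at least as
extreme as the observed one, and the FDR q follows the NES-normalized
permutation procedure.

Gene-label permutation (rather than phenotype permutation) is used
throughout: with the three-replicate contrasts this pipeline targets,
phenotype permutation is not defined.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputError

__all__ = ["RankedList", "GseaResult", "rank_genes", "enrichment_score", "normalize_and_test"]


@dataclass
class RankedList:
    """Genes ordered (descending) by a signed ranking metric."""

    genes: list[str]
    metric: np.ndarray

    def __post_init__(self) -> None:
        if len(self.genes) != len(self.metric):
            raise InputError("genes and metric lengths differ")
        if len(set(self.genes)) != len(self.genes):
            raise InputError("duplicate genes in ranked list")


@dataclass
class GseaResult:
    es: float
    nes: float
    nominal_p: float
    fdr_q: float
    running_profile: np.ndarray
    leading_edge: list[str]


def rank_genes(
    expr: pd.DataFrame,
    group_a: list[str],
    group_b: list[str],
    metric: str = "log2_ratio",
) -> RankedList:
    """Rank genes by a two-group metric (default log2 ratio of means).

    To keep the log defined, expression is positive-shifted by
    ``|global min| + 1`` whenever nonpositive values are present. Ties
    are broken deterministically by lexical gene ID.
    """
    if set(group_a) & set(group_b):
        raise InputError("groups overlap")
    missing = (set(group_a) | set(group_b)) - set(expr.columns)
    if missing:
        raise InputError(f"unknown samples: {sorted(missing)}")
    if metric != "log2_ratio":
        raise InputError(f"unknown metric {metric!r}")
    values = expr.to_numpy(dtype=float)
    if values.min() <= 0:
        values = values + abs(values.min()) + 1.0
    shifted = pd.DataFrame(values, index=expr.index, columns=expr.columns)
    mean_a = shifted[group_a].mean(axis=1)
    mean_b = shifted[group_b].mean(axis=1)
    scores = np.log2(mean_a / mean_b)
    order = sorted(expr.index, key=lambda g: (-scores[g], g))
    return RankedList(genes=list(order), metric=scores.loc[order].to_numpy())


def enrichment_score(
    ranked: RankedList, gene_set: set[str] | frozenset[str], weight_p: float = 1.0
) -> tuple[float, np.ndarray, list[str]]:
    """Weighted KS enrichment score for one gene set.

    Returns (ES, running profile of length N+1 starting and ending at 0,
    leading-edge genes). ES is the running-sum value of maximum
    magnitude, signed.
    """
    members = set(gene_set)
    hit = np.array([g in members for g in ranked.genes])
    n = len(ranked.genes)
    n_hit = int(hit.sum())
    if n_hit == 0:
        raise InputError("no overlap between gene set and ranked list")
    if n_hit == n:
        # no misses: the profile climbs to 1 and the set is maximally enriched
        w = np.abs(ranked.metric) ** weight_p
        if w.sum() == 0:
            w = np.ones(n)
        profile = np.concatenate([[0.0], np.cumsum(w / w.sum())])
        profile[-1] = 1.0
        return 1.0, profile, list(ranked.genes)

    w = np.where(hit, np.abs(ranked.metric) ** weight_p, 0.0)
    total = w.sum()
    if total == 0:  # all hit metrics are exactly zero: fall back to equal steps
        w = hit.astype(float)
        total = w.sum()
    steps = np.where(hit, w / total, -1.0 / (n - n_hit))
    running = np.concatenate([[0.0], np.cumsum(steps)])
    running[-1] = 0.0  # exact by construction; pin down float residue
    i_max = int(np.argmax(np.abs(running)))
    es = float(running[i_max])
    if es >= 0:
        leading = [g for g, h in zip(ranked.genes[:i_max], hit[:i_max]) if h]
    else:
        leading = [g for g, h in zip(ranked.genes[i_max - 1:], hit[i_max - 1:]) if h]
    return es, running, leading


def _permuted_es(
    ranked: RankedList,
    set_size: int,
    n_perm: int,
    weight_p: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """ES values for random same-size gene sets (gene-label permutation)."""
    n = len(ranked.genes)
    absw = np.abs(ranked.metric) ** weight_p
    out = np.empty(n_perm)
    miss_step = -1.0 / (n - set_size) if set_size < n else 0.0
    for p in range(n_perm):
        pos = rng.choice(n, size=set_size, replace=False)
        hit = np.zeros(n, dtype=bool)
        hit[pos] = True
        w = np.where(hit, absw, 0.0)
        total = w.sum()
        if total == 0:
            w = hit.astype(float)
            total = float(set_size)
        steps = np.where(hit, w / total, miss_step)
        running = np.cumsum(steps)
        out[p] = running[np.argmax(np.abs(running))]
    return out


def normalize_and_test(
    ranked: RankedList,
    gene_set: set[str] | frozenset[str],
    n_perm: int = 1000,
    seed: int | None = None,
    weight_p: float = 1.0,
) -> GseaResult:
    """Permutation normalization and significance for one gene set.

    NES = ES / mean(|same-sign permuted ES|); the nominal p-value is the
    fraction of same-sign permuted ES with |ES_perm| >= |ES|. The FDR q
    compares the observed NES against the distribution of sign-matched
    permuted NES values (each permuted ES normalized by the mean of its
    own sign class). Deterministic given the seed.
    """
    if n_perm < 100:
        raise InputError("n_perm must be >= 100")
    rng = np.random.default_rng(seed)
    overlap = set(gene_set) & set(ranked.genes)
    es, profile, leading = enrichment_score(ranked, overlap, weight_p)
    perm = _permuted_es(ranked, len(overlap), n_perm, weight_p, rng)

    same_sign = perm[np.sign(perm) == np.sign(es)] if es != 0 else perm
    if len(same_sign) == 0:
        warnings.warn("no same-sign permuted ES; q reported as 0", stacklevel=2)
        return GseaResult(es, float("inf") * np.sign(es), 0.0, 0.0, profile, leading)
    denom = np.abs(same_sign).mean()
    nes = float(es / denom)
    nominal_p = float(np.mean(np.abs(same_sign) >= abs(es)))

    # normalize every permuted ES by its own sign-class mean to get a
    # permuted NES distribution, then compare tails
    pos = perm[perm > 0]
    neg = perm[perm < 0]
    nes_perm = np.concatenate(
        [
            pos / pos.mean() if len(pos) else np.empty(0),
            neg / abs(neg).mean() if len(neg) else np.empty(0),
        ]
    )
    tail = nes_perm[np.sign(nes_perm) == np.sign(nes)]
    if len(tail) == 0:
        fdr_q = 0.0
    else:
        fdr_q = float(min(1.0, np.mean(np.abs(tail) >= abs(nes)) / (len(tail) / len(nes_perm))))
    return GseaResult(es, nes, nominal_p, fdr_q, profile, leading)
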