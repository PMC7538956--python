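"""Annotation enrichment and upstream-regulator activation scoring.

Implements the right-tailed Fisher (hypergeometric) enrichment test, the
direction-aware activation z-score for signed regulator->target
relations, ranking of candidate upstream regulators of a co-expression
module by summed activation z-scores over linked annotation terms, the
rank-deviation combined score used to order enriched terms, and
promoter-window calling of direct targets from binding peaks.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom, rankdata

from .coexpnet import ModuleAssignment
from .errors import InputError

__all__ = [
    "GeneSet",
    "EnrichmentRecord",
    "fisher_enrichment",
    "activation_zscore",
    "rank_upstream_regulators",
    "combined_score",
    "combined_score_table",
    "promoter_peak_targets",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise InputError(f"gene set {self.name!r} has no members")


@dataclass
class EnrichmentRecord:
    term: str
    overlap: int
    fisher_p: float
    activation_z: float = float("nan")
    combined_score: float = float("nan")


def fisher_enrichment(
    query: Iterable[str], term: GeneSet | set[str], universe: Iterable[str]
) -> EnrichmentRecord:
    """Right-tailed Fisher's exact test for query/term overlap.

    The p-value is the upper-tail hypergeometric probability of drawing
    the observed-or-greater overlap when ``|query|`` genes are sampled
    from the universe without replacement. The term is intersected with
    the universe before testing.
    """
    query = set(query)
    universe = set(universe)
    if not universe:
        raise InputError("empty universe")
    if not query:
        raise InputError("empty query")
    if not query <= universe:
        raise InputError("query must be a subset of the universe")
    if isinstance(term, GeneSet):
        name, members = term.name, set(term.members)
    else:
        name, members = "term", set(term)
    members &= universe
    k = len(query & members)
    M, K, n = len(universe), len(members), len(query)
    p = float(hypergeom.sf(k - 1, M, K, n)) if K else 1.0
    return EnrichmentRecord(term=name, overlap=k, fisher_p=min(p, 1.0))


def activation_zscore(
    observed_direction: Mapping[str, int],
    expected_sign: Mapping[str, int],
    weights: Mapping[str, float] | None = None,
) -> float:
    """Direction-aware activation z-score over regulator targets.

    ``z = sum_i w_i x_i / sqrt(sum_i w_i^2)`` where ``x_i = +1`` when the
    observed regulation direction of target i matches the direction
    expected under regulator activation and ``-1`` otherwise. Unit
    weights with N consistent targets give ``z = sqrt(N)``.
    """
    targets = [t for t in observed_direction if t in expected_sign]
    if weights is None:
        weights = {t: 1.0 for t in targets}
    w = np.array([float(weights.get(t, 0.0)) for t in targets])
    if np.any(w < 0):
        raise InputError("weights must be >= 0")
    keep = w > 0
    if not np.any(keep):
        raise InputError("no target with nonzero weight")
    x = np.array(
        [
            1.0 if np.sign(observed_direction[t]) == np.sign(expected_sign[t]) else -1.0
            for t in targets
        ]
    )
    w, x = w[keep], x[keep]
    return float(np.sum(w * x) / np.sqrt(np.sum(w * w)))


def rank_upstream_regulators(
    assignment: ModuleAssignment,
    module_id: int,
    network: pd.DataFrame,
    annotations: Sequence[tuple[str, set[str]]],
    universe: Iterable[str] | None = None,
    min_targets: int = 3,
) -> pd.DataFrame:
    """Rank candidate upstream regulators of one module.

    For each regulator in the signed network (columns regulator, target,
    sign) with at least ``min_targets`` targets inside the module:

    * a Fisher enrichment p of its target set against the module genes,
    * a module-level activation z-score using |kME| as weights, the kME
      sign as each gene's observed regulation direction, and the edge
      sign as the direction expected under activation,
    * one activation z-score per annotation term over the regulator's
      in-module targets inside that term,
    * a summary score = sum of the per-annotation activation z-scores
      (the color scale of the regulator network view).

    Regulators are ranked by summary score (descending), ties broken by
    Fisher p then lexical regulator ID.
    """
    if assignment.membership is None:
        raise InputError("assignment lacks kME membership; run eigengene step first")
    if {"regulator", "target", "sign"} - set(network.columns):
        raise InputError("network needs columns regulator, target, sign")
    if network.duplicated(["regulator", "target"]).any():
        raise InputError("duplicate (regulator, target) edges")
    if not set(network["sign"]) <= {-1, 1}:
        raise InputError("edge signs must be +/-1")

    module_genes = set(assignment.module_genes(module_id))
    if universe is None:
        universe = set(assignment.labels.index)
    universe = set(universe)
    kme = assignment.membership

    rows = []
    for reg, edges in network.groupby("regulator"):
        targets = dict(zip(edges["target"], edges["sign"]))
        in_module = {t: s for t, s in targets.items() if t in module_genes}
        if len(in_module) < min_targets:
            log.info("regulator %s excluded: %d in-module targets", reg, len(in_module))
            continue
        observed = {t: int(np.sign(kme[t])) for t in in_module if kme[t] != 0}
        weights = {t: abs(float(kme[t])) for t in observed}
        fisher_p = fisher_enrichment(
            set(targets) & universe, module_genes, universe
        ).fisher_p
        module_z = activation_zscore(observed, in_module, weights)
        summary = 0.0
        n_linked = 0
        for _, members in annotations:
            ann_targets = {t: in_module[t] for t in observed if t in members}
            if not ann_targets:
                continue
            obs = {t: observed[t] for t in ann_targets}
            wts = {t: weights[t] for t in ann_targets}
            summary += activation_zscore(obs, ann_targets, wts)
            n_linked += 1
        rows.append(
            {
                "regulator": reg,
                "n_targets": len(in_module),
                "fisher_p": fisher_p,
                "module_z": module_z,
                "n_linked_annotations": n_linked,
                "summary_score": summary,
            }
        )
    if not rows:
        raise InputError("no regulator has enough in-module targets")
    out = pd.DataFrame(rows).sort_values(
        ["summary_score", "fisher_p", "regulator"],
        ascending=[False, True, True],
        kind="stable",
    )
    out["rank"] = np.arange(1, len(out) + 1)
    return out.set_index("regulator")


def combined_score(fisher_p: float, rank_z: float) -> float:
    """Combined enrichment score ``c = ln(P) * z``.

    ``P`` is the Fisher exact p-value and ``z`` the deviation of the
    term's p-value rank from its expected rank under random queries
    (see :func:`combined_score_table`). ``c`` is reported signed; a
    strongly enriched term (small P, positive z) is strongly negative.
    """
    if not 0 <= fisher_p <= 1:
        raise InputError("fisher_p must lie in [0, 1]")
    if fisher_p == 0:
        warnings.warn("fisher_p == 0 clamped to smallest positive float", stacklevel=2)
        fisher_p = np.finfo(float).tiny
    return float(np.log(fisher_p) * rank_z)


def combined_score_table(
    query: Iterable[str],
    terms: Sequence[GeneSet],
    universe: Iterable[str],
    n_null: int = 100,
    seed: int | None = None,
) -> pd.DataFrame:
    """Fisher p, rank-deviation z, and combined score for a term collection.

    Terms are ranked by Fisher p for the actual query; the same ranking
    is recomputed for ``n_null`` seeded random query lists of the same
    size, and each term's z is its mean null rank minus its observed
    rank, divided by the null rank standard deviation (positive z = the
    term ranks better than expected by chance).
    """
    query = sorted(set(query))
    universe = sorted(set(universe))
    rng = np.random.default_rng(seed)

    def ranks_for(q: Sequence[str]) -> np.ndarray:
        ps = np.array(
            [fisher_enrichment(q, t, universe).fisher_p for t in terms]
        )
        return rankdata(ps, method="average")

    obs_p = np.array([fisher_enrichment(query, t, universe).fisher_p for t in terms])
    obs_rank = rankdata(obs_p, method="average")
    null_ranks = np.empty((n_null, len(terms)))
    for r in range(n_null):
        random_query = rng.choice(universe, size=len(query), replace=False)
        null_ranks[r] = ranks_for(list(random_query))
    mu = null_ranks.mean(axis=0)
    sd = null_ranks.std(axis=0, ddof=1)
    sd[sd == 0] = np.nan
    z = (mu - obs_rank) / sd
    c = np.array(
        [combined_score(p, 0.0 if np.isnan(zz) else zz) for p, zz in zip(obs_p, z)]
    )
    return pd.DataFrame(
        {
            "term": [t.name for t in terms],
            "fisher_p": obs_p,
            "rank_z": z,
            "combined_score": c,
        }
    ).set_index("term")


_STRANDS = {"+", "-"}


def promoter_peak_targets(
    peaks: pd.DataFrame,
    tss: pd.DataFrame,
    de_genes: Iterable[str],
    upstream: int = 5000,
    downstream: int = 1000,
) -> list[str]:
    """Direct-target calling from binding peaks near transcription starts.

    A gene is a direct target iff at least one peak (BED convention:
    0-based, half-open [start, end)) overlaps its strand-aware promoter
    window [TSS - upstream, TSS + downstream] (mirrored on the - strand)
    and the gene is in ``de_genes``. ``tss`` needs columns gene, chrom,
    pos, strand.
    """
    if {"chrom", "start", "end"} - set(peaks.columns):
        raise InputError("peaks need columns chrom, start, end")
    if {"gene", "chrom", "pos", "strand"} - set(tss.columns):
        raise InputError("tss needs columns gene, chrom, pos, strand")
    bad = set(tss["strand"]) - _STRANDS
    if bad:
        raise InputError(f"unknown strand symbol(s): {sorted(bad)}")
    de_genes = set(de_genes)

    hits = []
    by_chrom = {c: g for c, g in peaks.groupby("chrom")}
    for row in tss.itertuples(index=False):
        if row.gene not in de_genes:
            continue
        if row.strand == "+":
            w0, w1 = row.pos - upstream, row.pos + downstream
        else:
            w0, w1 = row.pos - downstream, row.pos + upstream
        w0 = max(w0, 0)
        chrom_peaks = by_chrom.get(row.chrom)
        if chrom_peaks is None:
            continue
        # peak [start, end) overlaps closed window [w0, w1]
        overlap = (chrom_peaks["start"] <= w1) & (chrom_peaks["end"] - 1 >= w0)
        if overlap.any():
            hits.append(row.gene)
    return sorted(set(hits))
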