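"""Weighted gene co-expression network construction and module detection.

The network is built from pairwise Pearson correlations raised to a soft
threshold power, summarized by the topological overlap matrix (TOM), and
clustered by average-linkage hierarchical clustering on 1 - TOM with a
static tree cut. Modules are summarized by their eigengene (first
principal component) and per-gene module membership kME.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform

from .errors import ConfigurationError, InputError

__all__ = [
    "SoftThresholdReport",
    "ModuleAssignment",
    "pick_soft_threshold",
    "adjacency_matrix",
    "topological_overlap",
    "detect_modules",
    "module_eigengene_and_membership",
    "hub_network",
]

log = logging.getLogger(__name__)


@dataclass
class SoftThresholdReport:
    candidate_powers: list[int]
    scale_free_fit_r2: list[float]      # NaN where the fit is degenerate
    mean_connectivity: list[float]
    chosen_power: int
    degenerate: bool = False


@dataclass
class ModuleAssignment:
    """Gene -> module labels with eigengenes and membership (kME).

    Label 0 marks unassigned genes. ``eigengenes`` is a module x sample
    DataFrame whose rows have unit Euclidean norm; ``membership`` maps each
    assigned gene to its correlation with its own module's eigengene.
    """

    labels: pd.Series
    eigengenes: pd.DataFrame | None = None
    membership: pd.Series | None = None

    def module_genes(self, module_id: int) -> list[str]:
        return list(self.labels.index[self.labels == module_id])


def _validate_expression(expr: pd.DataFrame) -> pd.DataFrame:
    if expr.index.duplicated().any():
        dupes = sorted(set(expr.index[expr.index.duplicated()]))
        raise InputError(f"duplicate gene IDs: {dupes}")
    if expr.isna().any().any():
        n_bad = int(expr.isna().any(axis=1).sum())
        log.warning("dropping %d genes with missing values", n_bad)
        expr = expr.dropna(axis=0)
    variances = expr.var(axis=1, ddof=0)
    zero_var = variances[variances == 0.0]
    if len(zero_var):
        log.warning("dropping %d zero-variance genes", len(zero_var))
        expr = expr.drop(index=zero_var.index)
    if expr.empty:
        raise InputError("no variable genes")
    return expr


def adjacency_matrix(
    expr: pd.DataFrame, power: int, signed: bool = False
) -> pd.DataFrame:
    """Soft-thresholded co-expression adjacency.

    Unsigned mode: ``a_ij = |cor(x_i, x_j)|**power``; signed mode:
    ``a_ij = ((1 + cor)/2)**power``. The diagonal is set to 0 (self-edges
    are excluded from connectivity; the TOM formula is diagonal-free).
    """
    if power < 1:
        raise ConfigurationError("power must be >= 1")
    variances = expr.var(axis=1, ddof=0)
    zero_var = list(variances.index[variances == 0.0])
    if zero_var:
        raise InputError(f"zero-variance genes: {zero_var}")
    cor = np.corrcoef(expr.to_numpy(dtype=float))
    cor = np.clip(cor, -1.0, 1.0)
    adj = ((1.0 + cor) / 2.0) ** power if signed else np.abs(cor) ** power
    np.fill_diagonal(adj, 0.0)
    return pd.DataFrame(adj, index=expr.index, columns=expr.index)


def pick_soft_threshold(
    expr: pd.DataFrame,
    powers: list[int] | None = None,
    target_r2: float = 0.8,
    n_bins: int = 10,
) -> SoftThresholdReport:
    """Scale-free topology criterion for the soft threshold power.

    For each candidate power the connectivities ``k_i = sum_j a_ij`` are
    binned on a log scale and log10(frequency) is regressed on
    log10(mean k); the report records the R^2 of that fit. The chosen
    power is the smallest candidate whose R^2 reaches ``target_r2``, else
    the R^2-maximizing candidate. If every fit is degenerate (all k equal,
    as in noiseless rank-1 data) the smallest candidate is returned with
    the ``degenerate`` flag set.
    """
    if expr.shape[1] < 3:
        raise InputError("need >= 3 samples")
    if powers is None:
        powers = list(range(1, 21))
    if any(p < 1 for p in powers):
        raise ConfigurationError("powers must be positive")
    expr = _validate_expression(expr)

    r2s: list[float] = []
    mean_ks: list[float] = []
    for p in powers:
        adj = adjacency_matrix(expr, p).to_numpy()
        k = adj.sum(axis=1)
        mean_ks.append(float(k.mean()))
        r2s.append(_scale_free_r2(k, n_bins))

    r2_arr = np.asarray(r2s, dtype=float)
    degenerate = bool(np.all(np.isnan(r2_arr)))
    if degenerate:
        chosen = int(min(powers))
    else:
        ok = [p for p, r in zip(powers, r2_arr) if not np.isnan(r) and r >= target_r2]
        if ok:
            chosen = int(min(ok))
        else:
            chosen = int(powers[int(np.nanargmax(r2_arr))])
    return SoftThresholdReport(
        candidate_powers=list(powers),
        scale_free_fit_r2=[float(r) for r in r2_arr],
        mean_connectivity=mean_ks,
        chosen_power=chosen,
        degenerate=degenerate,
    )


def _scale_free_r2(k: np.ndarray, n_bins: int) -> float:
    k = k[k > 0]
    if len(k) < n_bins or np.isclose(k.max(), k.min()):
        return float("nan")
    edges = np.linspace(k.min(), k.max() * (1 + 1e-12), n_bins + 1)
    which = np.digitize(k, edges) - 1
    log_k, log_f = [], []
    for b in range(n_bins):
        members = k[which == b]
        if len(members) == 0:
            continue
        log_k.append(np.log10(members.mean()))
        log_f.append(np.log10(len(members) / len(k)))
    if len(log_k) < 3:
        return float("nan")
    x, y = np.asarray(log_k), np.asarray(log_f)
    if np.isclose(x.var(), 0.0):
        return float("nan")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def topological_overlap(adjacency: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap matrix.

    ``TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)``
    with ``k_i = sum_j a_ij``; the diagonal is set to 1 by convention.
    """
    A = np.asarray(adjacency, dtype=float).copy()
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise InputError("adjacency must be square")
    if np.max(np.abs(A - A.T)) > 1e-10:
        raise InputError("adjacency not symmetric within 1e-10")
    np.fill_diagonal(A, 0.0)
    if A.min() < -1e-12 or A.max() > 1.0 + 1e-12:
        raise InputError("adjacency values must lie in [0, 1]")
    k = A.sum(axis=1)
    shared = A @ A
    denom = np.minimum.outer(k, k) + 1.0 - A
    tom = (shared + A) / denom
    np.fill_diagonal(tom, 1.0)
    tom = np.clip((tom + tom.T) / 2.0, 0.0, 1.0)
    idx = getattr(adjacency, "index", pd.RangeIndex(A.shape[0]))
    return pd.DataFrame(tom, index=idx, columns=idx)


def detect_modules(
    tom: pd.DataFrame, min_module_size: int = 30, cut_height: float = 0.95
) -> ModuleAssignment:
    """Average-linkage clustering on 1 - TOM with a static tree cut.

    Clusters smaller than ``min_module_size`` are assigned label 0;
    surviving clusters are relabeled 1, 2, ... in decreasing size order
    (ties broken by first gene appearance, keeping labels deterministic).
    """
    if min_module_size < 2:
        raise ConfigurationError("min_module_size must be >= 2")
    dissim = 1.0 - np.asarray(tom, dtype=float)
    np.fill_diagonal(dissim, 0.0)
    condensed = squareform(dissim, checks=False)
    link = average(condensed)
    raw = fcluster(link, t=cut_height, criterion="distance")

    sizes = pd.Series(raw).value_counts()
    keep = sizes[sizes >= min_module_size]
    # decreasing size, ties by smallest original cluster id
    order = sorted(keep.index, key=lambda c: (-keep[c], c))
    relabel = {c: i + 1 for i, c in enumerate(order)}
    labels = np.array([relabel.get(c, 0) for c in raw], dtype=int)
    return ModuleAssignment(labels=pd.Series(labels, index=tom.index, name="module"))


def module_eigengene_and_membership(
    expr: pd.DataFrame, assignment: ModuleAssignment
) -> ModuleAssignment:
    """Complete an assignment with eigengenes and kME membership.

    The eigengene is the first right-singular vector of the module's
    standardized (per-gene z-scored) expression, sign-oriented to
    correlate positively with the module's mean standardized expression
    profile, and stored with unit norm. ``kME_i`` is the Pearson
    correlation of gene i with its module's eigengene.
    """
    labels = assignment.labels
    modules = sorted(set(labels) - {0})
    if not modules:
        raise InputError("assignment has no modules")
    eigengenes = {}
    kme = pd.Series(np.nan, index=labels.index, dtype=float)
    for mod in modules:
        genes = labels.index[labels == mod]
        if len(genes) < 2:
            raise InputError(f"module {mod} has fewer than 2 genes")
        X = expr.loc[genes].to_numpy(dtype=float)
        X = (X - X.mean(axis=1, keepdims=True)) / X.std(axis=1, keepdims=True)
        # first right-singular vector = per-sample PC scores direction
        _, _, vt = np.linalg.svd(X, full_matrices=False)
        eg = vt[0]
        mean_profile = X.mean(axis=0)
        if np.corrcoef(eg, mean_profile)[0, 1] < 0:
            eg = -eg
        eigengenes[mod] = eg
        for g in genes:
            kme[g] = float(np.corrcoef(expr.loc[g].to_numpy(dtype=float), eg)[0, 1])
    eg_df = pd.DataFrame(eigengenes, index=expr.columns).T
    eg_df.index.name = "module"
    return ModuleAssignment(labels=labels, eigengenes=eg_df, membership=kme)


def hub_network(
    tom: pd.DataFrame,
    assignment: ModuleAssignment,
    module_id: int,
    top_n: int = 59,
    tom_threshold: float = 0.13,
) -> tuple[pd.DataFrame, pd.Series]:
    """Hub sub-network of a module's most connected genes.

    Restricts to the ``top_n`` genes by intramodular connectivity (TOM
    row-sum within the module), keeps edges with TOM strictly above
    ``tom_threshold``, and ranks genes by their retained-edge degree
    (hub genes sit at the network center).
    """
    genes = assignment.module_genes(module_id)
    if not genes:
        raise InputError(f"module {module_id} does not exist")
    if top_n > len(genes):
        warnings.warn(
            f"top_n={top_n} exceeds module size {len(genes)}; clamping",
            stacklevel=2,
        )
        top_n = len(genes)
    sub = tom.loc[genes, genes].to_numpy(dtype=float).copy()
    np.fill_diagonal(sub, 0.0)
    connectivity = pd.Series(sub.sum(axis=1), index=genes)
    top = connectivity.sort_values(ascending=False, kind="stable").index[:top_n]
    T = tom.loc[top, top]
    edges = []
    for i, gi in enumerate(top):
        for gj in top[i + 1:]:
            w = float(T.loc[gi, gj])
            if w > tom_threshold:
                edges.append((gi, gj, w))
    edge_df = pd.DataFrame(edges, columns=["gene_a", "gene_b", "tom"])
    degree = pd.Series(0, index=top, dtype=int)
    for ga, gb, _ in edges:
        degree[ga] += 1
        degree[gb] += 1
    ranking = degree.sort_values(ascending=False, kind="stable")
    return edge_df, ranking
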