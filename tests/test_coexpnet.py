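"""Co-expression network construction against brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from malignet import coexpnet, synthio
from malignet.errors import ConfigurationError, InputError

from conftest import random_correlation_data


def brute_force_tom(adj: np.ndarray) -> np.ndarray:
    """Triple-loop evaluation of the topological overlap formula."""
    a = adj.copy()
    np.fill_diagonal(a, 0.0)
    n = a.shape[0]
    k = a.sum(axis=1)
    tom = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = sum(a[i, u] * a[u, j] for u in range(n))
            tom[i, j] = (shared + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
    return tom


class TestAdjacency:
    def test_matches_bruteforce_powered_correlation(self):
        expr = random_correlation_data(10, 25, seed=0)
        for power in (1, 3, 6):
            adj = coexpnet.adjacency_matrix(expr, power).to_numpy()
            cor = np.corrcoef(expr.values)
            expected = np.abs(cor) ** power
            np.fill_diagonal(expected, 0.0)
            assert np.max(np.abs(adj - expected)) < 1e-12

    def test_perfect_correlation_gives_unit_edge(self):
        x = np.arange(10.0)
        expr = pd.DataFrame([x, 2 * x + 3], index=["a", "b"])
        for power in (1, 5):
            adj = coexpnet.adjacency_matrix(expr, power)
            assert adj.loc["a", "b"] == pytest.approx(1.0)

    def test_half_correlation_squared(self):
        # construct an exact r = 0.5 pair, then a = 0.5^2 = 0.25
        rng = np.random.default_rng(1)
        z1 = rng.standard_normal(50)
        z2 = rng.standard_normal(50)
        z1 = (z1 - z1.mean()) / z1.std()
        z2 -= z2 @ z1 / 50 * z1
        z2 = (z2 - z2.mean()) / z2.std()
        expr = pd.DataFrame([z1, 0.5 * z1 + np.sqrt(0.75) * z2], index=["a", "b"])
        adj = coexpnet.adjacency_matrix(expr, 2)
        assert adj.loc["a", "b"] == pytest.approx(0.25, abs=1e-10)

    def test_signed_mode(self):
        x = np.arange(8.0)
        expr = pd.DataFrame([x, -x], index=["a", "b"])
        adj = coexpnet.adjacency_matrix(expr, 3, signed=True)
        assert adj.loc["a", "b"] == pytest.approx(0.0, abs=1e-12)

    def test_zero_variance_gene_rejected_by_name(self):
        expr = pd.DataFrame([[1, 2, 3], [5, 5, 5]], index=["ok", "flat"], dtype=float)
        with pytest.raises(InputError, match="flat"):
            coexpnet.adjacency_matrix(expr, 2)


class TestTopologicalOverlap:
    def test_complete_triangle_fully_overlapping(self):
        adj = pd.DataFrame(np.ones((3, 3)) - np.eye(3))
        tom = coexpnet.topological_overlap(adj).to_numpy()
        off = tom[~np.eye(3, dtype=bool)]
        assert np.allclose(off, 1.0)

    def test_path_graph_hand_values(self):
        # 1-2-3 path: TOM_12 = 1, TOM_13 = 0.5
        adj = pd.DataFrame(
            [[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=float
        )
        tom = coexpnet.topological_overlap(adj).to_numpy()
        assert tom[0, 1] == pytest.approx(1.0)
        assert tom[0, 2] == pytest.approx(0.5)

    def test_matches_triple_loop_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(5):
            a = rng.uniform(0, 1, (10, 10))
            a = (a + a.T) / 2
            np.fill_diagonal(a, 0.0)
            tom = coexpnet.topological_overlap(pd.DataFrame(a)).to_numpy()
            assert np.max(np.abs(tom - brute_force_tom(a))) < 1e-12

    def test_bounded_and_symmetric(self):
        rng = np.random.default_rng(6)
        a = rng.uniform(0, 1, (15, 15))
        a = (a + a.T) / 2
        tom = coexpnet.topological_overlap(pd.DataFrame(a)).to_numpy()
        assert (tom >= 0).all() and (tom <= 1).all()
        assert np.allclose(tom, tom.T)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(8)
        a = rng.uniform(0, 1, (8, 8))
        a = (a + a.T) / 2
        perm = rng.permutation(8)
        t1 = coexpnet.topological_overlap(pd.DataFrame(a)).to_numpy()
        t2 = coexpnet.topological_overlap(pd.DataFrame(a[np.ix_(perm, perm)])).to_numpy()
        assert np.allclose(t1[np.ix_(perm, perm)], t2)

    def test_asymmetric_input_rejected(self):
        a = np.zeros((3, 3))
        a[0, 1] = 0.5
        with pytest.raises(InputError, match="symmetric"):
            coexpnet.topological_overlap(pd.DataFrame(a))


class TestSoftThreshold:
    def test_degenerate_rank_one_flagged(self):
        cfg = synthio.SimulationConfig(
            n_samples=20, n_genes=15, module_sizes=(15,), noise_sd=0.0
        )
        expr, _ = synthio.generate_cohort(cfg)
        report = coexpnet.pick_soft_threshold(expr, [2, 4, 6], 0.8)
        assert report.degenerate
        assert report.chosen_power == 2

    def test_deterministic(self, default_cohort):
        _, expr, _ = default_cohort
        r1 = coexpnet.pick_soft_threshold(expr, [2, 4, 6], 0.8)
        r2 = coexpnet.pick_soft_threshold(expr, [2, 4, 6], 0.8)
        assert r1.chosen_power == r2.chosen_power
        assert r1.scale_free_fit_r2 == r2.scale_free_fit_r2

    def test_scale_free_data_reaches_target_fit(self):
        # one-factor model with heavy-tailed communalities: few hub genes,
        # many weakly connected ones
        rng = np.random.default_rng(5)
        n_genes, n_samples = 400, 200
        h = 0.05 + 0.9 * rng.uniform(0, 1, n_genes) ** 4
        f = rng.standard_normal(n_samples)
        X = np.sqrt(h)[:, None] * f + np.sqrt(1 - h)[:, None] * rng.standard_normal(
            (n_genes, n_samples)
        )
        expr = pd.DataFrame(X, index=[f"g{i}" for i in range(n_genes)])
        report = coexpnet.pick_soft_threshold(expr, list(range(1, 13)), 0.8)
        chosen_idx = report.candidate_powers.index(report.chosen_power)
        assert report.scale_free_fit_r2[chosen_idx] >= 0.8


class TestModuleDetection:
    def test_noiseless_blocks_recovered_exactly(self):
        cfg = synthio.SimulationConfig(
            n_samples=30, n_genes=40, module_sizes=(20, 20), noise_sd=1e-6
        )
        expr, truth = synthio.generate_cohort(cfg)
        adj = coexpnet.adjacency_matrix(expr, 6)
        tom = coexpnet.topological_overlap(adj)
        assignment = coexpnet.detect_modules(tom, min_module_size=5)
        assert adjusted_rand_score(truth.module_labels, assignment.labels) == 1.0

    def test_default_cohort_recovery(self, default_cohort, default_assignment):
        _, _, truth = default_cohort
        ari = adjusted_rand_score(truth.module_labels, default_assignment.labels)
        assert ari >= 0.9

    def test_pure_noise_mostly_unassigned(self):
        cfg = synthio.SimulationConfig(
            n_samples=40, n_genes=300, module_sizes=(), seed=2
        )
        expr, _ = synthio.generate_cohort(cfg)
        adj = coexpnet.adjacency_matrix(expr, 6)
        tom = coexpnet.topological_overlap(adj)
        assignment = coexpnet.detect_modules(tom, min_module_size=30)
        assert (assignment.labels == 0).mean() >= 0.9

    def test_min_module_size_validated(self, default_tom):
        with pytest.raises(ConfigurationError):
            coexpnet.detect_modules(default_tom, min_module_size=1)

    def test_sample_order_invariance(self, default_cohort):
        _, expr, _ = default_cohort
        rng = np.random.default_rng(0)
        shuffled = expr.iloc[:, rng.permutation(expr.shape[1])]
        a1 = coexpnet.adjacency_matrix(expr, 6)
        a2 = coexpnet.adjacency_matrix(shuffled, 6)
        l1 = coexpnet.detect_modules(coexpnet.topological_overlap(a1)).labels
        l2 = coexpnet.detect_modules(coexpnet.topological_overlap(a2)).labels
        assert (l1 == l2).all()


class TestEigengene:
    def test_rank_one_module_unit_membership(self):
        cfg = synthio.SimulationConfig(
            n_samples=25, n_genes=10, module_sizes=(10,), noise_sd=0.0
        )
        expr, truth = synthio.generate_cohort(cfg)
        assignment = coexpnet.ModuleAssignment(labels=truth.module_labels)
        completed = coexpnet.module_eigengene_and_membership(expr, assignment)
        assert np.allclose(np.abs(completed.membership.dropna()), 1.0)

    def test_sign_flip_symmetry(self, default_cohort, truth_assignment):
        _, expr, truth = default_cohort
        flipped = expr.copy()
        genes1 = truth.module_labels.index[truth.module_labels == 1]
        flipped.loc[genes1] = -flipped.loc[genes1]
        assignment = coexpnet.ModuleAssignment(labels=truth.module_labels)
        completed = coexpnet.module_eigengene_and_membership(flipped, assignment)
        eg_orig = truth_assignment.eigengenes.loc[1]
        eg_flip = completed.eigengenes.loc[1]
        assert np.allclose(eg_flip, -eg_orig, atol=1e-8)
        kme_orig = truth_assignment.membership[genes1].abs()
        kme_flip = completed.membership[genes1].abs()
        assert np.allclose(kme_orig, kme_flip, atol=1e-8)

    def test_eigengene_rows_unit_norm(self, truth_assignment):
        norms = np.linalg.norm(truth_assignment.eigengenes.to_numpy(), axis=1)
        assert np.allclose(norms, 1.0)

    def test_eigengene_tracks_planted_activity(self, default_cohort, truth_assignment):
        _, _, truth = default_cohort
        eg = truth_assignment.eigengenes.loc[1]
        assert abs(np.corrcoef(eg, truth.activity)[0, 1]) >= 0.95


class TestHubNetwork:
    def _toy(self):
        tom = np.array(
            [
                [1.0, 0.14, 0.13, 0.12],
                [0.14, 1.0, 0.12, 0.12],
                [0.13, 0.12, 1.0, 0.12],
                [0.12, 0.12, 0.12, 1.0],
            ]
        )
        genes = ["a", "b", "c", "d"]
        tom_df = pd.DataFrame(tom, index=genes, columns=genes)
        labels = pd.Series([1, 1, 1, 1], index=genes)
        return tom_df, coexpnet.ModuleAssignment(labels=labels)

    def test_strict_threshold_boundary(self):
        tom_df, assignment = self._toy()
        edges, _ = coexpnet.hub_network(tom_df, assignment, 1, top_n=4)
        assert len(edges) == 1
        assert set(edges.iloc[0][["gene_a", "gene_b"]]) == {"a", "b"}

    def test_star_center_ranked_first(self):
        n = 6
        tom = np.full((n, n), 0.01)
        tom[0, 1:] = tom[1:, 0] = 0.5
        np.fill_diagonal(tom, 1.0)
        genes = [f"g{i}" for i in range(n)]
        tom_df = pd.DataFrame(tom, index=genes, columns=genes)
        assignment = coexpnet.ModuleAssignment(labels=pd.Series(1, index=genes))
        _, ranking = coexpnet.hub_network(tom_df, assignment, 1, top_n=n)
        assert ranking.index[0] == "g0"

    def test_edges_match_bruteforce_filter(self, default_tom, default_assignment):
        edges, _ = coexpnet.hub_network(
            default_tom, default_assignment, 1, top_n=20, tom_threshold=0.13
        )
        got = {frozenset((a, b)) for a, b in zip(edges["gene_a"], edges["gene_b"])}
        sub = default_tom.loc[edges["gene_a"].tolist() + edges["gene_b"].tolist()]
        # recompute from scratch: top-20 by intramodular connectivity
        genes = default_assignment.module_genes(1)
        block = default_tom.loc[genes, genes].to_numpy().copy()
        np.fill_diagonal(block, 0.0)
        top = pd.Series(block.sum(1), index=genes).nlargest(20).index
        expected = {
            frozenset((gi, gj))
            for i, gi in enumerate(top)
            for gj in top[i + 1:]
            if default_tom.loc[gi, gj] > 0.13
        }
        assert got == expected

    def test_top_n_clamped_with_warning(self):
        tom_df, assignment = self._toy()
        with pytest.warns(UserWarning, match="clamp"):
            coexpnet.hub_network(tom_df, assignment, 1, top_n=10)

    def test_missing_module_rejected(self):
        tom_df, assignment = self._toy()
        with pytest.raises(InputError):
            coexpnet.hub_network(tom_df, assignment, 7)
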