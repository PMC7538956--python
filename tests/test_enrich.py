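"""Enrichment statistics against exact enumeration oracles."""

import math

import numpy as np
import pandas as pd
import pytest

from malignet import coexpnet, enrich, synthio
from malignet.errors import InputError


def hypergeom_upper_tail(M: int, K: int, n: int, k: int) -> float:
    """Exact P(overlap >= k) by direct binomial-coefficient enumeration."""
    total = math.comb(M, n)
    return sum(
        math.comb(K, j) * math.comb(M - K, n - j)
        for j in range(k, min(K, n) + 1)
    ) / total


def make_sets(M: int, K: int, n: int, k: int):
    universe = [f"u{i}" for i in range(M)]
    term = set(universe[:K])
    query = set(universe[:k]) | set(universe[K:K + (n - k)])
    assert len(query) == n
    return query, term, universe


class TestFisher:
    def test_full_overlap_exact_value(self):
        # universe 10, query 5, term 5, overlap 5: p = 1/C(10,5) = 1/252
        query, term, universe = make_sets(10, 5, 5, 5)
        rec = enrich.fisher_enrichment(query, term, universe)
        assert rec.overlap == 5
        assert rec.fisher_p == pytest.approx(1 / 252, rel=1e-12)

    def test_disjoint_sets_no_enrichment(self):
        query, term, universe = make_sets(20, 8, 6, 0)
        rec = enrich.fisher_enrichment(query, term, universe)
        assert rec.fisher_p == pytest.approx(1.0)

    def test_matches_enumeration_for_small_universes(self):
        for M in (5, 9, 16, 23, 30):
            for K in range(1, M + 1, 3):
                for n in range(1, M + 1, 3):
                    for k in range(max(0, K + n - M), min(K, n) + 1):
                        query, term, universe = make_sets(M, K, n, k)
                        rec = enrich.fisher_enrichment(query, term, universe)
                        expected = hypergeom_upper_tail(M, K, n, k)
                        assert rec.fisher_p == pytest.approx(expected, abs=1e-12)

    def test_monotone_in_overlap(self):
        ps = []
        for k in range(0, 6):
            query, term, universe = make_sets(30, 10, 5, k)
            ps.append(enrich.fisher_enrichment(query, term, universe).fisher_p)
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_empty_inputs_rejected(self):
        with pytest.raises(InputError):
            enrich.fisher_enrichment(set(), {"a"}, {"a"})
        with pytest.raises(InputError):
            enrich.fisher_enrichment({"a"}, {"a"}, set())


class TestActivationZ:
    def test_all_consistent_unit_weights(self):
        obs = {t: 1 for t in "abcd"}
        assert enrich.activation_zscore(obs, obs) == pytest.approx(2.0)

    def test_balanced_targets_cancel(self):
        obs = {"a": 1, "b": 1, "c": -1, "d": -1}
        exp = {"a": 1, "b": 1, "c": 1, "d": 1}
        assert enrich.activation_zscore(obs, exp) == pytest.approx(0.0)

    def test_weighted_hand_value(self):
        obs = {"a": 1, "b": 1, "c": 1}
        w = {"a": 2.0, "b": 1.0, "c": 1.0}
        z = enrich.activation_zscore(obs, obs, w)
        assert z == pytest.approx(4 / math.sqrt(6), rel=1e-12)

    def test_antisymmetric_under_direction_flip(self):
        rng = np.random.default_rng(3)
        targets = [f"t{i}" for i in range(12)]
        obs = {t: int(s) for t, s in zip(targets, rng.choice([-1, 1], 12))}
        exp = {t: int(s) for t, s in zip(targets, rng.choice([-1, 1], 12))}
        w = {t: float(v) for t, v in zip(targets, rng.uniform(0.1, 2, 12))}
        z = enrich.activation_zscore(obs, exp, w)
        flipped = {t: -s for t, s in obs.items()}
        assert enrich.activation_zscore(flipped, exp, w) == pytest.approx(-z)

    def test_scale_invariant_weights(self):
        obs = {"a": 1, "b": -1, "c": 1}
        exp = {"a": 1, "b": 1, "c": 1}
        w = {"a": 0.5, "b": 1.0, "c": 2.0}
        w10 = {t: 10 * v for t, v in w.items()}
        assert enrich.activation_zscore(obs, exp, w) == pytest.approx(
            enrich.activation_zscore(obs, exp, w10)
        )

    def test_all_zero_weights_rejected(self):
        obs = {"a": 1}
        with pytest.raises(InputError):
            enrich.activation_zscore(obs, obs, {"a": 0.0})


class TestUpstreamRanking:
    def test_planted_regulator_outranks_shuffled_decoys(self, default_cohort, truth_assignment):
        cfg, _, truth = default_cohort
        network, annotations = synthio.generate_regulator_network(truth, cfg)
        table = enrich.rank_upstream_regulators(truth_assignment, 1, network, annotations)
        assert table.index[0] == "REG_TRUE"
        assert table.loc["REG_TRUE", "rank"] == 1

    def test_balanced_regulator_scores_zero(self, truth_assignment):
        genes = truth_assignment.labels.index[truth_assignment.labels == 1][:4]
        kme_signs = [int(np.sign(truth_assignment.membership[g])) for g in genes]
        # expected signs: two agree, two disagree, with equal |kME| weights
        # enforced by overriding membership on a copy
        assignment = coexpnet.ModuleAssignment(
            labels=truth_assignment.labels.copy(),
            eigengenes=truth_assignment.eigengenes,
            membership=truth_assignment.membership.copy(),
        )
        assignment.membership[genes] = [0.9 * s for s in kme_signs]
        edges = pd.DataFrame(
            {
                "regulator": "R",
                "target": genes,
                "sign": [kme_signs[0], kme_signs[1], -kme_signs[2], -kme_signs[3]],
            }
        )
        annotations = [("A", set(genes))]
        table = enrich.rank_upstream_regulators(assignment, 1, edges, annotations)
        assert table.loc["R", "summary_score"] == pytest.approx(0.0, abs=1e-12)

    def test_single_annotation_summary_equals_module_z(self, default_cohort, truth_assignment):
        cfg, _, truth = default_cohort
        network, _ = synthio.generate_regulator_network(truth, cfg, n_decoys=0)
        module_genes = set(truth.module_labels.index[truth.module_labels == 1])
        annotations = [("ALL", module_genes)]
        table = enrich.rank_upstream_regulators(truth_assignment, 1, network, annotations)
        assert table.loc["REG_TRUE", "summary_score"] == pytest.approx(
            table.loc["REG_TRUE", "module_z"]
        )

    def test_regulators_below_target_floor_excluded(self, truth_assignment):
        genes = list(truth_assignment.labels.index[truth_assignment.labels == 1][:5])
        edges = pd.DataFrame(
            {
                "regulator": ["few"] * 2 + ["enough"] * 5,
                "target": genes[:2] + genes,
                "sign": [1] * 7,
            }
        )
        table = enrich.rank_upstream_regulators(
            truth_assignment, 1, edges, [("A", set(genes))]
        )
        assert "few" not in table.index
        assert "enough" in table.index


class TestCombinedScore:
    def test_direct_product_natural_log(self):
        c = enrich.combined_score(math.exp(-4), 2.5)
        assert c == pytest.approx(-10.0, rel=1e-12)

    def test_zero_z_annihilates(self):
        assert enrich.combined_score(0.01, 0.0) == 0.0

    def test_zero_p_clamped_with_warning(self):
        with pytest.warns(UserWarning):
            c = enrich.combined_score(0.0, 1.0)
        assert np.isfinite(c)

    def test_rank_z_standardized_under_null(self):
        # for random queries, any fixed term's rank-z should be ~N(0, 1)
        rng = np.random.default_rng(5)
        universe = [f"u{i}" for i in range(60)]
        terms = [
            enrich.GeneSet(f"T{j}", "", frozenset(rng.choice(universe, 12, replace=False)))
            for j in range(8)
        ]
        zs = []
        for rep in range(40):
            query = list(rng.choice(universe, 10, replace=False))
            tab = enrich.combined_score_table(
                query, terms, universe, n_null=60, seed=500 + rep
            )
            zs.append(tab["rank_z"].iloc[0])
        zs = np.asarray(zs)
        assert abs(zs.mean()) < 0.5
        assert 0.5 < zs.std() < 2.0


class TestPromoterTargets:
    TSS = pd.DataFrame(
        {
            "gene": ["plus_hit", "plus_far", "minus_hit"],
            "chrom": ["chr1", "chr3", "chr2"],
            "pos": [1000, 1000, 10000],
            "strand": ["+", "+", "-"],
        }
    )

    def test_window_arithmetic_both_strands(self):
        peaks = pd.DataFrame(
            {
                "chrom": ["chr1", "chr3", "chr2"],
                "start": [400, 6500, 9500],
                "end": [600, 6600, 9600],
            }
        )
        de = {"plus_hit", "plus_far", "minus_hit"}
        hits = enrich.promoter_peak_targets(peaks, self.TSS, de)
        # + strand window [-5000, +1000] around 1000 covers [0, 2000]:
        # peak [400, 600) hits, [6500, 6600) does not; - strand window
        # around 10000 is [9000, 15000]: peak [9500, 9600) hits
        assert hits == ["minus_hit", "plus_hit"]

    def test_de_gate_required(self):
        peaks = pd.DataFrame({"chrom": ["chr1"], "start": [400], "end": [600]})
        assert enrich.promoter_peak_targets(peaks, self.TSS, set()) == []

    def test_unknown_strand_rejected(self):
        tss = self.TSS.copy()
        tss.loc[0, "strand"] = "*"
        peaks = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [10]})
        with pytest.raises(InputError, match="strand"):
            enrich.promoter_peak_targets(peaks, tss, {"plus_hit"})

    def test_half_open_peak_end(self):
        # peak [0, 100) does not reach a window starting at 100
        tss = pd.DataFrame(
            {"gene": ["g"], "chrom": ["c"], "pos": [5100], "strand": ["+"]}
        )
        peaks = pd.DataFrame({"chrom": ["c"], "start": [0], "end": [100]})
        assert enrich.promoter_peak_targets(peaks, tss, {"g"}) == []
        peaks2 = pd.DataFrame({"chrom": ["c"], "start": [0], "end": [101]})
        assert enrich.promoter_peak_targets(peaks2, tss, {"g"}) == ["g"]
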