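"""Gene-set enrichment, correlation pruning and candidate-set enumeration."""

import itertools

import numpy as np
import pandas as pd
import pytest

from methylpanel.features import (
    CandidateFeatureSet,
    best_probe_per_gene,
    enumerate_candidate_sets,
    go_enrichment,
    maximal_independent_sets,
    within_term_correlations,
)


def _collection(**terms):
    return {tid: (tid.lower(), frozenset(genes)) for tid, genes in terms.items()}


class TestGoEnrichment:
    def test_direct_hypergeometric_value(self):
        # all 5 query genes inside a 5-gene term of a 20-gene background:
        # C(5,5) C(15,0) / C(20,5) = 1/15504
        res = go_enrichment(
            {"g1", "g2", "g3", "g4", "g5"},
            _collection(T={"g1", "g2", "g3", "g4", "g5"}),
            {f"g{i}" for i in range(1, 21)},
        )
        assert res["p_raw"].iloc[0] == pytest.approx(1 / 15504, rel=1e-12)
        # single term tested -> Bonferroni multiplier 1
        assert res["p_bonferroni"].iloc[0] == pytest.approx(1 / 15504, rel=1e-12)

    def test_zero_overlap_is_certain_event(self):
        res = go_enrichment(
            {"g1"}, _collection(T={"g2", "g3"}), {"g1", "g2", "g3", "g4"}
        )
        assert res["p_raw"].iloc[0] == pytest.approx(1.0)

    def test_monotone_in_overlap(self):
        background = {f"g{i}" for i in range(40)}
        term = {f"g{i}" for i in range(10)}
        ps = []
        for k in range(1, 6):
            query = {f"g{i}" for i in range(k)} | {f"g{30 + i}" for i in range(5 - k)}
            res = go_enrichment(query, _collection(T=term), background)
            ps.append(res["p_raw"].iloc[0])
        assert all(p2 < p1 for p1, p2 in zip(ps, ps[1:]))

    def test_bonferroni_multiplier_counts_terms(self):
        background = {f"g{i}" for i in range(30)}
        res = go_enrichment(
            {"g0", "g1"},
            _collection(A={"g0", "g1"}, B={"g5"}, C={"g6"}),
            background,
        )
        assert res.loc["A", "p_bonferroni"] == pytest.approx(
            min(1.0, res.loc["A", "p_raw"] * 3)
        )

    def test_query_outside_background_rejected(self):
        with pytest.raises(ValueError):
            go_enrichment({"gX"}, _collection(T={"g1"}), {"g1", "g2"})


class TestWithinTermCorrelations:
    def _beta(self, rng, probes, n=42):
        return pd.DataFrame(
            rng.uniform(0.3, 0.9, size=(len(probes), n)),
            index=probes,
            columns=[f"s{j}" for j in range(n)],
        )

    def test_shared_signal_flagged(self, rng):
        beta = self._beta(rng, ["a", "b", "c"])
        beta.loc["b"] = beta.loc["a"]  # identical signal, rho = 1
        flagged = within_term_correlations(beta, {"T": ["a", "b", "c"]})
        assert ("a", "b") in flagged["T"]

    def test_cross_term_pairs_never_tested(self, rng):
        beta = self._beta(rng, ["a", "b"])
        beta.loc["b"] = beta.loc["a"]
        flagged = within_term_correlations(beta, {"T1": ["a"], "T2": ["b"]})
        assert flagged == {"T1": [], "T2": []}

    def test_constant_probe_skipped_with_warning(self, rng):
        beta = self._beta(rng, ["a", "b"])
        beta.loc["a"] = 0.5
        with pytest.warns(UserWarning):
            flagged = within_term_correlations(beta, {"T": ["a", "b"]})
        assert flagged["T"] == []

    def test_type_i_rate_near_alpha(self):
        """Independent probes are flagged in roughly 5% of replicates."""
        hits = trials = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            beta = self._beta(rng, ["a", "b"])
            flagged = within_term_correlations(beta, {"T": ["a", "b"]})
            hits += len(flagged["T"])
            trials += 1
        assert hits / trials < 0.25  # loose upper bound on a 5% rate


def brute_force_mis(vertices, edges):
    """Independent sets by subset filtering, keeping the maximal ones."""
    edges = {frozenset(e) for e in edges}
    independent = []
    for r in range(len(vertices) + 1):
        for subset in itertools.combinations(sorted(vertices), r):
            if all(frozenset(p) not in edges for p in itertools.combinations(subset, 2)):
                independent.append(frozenset(subset))
    maximal = [
        s for s in independent if not any(s < t for t in independent)
    ]
    return sorted(tuple(sorted(s)) for s in maximal)


class TestEnumeration:
    def test_single_conflict_pair(self):
        sets = maximal_independent_sets(["A", "B", "C"], [("A", "B")])
        assert sets == [("A", "C"), ("B", "C")]

    def test_matches_brute_force_on_random_graphs(self, rng):
        for _ in range(30):
            n = int(rng.integers(2, 10))
            vertices = [f"v{i}" for i in range(n)]
            edges = [
                pair
                for pair in itertools.combinations(vertices, 2)
                if rng.uniform() < 0.3
            ]
            assert maximal_independent_sets(vertices, edges) == brute_force_mis(
                vertices, edges
            )

    def test_no_conflicts_single_full_candidate(self):
        cands = enumerate_candidate_sets(
            ["T"], {"T": ["a", "b", "c"]}, {"T": []}
        )
        assert len(cands) == 1 and cands[0].probes == ("a", "b", "c")

    def test_correlated_genes_never_cofeature(self):
        """A conflict pair in each category splits the candidates so that no
        emitted roster carries both members of any flagged pair."""
        term_probes = {
            "transcription": ["HOXA9", "ZNF154", "SOX17", "HOXD13"],
            "signaling": ["SFRP1", "VIPR2", "HBP1"],
            "adhesion": ["CD34", "PCDH17", "ITGA5"],
        }
        flagged = {
            "transcription": [("HOXA9", "ZNF154")],
            "signaling": [("SFRP1", "VIPR2")],
            "adhesion": [("CD34", "PCDH17")],
        }
        cands = enumerate_candidate_sets(list(term_probes), term_probes, flagged)
        assert len(cands) == 8  # 2 x 2 x 2 admissible rosters
        for cs in cands:
            for pairs in flagged.values():
                for x, y in pairs:
                    assert not ({x, y} <= set(cs.probes))

    def test_candidates_satisfy_their_invariant(self, rng):
        term_probes = {"T": [f"p{i}" for i in range(8)]}
        edges = [
            pair
            for pair in itertools.combinations(term_probes["T"], 2)
            if rng.uniform() < 0.25
        ]
        cands = enumerate_candidate_sets(["T"], term_probes, {"T": edges})
        edge_sets = {frozenset(e) for e in edges}
        for cs in cands:
            for pair in itertools.combinations(cs.probes, 2):
                assert frozenset(pair) not in edge_sets

    def test_deterministic_order_and_cap(self):
        term_probes = {"T": ["a", "b", "c", "d"]}
        flagged = {"T": [("a", "b"), ("c", "d")]}
        c1 = enumerate_candidate_sets(["T"], term_probes, flagged)
        c2 = enumerate_candidate_sets(["T"], term_probes, flagged)
        assert [c.probes for c in c1] == [c.probes for c in c2]
        capped = enumerate_candidate_sets(["T"], term_probes, flagged, max_sets=2)
        assert len(capped) == 2
        with pytest.raises(ValueError):
            enumerate_candidate_sets(["T"], term_probes, flagged, max_sets=0)

    def test_per_term_truncation_respects_ranking(self):
        # probes listed in ranking order; truncation keeps the best two
        cands = enumerate_candidate_sets(
            ["T"], {"T": ["best", "mid", "worst"]}, {"T": []}, max_probes_per_term=2
        )
        assert cands[0].probes == ("best", "mid")


def test_best_probe_per_gene_smallest_p_wins():
    probes = ["cg1", "cg2", "cg3"]
    gene = {"cg1": "G1", "cg2": "G1", "cg3": "G2"}
    pvals = {"cg1": 1e-9, "cg2": 1e-12, "cg3": 1e-5}
    assert best_probe_per_gene(probes, gene, pvals) == ["cg2", "cg3"]
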