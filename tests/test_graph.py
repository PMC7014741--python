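"""Coverage filter, read-sharing edges, and pre-cluster detection."""

import random

import networkx as nx
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from contigclust.alignment_io import compute_contig_stats
from contigclust.graph import (
    ClusteringParams,
    build_edges,
    effective_coverage,
    filter_low_evidence,
    find_preclusters,
)

from conftest import make_table, random_instance


class TestEffectiveCoverage:
    @pytest.mark.parametrize(
        "n_reads,read_len,contig_len,expected",
        [
            (9, 250, 750, 3.0),   # nine 250-base reads on a 750-bp contig
            (0, 100, 750, 0.0),   # no reads at all
            (10, 100, 400, 2.5),
        ],
    )
    def test_fold_coverage(self, n_reads, read_len, contig_len, expected):
        frags = {f"r{i}": {"X"} for i in range(n_reads)}
        table = make_table(frags, {"X": contig_len}, fragment_length=read_len)
        stats = compute_contig_stats(table)
        assert effective_coverage(stats, table.contig_lengths, "X") == expected

    def test_missing_length_is_a_contract_violation(self):
        table = make_table({"r1": {"X"}}, {"X": 100})
        stats = compute_contig_stats(table)
        with pytest.raises(ValueError):
            effective_coverage(stats, {}, "X")


class TestLowEvidenceFilter:
    @pytest.fixture
    def covered_contig(self):
        frags = {f"r{i}": {"X"} for i in range(9)}
        table = make_table(frags, {"X": 750}, fragment_length=250)
        return table, compute_contig_stats(table)

    def test_exactly_at_threshold_passes(self, covered_contig):
        table, stats = covered_contig
        passing, low = filter_low_evidence(stats, table.contig_lengths, 3.0)
        assert "X" in passing and not low

    def test_just_above_threshold_fails(self, covered_contig):
        table, stats = covered_contig
        passing, low = filter_low_evidence(stats, table.contig_lengths, 3.01)
        assert "X" in low and not passing

    def test_l_zero_passes_everything_even_zero_reads(self):
        table = make_table({"r1": {"A"}}, {"A": 100, "B": 100})
        stats = compute_contig_stats(table)
        passing, low = filter_low_evidence(stats, table.contig_lengths, 0.0)
        assert passing == {"A", "B"} and low == set()

    def test_zero_read_contig_is_low_evidence_for_positive_l(self):
        table = make_table({"r1": {"A"}}, {"A": 100, "B": 100})
        stats = compute_contig_stats(table)
        _, low = filter_low_evidence(stats, table.contig_lengths, 0.01)
        assert "B" in low

    @given(l1=st.floats(0, 5), l2=st.floats(0, 5), seed=st.integers(0, 100))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_filter_is_monotone_in_l(self, l1, l2, seed):
        if l1 > l2:
            l1, l2 = l2, l1
        table = random_instance(random.Random(seed), max_contigs=12, max_fragments=60)
        stats = compute_contig_stats(table)
        pass1, low1 = filter_low_evidence(stats, table.contig_lengths, l1)
        pass2, low2 = filter_low_evidence(stats, table.contig_lengths, l2)
        assert pass2 <= pass1
        assert pass1 | low1 == set(table.contig_lengths)
        assert pass1 & low1 == set()


class TestBuildEdges:
    def test_subset_read_set_gives_weight_one(self):
        frags = {f"f{i}": ({"A", "B"} if i >= 6 else {"A"}) for i in range(1, 11)}
        table = make_table(frags, {"A": 100, "B": 100})
        graph = build_edges(table, {"A", "B"})
        (edge,) = graph.edges
        assert edge.shared == 5
        assert edge.weight == 1.0

    def test_disjoint_contigs_share_no_edge(self):
        frags = {"f1": {"A"}, "f2": {"B"}}
        table = make_table(frags, {"A": 100, "B": 100})
        graph = build_edges(table, {"A", "B"})
        assert graph.edges == []

    def test_weight_is_shared_over_smaller_read_count(self):
        # R_A=10, R_B=5, R_AB=3 -> w = 3/5 = 0.6
        frags = {}
        for i in range(10):
            frags[f"a{i}"] = {"A"}
        for i in range(2):
            frags[f"b{i}"] = {"B"}
        for i in range(3):
            frags[f"ab{i}"] = {"A", "B"}
        table = make_table(frags, {"A": 100, "B": 100})
        graph = build_edges(table, {"A", "B"})
        (edge,) = graph.edges
        assert edge.weight == pytest.approx(0.6)

    def test_low_evidence_contigs_touch_no_edge(self):
        frags = {"f1": {"A", "B"}, "f2": {"A", "B"}}
        table = make_table(frags, {"A": 100, "B": 100})
        graph = build_edges(table, {"A"})
        assert graph.edges == []
        assert graph.low_evidence == {"B"}

    @given(seed=st.integers(0, 500))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_weights_in_unit_interval_and_one_iff_subset(self, seed):
        table = random_instance(random.Random(seed), max_contigs=15, max_fragments=100)
        graph = build_edges(table, set(table.contig_lengths))
        for e in graph.edges:
            assert 0.0 < e.weight <= 1.0
            ri, rj = graph.read_sets[e.i], graph.read_sets[e.j]
            smaller, larger = (ri, rj) if len(ri) <= len(rj) else (rj, ri)
            assert (e.weight == 1.0) == (smaller <= larger)


class TestPreClusters:
    def test_transitive_connectivity(self):
        frags = {"f1": {"A", "B"}, "f2": {"B", "C"}, "f3": {"D"}}
        table = make_table(frags, {c: 100 for c in "ABCD"})
        graph = build_edges(table, {"A", "B", "C", "D"})
        pcs = find_preclusters(graph)
        assert [set(pc.members) for pc in pcs] == [{"A", "B", "C"}, {"D"}]

    def test_no_edges_means_all_singletons(self):
        frags = {f"f{i}": {f"c{i}"} for i in range(5)}
        table = make_table(frags, {f"c{i}": 100 for i in range(5)})
        graph = build_edges(table, set(table.contig_lengths))
        pcs = find_preclusters(graph)
        assert len(pcs) == 5
        assert all(len(pc.members) == 1 for pc in pcs)

    @pytest.mark.parametrize("seed", range(25))
    def test_components_match_brute_force_reachability(self, seed):
        """Components equal the transitive closure computed by hand."""
        rng = random.Random(seed)
        table = random_instance(rng, max_contigs=50, max_fragments=200)
        graph = build_edges(table, set(table.contig_lengths))
        pcs = find_preclusters(graph)
        # brute-force transitive closure over the boolean adjacency matrix
        nodes = sorted(graph.passing)
        idx = {c: k for k, c in enumerate(nodes)}
        n = len(nodes)
        closure = [[i == j for j in range(n)] for i in range(n)]
        for e in graph.edges:
            closure[idx[e.i]][idx[e.j]] = closure[idx[e.j]][idx[e.i]] = True
        for k in range(n):
            for i in range(n):
                if closure[i][k]:
                    for j in range(n):
                        if closure[k][j]:
                            closure[i][j] = True
        expected = {
            frozenset(nodes[j] for j in range(n) if closure[i][j]) for i in range(n)
        }
        assert {pc.members for pc in pcs} == expected

    def test_induced_edges_stay_within_component(self, seed=3):
        table = random_instance(random.Random(seed), max_contigs=30, max_fragments=150)
        graph = build_edges(table, set(table.contig_lengths))
        for pc in find_preclusters(graph):
            for e in pc.edges:
                assert e.i in pc.members and e.j in pc.members


def test_params_validate_ranges():
    with pytest.raises(ValueError):
        ClusteringParams(d=1.5)
    with pytest.raises(ValueError):
        ClusteringParams(l=-1)
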