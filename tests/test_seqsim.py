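"""Motif similarity: Hamming, clustering, PWMs, networks, communities."""

from itertools import combinations, product

import networkx as nx
import numpy as np
import pytest

from riboscreen.seqsim import (
    build_network,
    cluster_motifs,
    communities,
    community_summary,
    distance_matrix,
    hamming,
    pwm,
)


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def oracle_hamming(a, b):
    return sum(1 for x, y in zip(a, b) if x != y)


def all_partitions(items):
    """Every set partition of ``items`` (for exhaustive modularity search)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in all_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [part[i] | {first}] + part[i + 1 :]
        yield part + [{first}]


def oracle_best_modularity(g):
    """Max modularity over every partition of the node set."""
    best = -np.inf
    for part in all_partitions(g.nodes):
        q = nx.community.modularity(g, part)
        best = max(best, q)
    return best


# ---------------------------------------------------------------------------
# Hamming
# ---------------------------------------------------------------------------

class TestHamming:
    def test_identity_and_single_mismatch(self):
        assert hamming("CCGCAG", "CCGCAG") == 0
        assert hamming("CCGCAG", "CCGCAA") == 1

    def test_exhaustive_two_mers(self):
        mers = ["".join(p) for p in product("ACGT", repeat=2)]
        for a, b in combinations(mers, 2):
            assert hamming(a, b) == oracle_hamming(a, b)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            hamming("ACG", "ACGT")

    def test_distance_matrix_properties(self):
        motifs = ["AAAA", "AATT", "GGTT", "ACGT", "AAAT"]
        d = distance_matrix(motifs).values
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0)
        n = len(motifs)
        for i, j, k in product(range(n), repeat=3):
            assert d[i, j] <= d[i, k] + d[k, j] + 1e-12


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

class TestClustering:
    def test_single_motif_singleton(self):
        out = cluster_motifs(["ACGTAC"])
        assert len(out) == 1 and out[0].members == ["ACGTAC"]

    def test_identity_threshold_grouping(self):
        # AAAAAAAA vs AAAAAAAT share 87.5% identity (co-cluster at >75%);
        # TTTTTTTT shares at most 12.5% with either (separate)
        out = cluster_motifs(["AAAAAAAA", "AAAAAAAT", "TTTTTTTT"])
        members = sorted(tuple(c.members) for c in out)
        assert members == [("AAAAAAAA", "AAAAAAAT"), ("TTTTTTTT",)]

    def test_exact_threshold_not_grouped(self):
        # 75% identity exactly must NOT co-cluster under a strict > rule
        out = cluster_motifs(["AAAAAAAA", "AAAAAATT"])
        assert len(out) == 2

    def test_all_identical_degenerate_pwm(self):
        out = cluster_motifs(["ACG", "ACG", "ACG"])
        assert len(out) == 1
        assert np.allclose(out[0].pwm.max(axis=1), 1.0)
        assert np.allclose(out[0].information_content, 2.0)

    def test_mixed_lengths_rejected(self):
        with pytest.raises(ValueError, match="length"):
            cluster_motifs(["ACG", "ACGT"])

    def test_deterministic_under_input_order(self):
        motifs = ["ACGTAC", "ACGTAA", "TTTTGG", "TTTTGC", "GCGCGC"]
        a = cluster_motifs(motifs)
        b = cluster_motifs(motifs[::-1])
        assert [c.members for c in a] == [c.members for c in b]


class TestPWM:
    def test_quarter_split_zero_ic(self):
        probs, ic = pwm(["A", "C", "G", "T"])
        assert np.allclose(probs, 0.25)
        assert ic[0] == pytest.approx(0.0)

    def test_two_member_cluster(self):
        probs, ic = pwm(["AC", "AG"])
        assert ic[0] == pytest.approx(2.0)
        assert ic[1] == pytest.approx(1.0)  # 2 + 2*(0.5*log2 0.5)

    def test_columns_sum_to_one_with_pseudocount(self):
        probs, ic = pwm(["ACGT", "AAGT", "ACCT"], pseudocount=0.5)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-9)
        assert np.all((ic >= 0) & (ic <= 2))

    def test_empty_cluster_rejected(self):
        with pytest.raises(ValueError):
            pwm([])


# ---------------------------------------------------------------------------
# mutation network
# ---------------------------------------------------------------------------

class TestNetwork:
    def test_chain_edges_only(self):
        g = build_network({"AAA": 0.5, "AAT": 0.4, "ATT": 0.3})
        assert sorted(map(tuple, map(sorted, g.edges))) == [
            ("AAA", "AAT"), ("AAT", "ATT"),
        ]

    def test_full_one_neighborhood(self):
        center = "ACGTA"
        neighbors = {
            center[:i] + b + center[i + 1 :]
            for i in range(5)
            for b in "ACGT"
            if b != center[i]
        }
        g = build_network({m: 0.0 for m in neighbors | {center}})
        assert g.degree[center] == 3 * len(center)

    def test_edge_count_matches_all_pairs_oracle(self):
        rng = np.random.default_rng(4)
        motifs = {
            "".join(rng.choice(list("ACGT"), 6)): float(rng.normal())
            for _ in range(200)
        }
        g = build_network(motifs)
        expected = sum(
            1 for a, b in combinations(motifs, 2) if oracle_hamming(a, b) == 1
        )
        assert g.number_of_edges() == expected
        for a, b in g.edges:
            assert oracle_hamming(a, b) == 1

    def test_isolated_nodes_retained_and_lfc_stored(self):
        g = build_network({"AAAA": -1.2, "GGCC": 0.7})
        assert g.number_of_edges() == 0
        assert g.nodes["AAAA"]["log2fc"] == -1.2

    def test_duplicates_collapse_with_warning(self):
        import pandas as pd

        s = pd.Series([0.1, 0.2], index=["AAA", "AAA"])
        with pytest.warns(UserWarning, match="duplicate"):
            g = build_network(s)
        assert g.number_of_nodes() == 1


class TestCommunities:
    def _bridged(self, clique_size):
        g1 = nx.complete_graph(clique_size)
        g = nx.disjoint_union(g1, nx.complete_graph(clique_size))
        g = nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes})
        g.add_edge("n0", f"n{clique_size}")
        return g

    @pytest.mark.parametrize("clique_size", [3, 4])
    def test_two_bridged_cliques_split_at_bridge(self, clique_size):
        g = self._bridged(clique_size)
        part = communities(g)
        assert len(part) == 2
        sizes = sorted(len(c) for c in part)
        assert sizes == [clique_size, clique_size]
        # matches the exhaustive max-modularity partition
        assert nx.community.modularity(g, part) == pytest.approx(
            oracle_best_modularity(g)
        )

    def test_single_clique_one_community(self):
        g = nx.relabel_nodes(nx.complete_graph(5), {i: f"m{i}" for i in range(5)})
        part = communities(g)
        assert len(part) == 1 and part[0] == set(g.nodes)

    def test_isolated_nodes_singletons(self):
        g = nx.Graph()
        g.add_nodes_from(["AAA", "CCC", "GGG"])
        assert communities(g) == [{"AAA"}, {"CCC"}, {"GGG"}]

    def test_empty_graph(self):
        assert communities(nx.Graph()) == []

    def test_partition_covers_nodes_exactly_once(self):
        g = self._bridged(4)
        part = communities(g)
        all_nodes = [n for c in part for n in c]
        assert sorted(all_nodes) == sorted(g.nodes)

    def test_community_summary_mean_lfc(self):
        g = build_network({"AAA": -1.0, "AAT": -2.0, "GGG": 3.0})
        part = communities(g)
        summ = community_summary(g, part).set_index("members")
        assert summ.loc["AAA,AAT", "mean_log2fc"] == pytest.approx(-1.5)
        assert summ.loc["GGG", "mean_log2fc"] == pytest.approx(3.0)
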