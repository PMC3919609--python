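"""Similarity graph construction and greedy density clustering."""

import itertools
import math

import networkx as nx
import pytest
from Bio.Align import substitution_matrices

from zfselect import (
    aggregate_by_protein,
    build_graph,
    cluster_consensus,
    cluster_graph,
    entropy_filter,
    pairwise_similarity,
    rank_clusters,
)
from zfselect.clustering import Cluster, clusters_to_frame
from zfselect.entropy import ProteinObservation


def blosum_oracle(x, y):
    """Direct table lookup over the published BLOSUM62 matrix."""
    m = substitution_matrices.load("BLOSUM62")
    s_xy = sum(m[a][b] for a, b in zip(x, y))
    return max(0.0, s_xy) / math.sqrt(
        sum(m[a][a] for a in x) * sum(m[b][b] for b in y)
    )


def test_similarity_identity_and_symmetry():
    seqs = ["QGNKS", "WLFPM", "RSDNL", "QGNKT", "AAAAA"]
    for x in seqs:
        assert pairwise_similarity(x, x) == pytest.approx(1.0)
    for x, y in itertools.combinations(seqs, 2):
        s = pairwise_similarity(x, y)
        assert s == pytest.approx(pairwise_similarity(y, x))
        assert 0.0 <= s <= 1.0


def test_similarity_hand_computation():
    # published entries: Q/Q=5 G/G=6 N/N=6 K/K=5 S/S=4 T/T=5 S/T=1
    expected = 23 / math.sqrt(26 * 27)
    assert pairwise_similarity("QGNKS", "QGNKT") == pytest.approx(expected)
    assert pairwise_similarity("QGNKS", "QGNKT") == pytest.approx(
        blosum_oracle("QGNKS", "QGNKT")
    )


def test_similarity_clamped_at_zero():
    assert pairwise_similarity("QGNKS", "WLFPM") == 0.0


def test_similarity_rejects_length_mismatch():
    with pytest.raises(ValueError):
        pairwise_similarity("QGNKS", "QGNK")


def _observations(scheme, seq_counts):
    out = []
    for seq, count in seq_counts.items():
        encodings = itertools.islice(scheme.enumerate_encodings(seq), 1)
        out.append(
            ProteinObservation(seq, {next(iter(encodings)): count},
                               scheme.encoding_count(seq))
        )
    return out


def test_build_graph_strict_threshold(scheme):
    obs = _observations(scheme, {"QGNKS": 5, "QGNKT": 5, "WLFPM": 5})
    graph = build_graph(obs)
    assert graph.has_edge("QGNKS", "QGNKT")
    assert not graph.has_edge("QGNKS", "WLFPM")  # s = 0 <= 0.25
    # an edge exactly at the threshold is excluded (strict >)
    g2 = build_graph(obs, edge_threshold=pairwise_similarity("QGNKS", "QGNKT"))
    assert not g2.has_edge("QGNKS", "QGNKT")


def _clique_graph(sizes):
    """Disjoint union of cliques with unit edge weights and unit counts."""
    graph = nx.Graph()
    label = 0
    cliques = []
    for size in sizes:
        nodes = ["s%03d" % (label + k) for k in range(size)]
        label += size
        for node in nodes:
            graph.add_node(node, count=1)
        for u, v in itertools.combinations(nodes, 2):
            graph.add_edge(u, v, weight=1.0)
        cliques.append(set(nodes))
    return graph, cliques


@pytest.mark.parametrize(
    "sizes,expected_sizes",
    [((12,), [12]), ((15, 15), [15, 15]), ((9,), []), ((9, 12, 15), [15, 12])],
)
def test_cluster_graph_clique_oracle(sizes, expected_sizes):
    graph, cliques = _clique_graph(sizes)
    clusters = cluster_graph(graph)
    assert sorted((c.size for c in clusters), reverse=True) == expected_sizes
    recovered = [set(c.members) for c in clusters]
    for members in recovered:
        assert members in cliques


def test_cluster_density_contract():
    graph, _ = _clique_graph((12, 15))
    # thin one clique: remove a few edges, density stays above 0.5
    graph.remove_edge("s000", "s001")
    graph.remove_edge("s002", "s003")
    for cluster in cluster_graph(graph):
        sub = graph.subgraph(cluster.members)
        n = cluster.size
        density = sum(d["weight"] for _, _, d in sub.edges(data=True)) / (
            n * (n - 1) / 2
        )
        assert density >= 0.5


def test_clustering_invariant_to_input_order(scheme, planted_selection):
    observations, _ = aggregate_by_protein(planted_selection["pool"], scheme)
    retained, _ = entropy_filter(observations)
    forward = cluster_graph(build_graph(retained))
    backward = cluster_graph(build_graph(list(reversed(retained))))
    assert [sorted(c.members) for c in forward] == \
        [sorted(c.members) for c in backward]


def test_consensus_majority_and_ties():
    assert cluster_consensus({"QGNKS": 60, "QGNKT": 40}) == "QGNKS"
    assert cluster_consensus({"QGNKS": 3}) == "QGNKS"
    # tie at the last position resolves to the alphabetically earlier residue
    assert cluster_consensus({"QGNKS": 1, "QGNKT": 1})[-1] == "S"


def _cluster(members, share):
    return Cluster(members, count_share=share)


def test_rank_clusters_share_and_high_stringency_rules():
    low = [
        _cluster({"QGNKS": 300, "QGNKT": 100}, 0.30),
        _cluster({"WLFPM": 40}, 0.04),
    ]
    high = [_cluster({"QGNKS": 50}, 1.0)]
    ranked = rank_clusters(low, high)
    assert ranked[0][0].count_share == 0.30 and ranked[0][1] is True
    assert ranked[1][1] is False  # share 0.04 < 0.05
    # share above 5% but no similar high-stringency cluster -> unflagged
    ranked2 = rank_clusters([_cluster({"WLFPM": 400}, 0.40)], high)
    assert ranked2[0][1] is False


def test_rank_clusters_warns_without_high_pool():
    low = [_cluster({"QGNKS": 300}, 0.30)]
    with pytest.warns(UserWarning):
        ranked = rank_clusters(low, None)
    assert ranked[0][1] is False


def test_clusters_frame_shares_sum_to_one(scheme, planted_selection):
    observations, _ = aggregate_by_protein(planted_selection["pool"], scheme)
    retained, _ = entropy_filter(observations)
    clusters = cluster_graph(build_graph(retained))
    assert sum(c.count_share for c in clusters) == pytest.approx(1.0)
    frame = clusters_to_frame(rank_clusters(clusters, clusters))
    assert set(frame.cluster_id) == set(range(1, len(clusters) + 1))
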