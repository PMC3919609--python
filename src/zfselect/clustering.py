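"""Specificity-group clustering of retained recognition helices.

Entropy-filtered proteins that bind a common DNA target often fall into a
handful of distinct "specificity groups" — families of similar helices that
realize alternative binding strategies.  Each selection is modelled as a
graph: nodes are protein sequences (weighted by read counts), and two nodes
are joined when their normalized BLOSUM62 similarity exceeds 0.25.  Clusters
are found with a reimplementation of the SPICi greedy density-based
algorithm (seed at the highest weighted-degree vertex, add the best-support
neighbour while the support and density thresholds hold, both 0.5 by
default); clusters of fewer than 10 sequences are not reported.

A cluster is "highly populated" when it holds at least 5% of the clustered
read counts at low stringency and a similar cluster (consensus-to-consensus
similarity above the edge threshold) is recovered at high stringency.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass
from functools import lru_cache

import networkx as nx
import pandas as pd
from Bio.Align import substitution_matrices

from .entropy import ProteinObservation

EDGE_THRESHOLD = 0.25
MIN_CLUSTER_SIZE = 10
SUPPORT_THRESHOLD = 0.5
DENSITY_THRESHOLD = 0.5
MIN_SHARE = 0.05

_WEIGHT_BINS = (0.8, 0.6, 0.4, 0.2, 0.0)


@lru_cache(maxsize=1)
def _blosum62():
    return substitution_matrices.load("BLOSUM62")


def pairwise_similarity(x: str, y: str) -> float:
    """Normalized ungapped BLOSUM62 similarity in [0, 1].

    Raw score S(x, y) = sum over positions of BLOSUM62 entries; normalized by
    the geometric mean of self-scores and clamped at zero:
    s = max(0, S(x,y)) / sqrt(S(x,x) * S(y,y)).  Symmetric, s(x, x) = 1.
    All library members share fixed variable positions, so the comparison is
    strictly position-wise with no gaps.
    """
    if len(x) != len(y):
        raise ValueError("sequences must have equal length: %r vs %r" % (x, y))
    m = _blosum62()
    s_xy = sum(m[a][b] for a, b in zip(x, y))
    s_xx = sum(m[a][a] for a in x)
    s_yy = sum(m[b][b] for b in y)
    return max(0.0, s_xy) / math.sqrt(s_xx * s_yy)


def build_graph(
    observations: list[ProteinObservation],
    edge_threshold: float = EDGE_THRESHOLD,
) -> nx.Graph:
    """All-pairs similarity graph over retained proteins.

    Nodes carry read counts as ``count``; an edge is present iff similarity
    strictly exceeds ``edge_threshold`` and carries it as ``weight``.
    """
    if not observations:
        raise ValueError("no retained observations to build a graph from")
    graph = nx.Graph()
    for obs in observations:
        graph.add_node(obs.aa_seq, count=obs.total_count)
    seqs = sorted(graph.nodes)
    for i, x in enumerate(seqs):
        for y in seqs[i + 1:]:
            s = pairwise_similarity(x, y)
            if s > edge_threshold:
                graph.add_edge(x, y, weight=s)
    return graph


@dataclass
class Cluster:
    """A specificity group: member helices with counts and a consensus."""

    members: dict[str, int]
    count_share: float
    stringency: str | None = None

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def total_count(self) -> int:
        return sum(self.members.values())

    @property
    def consensus(self) -> str:
        return cluster_consensus(self.members)


def cluster_graph(
    graph: nx.Graph,
    min_size: int = MIN_CLUSTER_SIZE,
    support: float = SUPPORT_THRESHOLD,
    density: float = DENSITY_THRESHOLD,
) -> list[Cluster]:
    """Greedy density-based clustering (SPICi), reported clusters >= min_size.

    Repeatedly seeds at the unclustered vertex of highest weighted degree,
    pairs it with its best neighbour from the highest occupied edge-weight
    bin, then grows the cluster by the unclustered neighbour of maximal
    support while (a) that support is at least ``support * |S| * density(S)``
    and (b) the grown cluster's density stays >= ``density``.  The cluster's
    vertices are then removed and the search repeats.  Ties on degree and
    support are broken toward the lexicographically smaller sequence, making
    the output invariant to input order.
    """
    work = graph.copy()
    raw: list[set[str]] = []
    while work.number_of_nodes() > 0:
        seed = _best_vertex(work, work.nodes)
        neighbors = list(work.adj[seed])
        if not neighbors:
            raw.append({seed})
            work.remove_node(seed)
            continue
        second = _second_seed(work, seed, neighbors)
        members = {seed, second}
        internal_weight = work[seed][second]["weight"]
        while True:
            candidate, cand_support = _best_support(work, members)
            if candidate is None:
                break
            size = len(members)
            dens = internal_weight / (size * (size - 1) / 2)
            if cand_support < support * size * dens:
                break
            new_weight = internal_weight + cand_support
            new_size = size + 1
            if new_weight / (new_size * (new_size - 1) / 2) < density:
                break
            members.add(candidate)
            internal_weight = new_weight
        raw.append(members)
        work.remove_nodes_from(members)
    clusters = []
    denominator = 0
    kept: list[dict[str, int]] = []
    for members in raw:
        if len(members) < min_size:
            continue
        counts = {m: graph.nodes[m]["count"] for m in members}
        kept.append(counts)
        denominator += sum(counts.values())
    for counts in kept:
        clusters.append(
            Cluster(counts, count_share=sum(counts.values()) / denominator)
        )
    clusters.sort(key=lambda c: (-c.count_share, c.consensus))
    return clusters


def _weighted_degree(graph: nx.Graph, u: str) -> float:
    return sum(d["weight"] for d in graph.adj[u].values())


def _best_vertex(graph: nx.Graph, candidates) -> str:
    return min(candidates, key=lambda u: (-_weighted_degree(graph, u), u))


def _second_seed(graph: nx.Graph, seed: str, neighbors: list[str]) -> str:
    for lo in _WEIGHT_BINS:
        binned = [v for v in neighbors if graph[seed][v]["weight"] > lo]
        if binned:
            return _best_vertex(graph, binned)
    raise AssertionError("unreachable: neighbors non-empty")


def _best_support(graph: nx.Graph, members: set[str]):
    """Unclustered neighbour of the cluster with maximal support into it."""
    support: dict[str, float] = {}
    for m in members:
        for v, d in graph.adj[m].items():
            if v not in members:
                support[v] = support.get(v, 0.0) + d["weight"]
    if not support:
        return None, 0.0
    best = min(support, key=lambda v: (-support[v], v))
    return best, support[best]


def cluster_consensus(members: dict[str, int]) -> str:
    """Count-weighted modal residue per position; ties to the earlier letter."""
    if not members:
        raise ValueError("empty cluster")
    length = len(next(iter(members)))
    consensus = []
    for pos in range(length):
        votes: Counter[str] = Counter()
        for seq, count in members.items():
            votes[seq[pos]] += count
        consensus.append(min(votes, key=lambda aa: (-votes[aa], aa)))
    return "".join(consensus)


def rank_clusters(
    clusters_low: list[Cluster],
    clusters_high: list[Cluster] | None,
    min_share: float = MIN_SHARE,
    edge_threshold: float = EDGE_THRESHOLD,
) -> list[tuple[Cluster, bool]]:
    """Sort low-stringency clusters by count share and flag highly populated ones.

    A cluster is flagged iff its share at low stringency is >= ``min_share``
    and some high-stringency cluster's consensus is similar to its own
    (pairwise similarity strictly above ``edge_threshold``).  With no
    high-stringency pool all flags are False and a warning is emitted.
    """
    if clusters_high is None:
        warnings.warn(
            "no high-stringency clusters given; no cluster can be flagged "
            "highly populated",
            stacklevel=2,
        )
        clusters_high = []
    high_consensi = [c.consensus for c in clusters_high]
    ranked = sorted(clusters_low, key=lambda c: (-c.count_share, c.consensus))
    out = []
    for cluster in ranked:
        flagged = cluster.count_share >= min_share and any(
            pairwise_similarity(cluster.consensus, h) > edge_threshold
            for h in high_consensi
        )
        out.append((cluster, flagged))
    return out


def clusters_to_frame(ranked: list[tuple[Cluster, bool]]) -> pd.DataFrame:
    rows = []
    for idx, (cluster, flagged) in enumerate(ranked, start=1):
        for member in sorted(cluster.members):
            rows.append(
                {
                    "cluster_id": idx,
                    "member": member,
                    "count": cluster.members[member],
                    "cluster_size": cluster.size,
                    "count_share": cluster.count_share,
                    "consensus": cluster.consensus,
                    "highly_populated": flagged,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "cluster_id", "member", "count", "cluster_size", "count_share",
            "consensus", "highly_populated",
        ],
    )


def graph_to_edgelist(graph: nx.Graph, path) -> None:
    """Write the similarity graph as a weighted edge list (TSV)."""
    with open(path, "w") as fh:
        fh.write("node_a\tnode_b\tsimilarity\n")
        for u, v, d in sorted(graph.edges(data=True)):
            fh.write("%s\t%s\t%.6f\n" % (u, v, d["weight"]))
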