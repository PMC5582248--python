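"""Overlapping gene clusters via link communities.

Clusters edges (links) of a protein-interaction subnetwork rather than
nodes: adjacent links are scored by the Jaccard coefficient of the
inclusive neighborhoods of their non-shared endpoints, merged by
single-linkage agglomeration, and the dendrogram is cut where the
partition density is maximal.  Genes inherit (possibly multiple) cluster
memberships from their edges, which exposes overlapping and nested
communities that node partitioning cannot represent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

__all__ = [
    "PPIGraph",
    "LinkCommunityResult",
    "build_subnetwork",
    "link_jaccard",
    "partition_density",
    "cluster_links",
    "report_membership",
    "find_nested",
]

Edge = tuple[str, str]


def _norm_edge(u: str, v: str) -> Edge:
    return (u, v) if u <= v else (v, u)


@dataclass
class PPIGraph:
    """Undirected protein-interaction graph with optional edge scores."""

    edges: tuple[Edge, ...]
    scores: dict[Edge, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[Edge] = set()
        norm: list[Edge] = []
        for u, v in self.edges:
            if u == v:
                raise ValueError(f"self-loop on {u!r}")
            e = _norm_edge(u, v)
            if e in seen:
                raise ValueError(f"duplicate edge {e}")
            seen.add(e)
            norm.append(e)
        self.edges = tuple(norm)
        self.scores = {_norm_edge(*k): float(v) for k, v in self.scores.items()}

    @property
    def nodes(self) -> set[str]:
        return {n for e in self.edges for n in e}

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for e in self.edges:
            g.add_edge(*e, score=self.scores.get(e))
        return g


@dataclass
class LinkCommunityResult:
    """Outcome of link clustering: the cut, its clusters and diagnostics.

    ``clusters`` partition the edge set at ``cut_height``;
    ``density_curve`` holds (height, partition density) over all merge
    heights scanned; ``node_membership`` maps each gene to the ids of the
    clusters its edges fall in; ``nested_pairs`` lists (inner, outer)
    cluster ids whose node sets are strictly nested.
    """

    merge_tree: np.ndarray
    cut_height: float
    density_curve: tuple[tuple[float, float], ...]
    clusters: tuple[frozenset[Edge], ...]
    node_membership: dict[str, frozenset[int]]
    nested_pairs: tuple[tuple[int, int], ...]

    @property
    def max_density(self) -> float:
        return max(d for _, d in self.density_curve)

    def cluster_nodes(self, cid: int) -> frozenset[str]:
        return frozenset(n for e in self.clusters[cid] for n in e)


def build_subnetwork(
    de_genes: Iterable[str],
    ppi: PPIGraph,
    disease_genes: Iterable[str],
    *,
    disease_filter: str = "any",
    min_score: float | None = None,
) -> tuple[PPIGraph, dict[str, int]]:
    """Restrict a PPI edge list to DE genes, then to disease-linked pairs.

    Keeps edges whose both endpoints are differentially expressed and
    whose endpoints include at least one (``disease_filter="any"``) or
    require both (``"both"``) disease genes; edges below ``min_score``
    are dropped first when scores are present.  Returns the filtered
    graph and the edge count surviving each stage.
    """
    if disease_filter not in ("any", "both"):
        raise ValueError("disease_filter must be 'any' or 'both'")
    de = set(de_genes)
    dis = set(disease_genes)
    counts = {"input": len(ppi.edges)}

    edges = list(ppi.edges)
    if min_score is not None:
        edges = [e for e in edges if ppi.scores.get(e, 0.0) >= min_score]
    counts["score"] = len(edges)

    edges = [e for e in edges if e[0] in de and e[1] in de]
    counts["de"] = len(edges)

    if disease_filter == "any":
        edges = [e for e in edges if e[0] in dis or e[1] in dis]
    else:
        edges = [e for e in edges if e[0] in dis and e[1] in dis]
    counts["disease"] = len(edges)

    if not edges:
        warnings.warn("subnetwork filter left no edges", stacklevel=2)
    sub = PPIGraph(tuple(edges), {e: s for e, s in ppi.scores.items() if e in set(edges)})
    return sub, counts


def link_jaccard(graph: PPIGraph | nx.Graph, edge_a: Edge, edge_b: Edge) -> float:
    """Similarity of two links sharing a node.

    For edges (i, k) and (j, k) it is |n+(i) ∩ n+(j)| / |n+(i) ∪ n+(j)|
    with n+(x) the inclusive neighborhood of x (x and its neighbors).
    Identical edges score 1; edges with no common node score 0 by
    convention.
    """
    g = graph.to_networkx() if isinstance(graph, PPIGraph) else graph
    a, b = set(edge_a), set(edge_b)
    shared = a & b
    if len(shared) == 2:
        return 1.0
    if not shared:
        return 0.0
    i = (a - shared).pop()
    j = (b - shared).pop()
    ni = set(g[i]) | {i}
    nj = set(g[j]) | {j}
    return len(ni & nj) / len(ni | nj)


def partition_density(
    clusters: Sequence[Iterable[Edge]], n_edges_total: int
) -> float:
    """Partition density D of an edge partition.

    D = (2/M) Σ_c m_c (m_c - n_c + 1) / ((n_c - 2)(n_c - 1)), summed over
    clusters with more than 2 nodes; smaller clusters contribute 0 (the
    formula is undefined there).
    """
    if n_edges_total <= 0:
        raise ValueError("n_edges_total must be positive")
    total = 0.0
    for edges in clusters:
        es = list(edges)
        m = len(es)
        n = len({x for e in es for x in e})
        if n > 2:
            total += m * (m - n + 1) / ((n - 2) * (n - 1))
    return 2.0 * total / n_edges_total


def _link_distance_matrix(graph: PPIGraph) -> tuple[list[Edge], np.ndarray]:
    g = graph.to_networkx()
    edges = sorted(graph.edges)
    m = len(edges)
    neigh = {n: set(g[n]) | {n} for n in g}
    dist = np.ones((m, m))
    np.fill_diagonal(dist, 0.0)
    # only adjacent link pairs can be closer than the maximal distance 1
    by_node: dict[str, list[int]] = {}
    for idx, (u, v) in enumerate(edges):
        by_node.setdefault(u, []).append(idx)
        by_node.setdefault(v, []).append(idx)
    for node, idxs in by_node.items():
        for a_pos in range(len(idxs)):
            for b_pos in range(a_pos + 1, len(idxs)):
                ia, ib = idxs[a_pos], idxs[b_pos]
                i = (set(edges[ia]) - {node}).pop()
                j = (set(edges[ib]) - {node}).pop()
                ni, nj = neigh[i], neigh[j]
                sim = len(ni & nj) / len(ni | nj)
                d = 1.0 - sim
                if d < dist[ia, ib]:
                    dist[ia, ib] = dist[ib, ia] = d
    return edges, dist


def cluster_links(graph: PPIGraph) -> LinkCommunityResult:
    """Cluster the links of ``graph`` and cut at maximal partition density.

    Single-linkage agglomeration on distance 1 - Jaccard (non-adjacent
    links at distance 1); every merge height is scanned, the cut is the
    height maximizing D with ties broken toward the smallest height.
    """
    if len(graph.edges) < 2:
        raise ValueError("need at least 2 edges to cluster links")
    edges, dist = _link_distance_matrix(graph)
    z = linkage(squareform(dist, checks=False), method="single")

    heights = sorted({0.0, *z[:, 2]})
    best_h, best_d, best_labels = 0.0, -np.inf, None
    curve = []
    for h in heights:
        labels = fcluster(z, t=h, criterion="distance")
        groups: dict[int, list[Edge]] = {}
        for lab, e in zip(labels, edges):
            groups.setdefault(int(lab), []).append(e)
        d = partition_density(list(groups.values()), len(edges))
        curve.append((float(h), float(d)))
        if d > best_d:  # strict: ties keep the smallest height
            best_h, best_d, best_labels = float(h), float(d), labels

    groups = {}
    for lab, e in zip(best_labels, edges):
        groups.setdefault(int(lab), []).append(e)
    clusters = tuple(frozenset(v) for _, v in sorted(groups.items()))

    membership: dict[str, set[int]] = {}
    for cid, cl in enumerate(clusters):
        for e in cl:
            for n in e:
                membership.setdefault(n, set()).add(cid)
    node_membership = {n: frozenset(s) for n, s in membership.items()}

    result = LinkCommunityResult(
        merge_tree=z,
        cut_height=best_h,
        density_curve=tuple(curve),
        clusters=clusters,
        node_membership=node_membership,
        nested_pairs=(),
    )
    result.nested_pairs = find_nested(result)
    return result


def report_membership(
    result: LinkCommunityResult, min_clusters: int = 1
) -> list[tuple[str, int]]:
    """Genes belonging to more than ``min_clusters`` clusters.

    Sorted by descending membership count, then by gene name.
    """
    rows = [
        (g, len(cids))
        for g, cids in result.node_membership.items()
        if len(cids) > min_clusters
    ]
    return sorted(rows, key=lambda r: (-r[1], r[0]))


def find_nested(result: LinkCommunityResult) -> tuple[tuple[int, int], ...]:
    """All ordered (inner, outer) cluster pairs with strictly nested node sets."""
    node_sets = [result.cluster_nodes(c) for c in range(len(result.clusters))]
    pairs = [
        (i, j)
        for i in range(len(node_sets))
        for j in range(len(node_sets))
        if i != j and node_sets[i] < node_sets[j]
    ]
    return tuple(pairs)
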