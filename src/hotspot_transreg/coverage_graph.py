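"""Hotspot-coverage graph: meet/min similarity, clustering, coverage summaries.

Each candidate gene g covers a set of hotspots HS(g) — the hotspots with at
least one hit of its motif.  Pairwise coverage similarity is the meet/min
coefficient |HS(gi) n HS(gj)| / min(|HS(gi)|, |HS(gj)|).  Genes are grouped
either by dropping edges below a weight threshold and taking connected
components, or by average-linkage hierarchical clustering on distance 1 - w
cut at k clusters; on well-separated graphs the two agree.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

CoverageMap = Mapping[str, set[str]]


class CoverageError(ValueError):
    pass


def meet_min_weight(hs_i: set[str], hs_j: set[str]) -> float:
    """|A n B| / min(|A|, |B|): 1 when one coverage set contains the other."""
    if not hs_i or not hs_j:
        raise CoverageError("meet/min weight undefined for an empty hotspot set")
    return len(hs_i & hs_j) / min(len(hs_i), len(hs_j))


def coverage_from_hits(hits, genes: Sequence[str] | None = None) -> dict[str, set[str]]:
    """HS(g) per gene from a scan hit list (hits carry motif and region ids)."""
    cov: dict[str, set[str]] = {}
    for h in hits:
        cov.setdefault(h.motif, set()).add(h.region_id)
    if genes is not None:
        cov = {g: cov.get(g, set()) for g in genes}
    return cov


@dataclass
class CoverageGraph:
    """Complete weighted graph over genes; symmetric with unit diagonal."""

    genes: list[str]
    weights: np.ndarray

    def weight(self, gi: str, gj: str) -> float:
        i, j = self.genes.index(gi), self.genes.index(gj)
        return float(self.weights[i, j])


def build_graph(coverage: CoverageMap) -> CoverageGraph:
    genes = sorted(coverage)
    if not genes:
        raise CoverageError("no genes to build a coverage graph from")
    for g in genes:
        if not coverage[g]:
            raise CoverageError(f"gene {g!r} covers no hotspots")
    n = len(genes)
    w = np.eye(n)
    for i, j in combinations(range(n), 2):
        w[i, j] = w[j, i] = meet_min_weight(coverage[genes[i]], coverage[genes[j]])
    return CoverageGraph(genes, w)


def _order_clusters(clusters: list[list[str]]) -> list[list[str]]:
    clusters = [sorted(c) for c in clusters]
    clusters.sort(key=lambda c: (-len(c), c[0]))
    return clusters


def threshold_clusters(graph: CoverageGraph, w_t: float) -> list[list[str]]:
    """Keep edges with w >= w_t; clusters are the connected components,
    reported in descending size then lexicographic order."""
    if w_t < 0:  # w_t > 1 is allowed and yields all singletons
        raise CoverageError(f"w_t must be non-negative, got {w_t}")
    g = nx.Graph()
    g.add_nodes_from(graph.genes)
    n = len(graph.genes)
    for i, j in combinations(range(n), 2):
        if graph.weights[i, j] >= w_t:
            g.add_edge(graph.genes[i], graph.genes[j])
    return _order_clusters([list(c) for c in nx.connected_components(g)])


def hierarchical_clusters(graph: CoverageGraph, k: int, method: str = "average") -> list[list[str]]:
    """Agglomerative clustering on distance 1 - w, cut at k clusters."""
    n = len(graph.genes)
    if not (1 <= k <= n):
        raise CoverageError(f"k must be in [1, {n}], got {k}")
    if n == 1 or k == n:
        return _order_clusters([[g] for g in graph.genes] if k == n else [list(graph.genes)])
    dist = 1.0 - graph.weights
    np.fill_diagonal(dist, 0.0)
    z = linkage(squareform(dist, checks=False), method=method)
    labels = fcluster(z, t=k, criterion="maxclust")
    groups: dict[int, list[str]] = {}
    for gene, lab in zip(graph.genes, labels):
        groups.setdefault(int(lab), []).append(gene)
    return _order_clusters(list(groups.values()))


@dataclass
class CoverageSummary:
    cluster_sizes: list[int]  # genes per cluster
    cluster_union_sizes: list[int]  # hotspots covered per cluster
    pairwise_intersections: dict[tuple[int, int], int]
    venn_regions: dict[frozenset[int], int]  # exclusive cluster-combination counts
    total_covered: int
    uncovered: int


def coverage_summary(
    clusters: Sequence[Sequence[str]],
    coverage: CoverageMap,
    n_hotspots: int,
) -> CoverageSummary:
    """Per-cluster hotspot unions, all Venn regions and the uncovered count.

    The Venn region counts partition the overall union, so their sum equals
    ``total_covered`` and ``total_covered + uncovered == n_hotspots``.
    """
    unions = [set().union(*(coverage[g] for g in cl)) for cl in clusters]
    overall: set[str] = set().union(*unions) if unions else set()
    if len(overall) > n_hotspots:
        raise CoverageError("covered hotspots exceed the stated hotspot count")
    pairwise = {
        (i, j): len(unions[i] & unions[j]) for i, j in combinations(range(len(clusters)), 2)
    }
    venn: dict[frozenset[int], int] = {}
    for hs in overall:
        key = frozenset(i for i, u in enumerate(unions) if hs in u)
        venn[key] = venn.get(key, 0) + 1
    return CoverageSummary(
        cluster_sizes=[len(c) for c in clusters],
        cluster_union_sizes=[len(u) for u in unions],
        pairwise_intersections=pairwise,
        venn_regions=venn,
        total_covered=len(overall),
        uncovered=n_hotspots - len(overall),
    )
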