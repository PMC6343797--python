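"""Correlation-weighted dynamical network analysis.

Residues (and glycan rings) are graph nodes; an edge joins two nodes
whose residues stay in heavy-atom contact (within 4.5 Å in at least
75 % of frames, the dynamical-network convention) and carries weight
w_ij = −log|C_ij| from the DCCM, so strongly correlated residues are
"close".  Allosteric routes between a source (antigen/paratope) and a
sink (receptor domain) are minimum-weight paths; suboptimal paths
within a weight tolerance of the optimum provide alternative routes.
Communities come from the Girvan–Newman edge-betweenness hierarchy cut
at maximum modularity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import islice

import networkx as nx
import numpy as np

from igg_allostery.contacts import ContactFrequencyTable
from igg_allostery.dynamics import CorrelationMatrix
from igg_allostery.errors import ConfigurationError


@dataclass
class Path:
    nodes: tuple
    weight: float


@dataclass
class PathResult:
    """Optimal + suboptimal simple paths, sorted by non-decreasing weight."""

    connected: bool
    optimal: Path | None
    suboptimal: list[Path] = field(default_factory=list)

    @property
    def all_paths(self) -> list[Path]:
        return ([self.optimal] if self.optimal else []) + self.suboptimal


def build_network(
    correlations: CorrelationMatrix,
    contact_table: ContactFrequencyTable,
    contact_cutoff_freq: float = 0.75,
) -> nx.Graph:
    """Build the residue network from a DCCM and a contact-frequency table.

    Edge (i, j) exists iff the residue pair's contact frequency is at
    least ``contact_cutoff_freq``; its weight is −log|C_ij|.  Pairs with
    C_ij = 0 carry infinite weight and are dropped; |C_ij| > 1 is an
    input error.
    """
    labels = {lab: k for k, lab in enumerate(correlations.node_labels)}
    g = nx.Graph()
    g.add_nodes_from(correlations.node_labels)
    for row in contact_table.table.itertuples(index=False):
        a, b, freq = row.resid_a, row.resid_b, row.frequency
        if freq < contact_cutoff_freq or a == b:
            continue
        if a not in labels or b not in labels:
            raise ConfigurationError(f"contact residue {a if a not in labels else b} not a DCCM node")
        c = correlations.values[labels[a], labels[b]]
        if abs(c) > 1 + 1e-9:
            raise ConfigurationError(f"|correlation| > 1 for pair ({a}, {b})")
        if abs(c) <= 0.0:
            continue
        g.add_edge(a, b, weight=float(-np.log(min(abs(c), 1.0))), correlation=float(c))
    return g


def communities(graph: nx.Graph) -> tuple[list[set], float]:
    """Girvan–Newman community hierarchy cut at maximum modularity.

    Returns (partition as a list of node sets, modularity).  The trivial
    one-community partition (per connected component) is included as a
    candidate, so a single clique is reported as one community.
    Modularity is evaluated on connectivity only (unweighted): edges
    already encode persistent contacts, and their −log|C| weights are
    distances, not affinities, so they must not be summed as such.
    """
    if graph.number_of_nodes() == 0:
        raise ConfigurationError("empty graph")
    base = [set(c) for c in nx.connected_components(graph)]
    candidates: list[list[set]] = [base]
    if graph.number_of_edges() > 0:
        for level in islice(nx.community.girvan_newman(graph), 0, graph.number_of_nodes() - 1):
            candidates.append([set(c) for c in level])
            if len(candidates[-1]) >= graph.number_of_nodes():
                break
    best, best_q = None, -np.inf
    for part in candidates:
        q = (
            nx.community.modularity(graph, part, weight=None)
            if graph.number_of_edges()
            else 0.0
        )
        if q > best_q + 1e-12:
            best, best_q = part, q
    return best, float(best_q)


def optimal_paths(
    graph: nx.Graph,
    source: set | list,
    sink: set | list,
    k_suboptimal: int = 25,
    tolerance: float = 20.0,
) -> PathResult:
    """Optimal and suboptimal source→sink paths.

    The optimal path is the minimum-total-weight simple path over all
    (source, sink) node pairs (Dijkstra); suboptimal paths are up to
    ``k_suboptimal`` further loop-free paths with total weight within
    ``tolerance`` of the optimum, enumerated in weight order (Yen).  A
    disconnected source/sink yields ``PathResult(connected=False, ...)``
    rather than an exception.
    """
    source = [s for s in source]
    sink = [t for t in sink]
    if not source or not sink:
        raise ConfigurationError("source and sink must be non-empty")
    for n in source + sink:
        if n not in graph:
            raise ConfigurationError(f"node {n!r} not in graph")

    def pweight(nodes) -> float:
        return float(sum(graph[u][v]["weight"] for u, v in zip(nodes, nodes[1:])))

    best: Path | None = None
    for s in source:
        lengths, paths = nx.single_source_dijkstra(graph, s, weight="weight")
        for t in sink:
            if t in lengths and (best is None or lengths[t] < best.weight):
                best = Path(tuple(paths[t]), float(lengths[t]))
    if best is None:
        return PathResult(connected=False, optimal=None)

    collected: dict[tuple, float] = {}
    for s in source:
        for t in sink:
            if not nx.has_path(graph, s, t):
                continue
            for nodes in nx.shortest_simple_paths(graph, s, t, weight="weight"):
                w = pweight(nodes)
                if w > best.weight + tolerance + 1e-12:
                    break
                collected[tuple(nodes)] = w
                if len(collected) > (k_suboptimal + 1) * 4:
                    break
    ranked = sorted(collected.items(), key=lambda kv: (kv[1], kv[0]))
    ranked = [Path(n, w) for n, w in ranked if n != best.nodes]
    return PathResult(connected=True, optimal=best, suboptimal=ranked[:k_suboptimal])


def export_edge_list(graph: nx.Graph) -> list[tuple]:
    """Edges as (node_a, node_b, weight, correlation) tuples, sorted."""
    rows = [
        (u, v, d["weight"], d.get("correlation", np.nan))
        for u, v, d in graph.edges(data=True)
    ]
    return sorted(rows)
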