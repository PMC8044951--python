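"""Functional-interaction subnetwork construction and hub topology.

The common DEGs are mapped onto an undirected gene-gene functional
interaction network; per-node topology (degree, neighborhood connectivity,
average shortest path length) then defines the hub genes. Neighborhood
connectivity of a node is the mean degree of its neighbors; the per-node
average shortest path length is the mean unweighted hop distance from the
node to every other node it can reach.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

__all__ = ["SubnetworkResult", "build_subnetwork", "node_metrics", "filter_hubs"]


@dataclass
class SubnetworkResult:
    graph: nx.Graph
    unmapped: list[str]  # query genes absent from the interaction data


def build_subnetwork(edge_graph: nx.Graph, genes) -> SubnetworkResult:
    """Induce the subnetwork of an interaction graph on a gene set.

    Genes present in the interaction data but with no surviving edge are
    kept as degree-0 nodes; genes absent from the data are reported in
    ``unmapped``.
    """
    genes = set(genes)
    if not genes:
        raise ValueError("empty gene set")
    mapped = genes & set(edge_graph.nodes)
    if not mapped:
        raise ValueError("none of the genes map to the interaction network")
    sub = nx.Graph(edge_graph.subgraph(mapped))
    return SubnetworkResult(graph=sub, unmapped=sorted(genes - mapped))


def node_metrics(graph: nx.Graph) -> pd.DataFrame:
    """Per-node topology metrics.

    Returns a gene-indexed DataFrame with columns ``degree``,
    ``neighborhood_connectivity`` (0 with ``nc_defined=False`` for isolated
    nodes), ``avg_shortest_path`` (0 with ``aspl_defined=False`` for
    isolated nodes), ``component_id`` and ``component_size``. The graph-wide
    mean degree is stored in ``df.attrs["mean_degree"]``.
    """
    nodes = sorted(graph.nodes)
    deg = dict(graph.degree())
    nc = nx.average_neighbor_degree(graph)

    # components ordered by size desc, then smallest member, for stable ids
    comps = sorted(
        (sorted(c) for c in nx.connected_components(graph)),
        key=lambda c: (-len(c), c[0]),
    )
    comp_of = {}
    for cid, members in enumerate(comps):
        for g in members:
            comp_of[g] = (cid, len(members))

    rows = []
    for g in nodes:
        k = deg[g]
        if k == 0:
            rows.append((g, 0, 0.0, False, 0.0, False, *comp_of[g]))
            continue
        dists = nx.single_source_shortest_path_length(graph, g)
        reach = [d for node, d in dists.items() if node != g]
        aspl = float(np.mean(reach)) if reach else 0.0
        rows.append((g, k, float(nc[g]), True, aspl, bool(reach), *comp_of[g]))

    df = pd.DataFrame(
        rows,
        columns=[
            "gene",
            "degree",
            "neighborhood_connectivity",
            "nc_defined",
            "avg_shortest_path",
            "aspl_defined",
            "component_id",
            "component_size",
        ],
    ).set_index("gene")
    df.attrs["mean_degree"] = float(df["degree"].mean()) if len(df) else 0.0
    return df


def filter_hubs(
    metrics: pd.DataFrame, nc_min: float = 20.0, aspl_min: float = 3.5
) -> set[str]:
    """Hub genes: neighborhood connectivity >= ``nc_min`` AND per-node
    average shortest path length >= ``aspl_min`` (inclusive bounds), among
    nodes in connected components of size >= 2.
    """
    if len(metrics) == 0:
        return set()
    eligible = metrics[metrics["component_size"] >= 2]
    hubs = eligible[
        (eligible["neighborhood_connectivity"] >= nc_min)
        & (eligible["avg_shortest_path"] >= aspl_min)
    ]
    return set(hubs.index)
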