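"""Co-expression network construction, hubs, components, neighborhoods.

Nodes are transcripts touched by at least one significant extreme
correlation; edges carry the signed Pearson r. Hubs are nodes whose degree
exceeds mean + 2 sd of the degree distribution (sample sd, strict
inequality); hub-centrality nodes apply the same rule to exact unnormalized
betweenness centrality. "Clusters" are connected components, reported
largest first.
"""

from __future__ import annotations

import warnings
from typing import Dict, List, Optional, Sequence, Tuple

import networkx as nx
import numpy as np
import pandas as pd


def build_network(
    edges: pd.DataFrame,
    de_table: Optional[pd.DataFrame] = None,
    annotation: Optional[pd.DataFrame] = None,
    rif_table: Optional[pd.DataFrame] = None,
) -> nx.Graph:
    """Simple undirected graph from an extreme-edge table (node_a, node_b, r).

    Node attributes joined by transcript id: biotype (misc + warning when
    unannotated), de_comparisons, is_tf, rif_significant; hub flags start
    False and are set by :func:`classify_hubs`.
    """
    g = nx.Graph()
    for _, row in edges.iterrows():
        a, b = row["node_a"], row["node_b"]
        if a == b:
            continue
        g.add_edge(a, b, r=float(row["r"]))

    de_map: Dict[str, List[str]] = {}
    if de_table is not None and len(de_table):
        flagged = de_table[de_table["is_de"]]
        for tid, grp in flagged.groupby("transcript_id"):
            de_map[tid] = sorted(grp["comparison"].unique())
    rif_sig = set()
    if rif_table is not None and len(rif_table):
        rif_sig = set(rif_table.loc[rif_table["significant"], "regulator_id"])

    missing_annotation = []
    for node in g.nodes:
        if annotation is not None and node in annotation.index:
            g.nodes[node]["biotype"] = annotation.loc[node, "biotype"]
            g.nodes[node]["is_tf"] = bool(annotation.loc[node, "is_tf"])
        else:
            missing_annotation.append(node)
            g.nodes[node]["biotype"] = "misc"
            g.nodes[node]["is_tf"] = False
        g.nodes[node]["de_comparisons"] = de_map.get(node, [])
        g.nodes[node]["rif_significant"] = node in rif_sig
        g.nodes[node]["hub"] = False
        g.nodes[node]["hub_centrality"] = False
    if missing_annotation and annotation is not None:
        warnings.warn(
            f"{len(missing_annotation)} nodes without annotation set to biotype 'misc'"
        )
    return g


def classify_hubs(g: nx.Graph, sd_ddof: int = 1) -> nx.Graph:
    """Set hub / hub_centrality flags (degree resp. betweenness
    > mean + 2 sd). Modifies and returns the graph."""
    if g.number_of_nodes() < 2:
        raise ValueError("need >= 2 nodes to classify hubs")
    degrees = np.array([d for _, d in g.degree()], dtype=float)
    betweenness = nx.betweenness_centrality(g, normalized=False)
    bet = np.array([betweenness[n] for n in g.nodes], dtype=float)

    for values, attr in ((degrees, "hub"), (bet, "hub_centrality")):
        sd = values.std(ddof=sd_ddof) if len(values) > sd_ddof else 0.0
        if sd == 0:
            warnings.warn(f"zero spread in {attr} statistic; no {attr} flags set")
            threshold = np.inf
        else:
            threshold = values.mean() + 2.0 * sd
        for node, val in zip(g.nodes, values):
            g.nodes[node][attr] = bool(val > threshold)
    return g


def components(g: nx.Graph) -> List[List[str]]:
    """Connected components, largest first; ties broken by the
    lexicographically smallest member. Members sorted within a component."""
    comps = [sorted(c) for c in nx.connected_components(g)]
    comps.sort(key=lambda c: (-len(c), c[0]))
    return comps


def neighborhood(
    g: nx.Graph, node: str, order: int = 2
) -> Tuple[Dict[str, float], List[str]]:
    """First neighbors (with signed r) and, at order 2, second neighbors.

    Second neighbors are neighbors-of-neighbors excluding the node itself
    and its first neighbors.
    """
    if node not in g:
        raise KeyError(f"node {node!r} not in network")
    if order not in (1, 2):
        raise ValueError("order must be 1 or 2")
    first = {nbr: float(g.edges[node, nbr]["r"]) for nbr in g.neighbors(node)}
    if order == 1:
        return first, []
    second = set()
    for nbr in first:
        second.update(g.neighbors(nbr))
    second -= set(first)
    second.discard(node)
    return first, sorted(second)


def neighborhood_summary(g: nx.Graph, node: str) -> Dict[str, object]:
    """Degree and signed-correlation split of a node's direct neighborhood."""
    first, second = neighborhood(g, node, order=2)
    positive = sorted(n for n, r in first.items() if r > 0)
    negative = sorted(n for n, r in first.items() if r < 0)
    return {
        "node": node,
        "degree": len(first),
        "n_positive": len(positive),
        "n_negative": len(negative),
        "positive_neighbors": positive,
        "negative_neighbors": negative,
        "second_neighbors": second,
    }


def network_summary(g: nx.Graph) -> Dict[str, object]:
    comps = components(g)
    return {
        "n_nodes": g.number_of_nodes(),
        "n_edges": g.number_of_edges(),
        "n_components": len(comps),
        "largest_component_size": len(comps[0]) if comps else 0,
        "n_hubs": sum(1 for _, d in g.nodes(data=True) if d.get("hub")),
        "n_hub_centrality": sum(
            1 for _, d in g.nodes(data=True) if d.get("hub_centrality")
        ),
    }
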