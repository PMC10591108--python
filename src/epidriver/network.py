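"""Interaction networks over target genes from STRING-style score tables.

Edges with combined_score ≥ 700 (high confidence) form the graph; edge
weight is combined_score/1000. Hubs are nodes of degree ≥ 5; "clusters" are
connected components that contain at least one hub and whose mean internal
edge weight is at least 0.05.
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import pandas as pd

from .exceptions import ValidationError


def load_interactions(
    table: str | Path | pd.DataFrame, score_threshold: float = 700
) -> nx.Graph:
    """Build the interaction graph from a (protein1, protein2,
    combined_score) table; threshold is inclusive, duplicate pairs collapse
    to the maximum score, self-loops are dropped. Scores outside [0, 1000]
    raise with the offending line number."""
    if isinstance(table, pd.DataFrame):
        df = table
    else:
        df = pd.read_csv(table, sep="\t")
    required = {"protein1", "protein2", "combined_score"}
    if not required <= set(df.columns):
        raise ValidationError(f"interaction table needs columns {sorted(required)}")
    scores = pd.to_numeric(df["combined_score"], errors="coerce")
    bad = (scores.isna() | (scores < 0) | (scores > 1000)).to_numpy()
    if bad.any():
        pos = int(bad.argmax())
        # +2: header line plus 1-based numbering.
        raise ValidationError(
            f"line {pos + 2}: combined_score {df['combined_score'].iloc[pos]!r} outside [0, 1000]"
        )
    g = nx.Graph()
    kept = df[scores >= score_threshold]
    for p1, p2, s in zip(kept["protein1"], kept["protein2"], scores[scores >= score_threshold]):
        if p1 == p2:
            continue
        w = float(s) / 1000.0
        if g.has_edge(p1, p2):
            g[p1][p2]["weight"] = max(g[p1][p2]["weight"], w)
        else:
            g.add_edge(p1, p2, weight=w)
    return g


def subgraph(graph: nx.Graph, genes: set[str]) -> nx.Graph:
    """Induced subgraph on genes ∩ nodes; members without internal edges are
    retained as degree-0 nodes."""
    return graph.subgraph(set(genes) & set(graph.nodes)).copy()


def hub_nodes(graph: nx.Graph, min_degree: int = 5) -> list[str]:
    """Nodes of degree ≥ min_degree, sorted by (degree desc, id asc)."""
    hubs = [(n, d) for n, d in graph.degree if d >= min_degree]
    hubs.sort(key=lambda nd: (-nd[1], str(nd[0])))
    return [n for n, _d in hubs]


def filter_clusters(
    graph: nx.Graph, min_degree: int = 5, min_avg_weight: float = 0.05
) -> list[set[str]]:
    """Connected components holding ≥ 1 node of full-graph degree ≥
    min_degree and with mean internal edge weight ≥ min_avg_weight (0–1
    scale). Edgeless components have no internal weight and are dropped."""
    clusters: list[set[str]] = []
    degrees = dict(graph.degree)
    for comp in nx.connected_components(graph):
        if not any(degrees[n] >= min_degree for n in comp):
            continue
        weights = [d["weight"] for _u, _v, d in graph.subgraph(comp).edges(data=True)]
        if not weights:
            continue
        if sum(weights) / len(weights) >= min_avg_weight:
            clusters.append(set(comp))
    clusters.sort(key=lambda c: (-len(c), sorted(c)[0]))
    return clusters


def graph_summary(graph: nx.Graph, min_degree: int = 5, min_avg_weight: float = 0.05) -> dict:
    hubs = hub_nodes(graph, min_degree)
    clusters = filter_clusters(graph, min_degree, min_avg_weight)
    return {
        "n_nodes": graph.number_of_nodes(),
        "n_edges": graph.number_of_edges(),
        "n_hubs": len(hubs),
        "hubs": hubs,
        "n_clusters": len(clusters),
        "largest_cluster": max((len(c) for c in clusters), default=0),
    }
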