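"""Signed functional subnetworks for unbalanced processes.

Member cytokines of a process become nodes carrying their participation
sign (positive/negative G, conventionally drawn blue/red) and weight |G|;
edges come from a user-supplied STRING-style functional-interaction list,
restricted to pairs where both endpoints are members.  No live database
queries are made — the edge list is an input, which keeps runs offline and
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .datamodel import EdgeList
from .surprisal import UnbalancedProcess

__all__ = ["ProcessSubnetwork", "build_subnetwork", "write_graphml", "edges_frame"]


@dataclass
class ProcessSubnetwork:
    """Signed interaction subnetwork of one unbalanced process."""

    alpha: int
    graph: nx.Graph

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def build_subnetwork(
    process: UnbalancedProcess,
    edges: EdgeList,
    min_score: float | None = None,
) -> ProcessSubnetwork:
    """Restrict an edge list to one process's member cytokines.

    Nodes are the members with ``sign`` ("positive"/"negative" from the
    signed G weight) and ``weight`` (|G|) attributes; edges keep both
    endpoints inside the membership, optionally filtered by confidence
    ``min_score``.  Isolated members are retained; empty membership gives
    an empty network.
    """
    g = nx.Graph()
    for cyt, w in process.member_weights.items():
        g.add_node(
            str(cyt),
            sign="positive" if w >= 0 else "negative",
            weight=float(abs(w)),
            G=float(w),
        )
    members = set(g.nodes)
    for _, row in edges.table.iterrows():
        a, b = str(row["a"]), str(row["b"])
        if a not in members or b not in members:
            continue
        score = float(row["score"]) if edges.has_scores and pd.notna(row.get("score")) else None
        if min_score is not None and (score is None or score < min_score):
            continue
        attrs = {"score": score} if score is not None else {}
        g.add_edge(a, b, **attrs)
    return ProcessSubnetwork(alpha=process.alpha, graph=g)


def write_graphml(net: ProcessSubnetwork, path) -> None:
    nx.write_graphml(net.graph, path)


def edges_frame(net: ProcessSubnetwork) -> pd.DataFrame:
    """Tidy edge table: a, b, score (NaN when unscored)."""
    rows = [
        {"a": a, "b": b, "score": data.get("score")}
        for a, b, data in net.graph.edges(data=True)
    ]
    return pd.DataFrame(rows, columns=["a", "b", "score"])
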