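"""Shared attributed-graph container and the centrality statistics.

All term and gene networks in the pipeline use :class:`Network`, a thin
wrapper over a networkx graph carrying signed edges and per-node regulation
labels. The three statistics every figure-style output needs:

* degree — number of *distinct neighbors* (a reciprocal directed pair
  contributes one neighbor but one to each of indegree/outdegree; this is
  the only convention under which a printed hub row like degree 17 with
  indegree 16 / outdegree 16 is self-consistent);
* betweenness — Brandes shortest-path betweenness normalized to [0, 1] by
  (N-1)(N-2) for directed and (N-1)(N-2)/2 for undirected graphs;
* k-core — iterative-pruning core index on the undirected projection.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import pandas as pd

POSITIVE = "+"
NEGATIVE = "-"


@dataclass
class Network:
    """Attributed node/edge graph; ``graph`` is nx.DiGraph or nx.Graph."""

    graph: nx.Graph | nx.DiGraph

    def __post_init__(self) -> None:
        loops = list(nx.selfloop_edges(self.graph))
        if loops:
            raise ValueError(f"self-loops are not allowed: {loops[:3]}")

    @property
    def directed(self) -> bool:
        return self.graph.is_directed()

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    def undirected_projection(self) -> nx.Graph:
        """Simple undirected view (reciprocal pairs collapse to one edge)."""
        return nx.Graph(self.graph)

    def annotate(self) -> None:
        """Store degree/indegree/outdegree/betweenness/k_core on the nodes."""
        stats = degree_stats(self)
        bc = betweenness(self)
        kc = k_core(self)
        for node in self.graph.nodes:
            row = stats.loc[node]
            self.graph.nodes[node]["degree"] = int(row["degree"])
            self.graph.nodes[node]["indegree"] = int(row["indegree"])
            self.graph.nodes[node]["outdegree"] = int(row["outdegree"])
            self.graph.nodes[node]["betweenness"] = float(bc[node])
            self.graph.nodes[node]["k_core"] = int(kc[node])

    def set_regulation(self, regulation: dict[str, str], default: str = "both") -> None:
        for node in self.graph.nodes:
            self.graph.nodes[node]["regulation"] = regulation.get(node, default)

    # ------------------------------------------------------------------
    # serialization

    def write_graphml(self, path: str | Path) -> None:
        nx.write_graphml(self.graph, str(path))

    @classmethod
    def read_graphml(cls, path: str | Path) -> "Network":
        return cls(nx.read_graphml(str(path)))

    def write_edge_tsv(self, path: str | Path) -> None:
        rows = [
            {"source": u, "target": v, "sign": d.get("sign", POSITIVE)}
            for u, v, d in self.graph.edges(data=True)
        ]
        pd.DataFrame(rows, columns=["source", "target", "sign"]).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def read_edge_tsv(cls, path: str | Path, directed: bool) -> "Network":
        df = pd.read_csv(path, sep="\t", dtype=str)
        g: nx.Graph | nx.DiGraph = nx.DiGraph() if directed else nx.Graph()
        for row in df.itertuples(index=False):
            g.add_edge(row.source, row.target, sign=row.sign)
        return cls(g)


def degree_stats(network: Network) -> pd.DataFrame:
    """Per-node (degree, indegree, outdegree); distinct-neighbor degree."""
    g = network.graph
    proj = network.undirected_projection()
    rows = {}
    for node in g.nodes:
        if network.directed:
            indeg, outdeg = g.in_degree(node), g.out_degree(node)
        else:
            indeg = outdeg = g.degree(node)
        rows[node] = {"degree": proj.degree(node), "indegree": indeg, "outdegree": outdeg}
    return pd.DataFrame.from_dict(rows, orient="index", dtype=int)


def betweenness(network: Network) -> dict[str, float]:
    """Normalized shortest-path betweenness centrality in [0, 1]."""
    g = network.graph
    if g.number_of_nodes() < 3:
        return {node: 0.0 for node in g.nodes}
    return nx.betweenness_centrality(g, normalized=True)


def k_core(network: Network) -> dict[str, int]:
    """Core index per node on the undirected projection."""
    proj = network.undirected_projection()
    if proj.number_of_nodes() == 0:
        return {}
    return nx.core_number(proj)
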