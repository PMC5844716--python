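"""Directed signal network over differential genes; hubs by betweenness.

The network is induced from a curated signed, directed gene-gene interaction
edge list: an edge survives only when both endpoints are differential.
Nodes carry the up/down trend from the screening stage and the full degree /
indegree / outdegree / betweenness statistics; hub genes are ranked by
betweenness centrality (then degree, then id) in the shape of a published
hub table (gene, betweenness, degree, indegree, outdegree, trend).
"""

from __future__ import annotations

import logging
from pathlib import Path

import networkx as nx
import pandas as pd

from hubnet.graphs import Network, betweenness, degree_stats

logger = logging.getLogger(__name__)

RANK_COLUMNS = ["gene", "betweenness", "degree", "indegree", "outdegree", "trend"]


def build_signal_network(
    differential_genes,
    interaction_edges: pd.DataFrame,
    trend_of: dict[str, str] | None = None,
) -> Network:
    """Induce the directed interaction network on the differential genes.

    Parameters
    ----------
    differential_genes
        Gene ids that passed the differential screen.
    interaction_edges
        Frame with columns ``source``, ``target``, ``sign`` (+/-).
    trend_of
        Optional gene -> up/down mapping used to color nodes.
    """
    de = set(differential_genes)
    g = nx.DiGraph()
    dropped = 0
    for row in interaction_edges.itertuples(index=False):
        u, v, sign = str(row.source), str(row.target), str(row.sign)
        if u == v:
            dropped += 1
            continue
        if u in de and v in de:
            g.add_edge(u, v, sign=sign)
        else:
            dropped += 1
    if dropped:
        logger.info("dropped %d interaction edges outside the differential set", dropped)
    if g.number_of_edges() == 0:
        logger.warning("no interaction edge connects two differential genes")
    net = Network(g)
    if trend_of is not None:
        net.set_regulation(trend_of)
    net.annotate()
    return net


def rank_hub_genes(network: Network) -> pd.DataFrame:
    """Hub table sorted by descending betweenness, then degree, then id."""
    if network.n_nodes == 0:
        return pd.DataFrame(columns=RANK_COLUMNS)
    stats = degree_stats(network)
    bc = betweenness(network)
    rows = []
    for node in network.nodes():
        rows.append(
            {
                "gene": node,
                "betweenness": bc[node],
                "degree": int(stats.loc[node, "degree"]),
                "indegree": int(stats.loc[node, "indegree"]),
                "outdegree": int(stats.loc[node, "outdegree"]),
                "trend": network.graph.nodes[node].get("regulation", "both"),
            }
        )
    out = pd.DataFrame(rows, columns=RANK_COLUMNS)
    return out.sort_values(
        ["betweenness", "degree", "gene"], ascending=[False, False, True]
    ).reset_index(drop=True)


def write_hub_table(rank: pd.DataFrame, path: str | Path) -> None:
    out = rank.copy()
    out["betweenness"] = out["betweenness"].map(lambda v: f"{v:.7g}")
    out.to_csv(path, sep="\t", index=False)
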