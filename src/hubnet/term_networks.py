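"""Term-level networks: the GO map and the significant-pathway network.

The GO map links significantly enriched terms by their ontology hierarchy,
with a directed edge from the more specific (lower-ranking) term to its
nearest significant ancestor — an ancestor reachable through a path that
contains no other significant term. Connected components of size >= 2 are
reported as sub-networks.

The pathway network places the significantly enriched pathways as nodes and
keeps every curated pathway-pathway adjacency whose two endpoints are both
significant; hub pathways are ranked by degree. The curated adjacency is an
explicit two-column input; when none is available a helper derives one from
shared-gene counts in the annotation collection.
"""

from __future__ import annotations

import itertools
from pathlib import Path

import networkx as nx
import pandas as pd

from hubnet.enrichment import (
    GeneSetCollection,
    PATHWAY_CATEGORIES,
    significant_terms,
    term_regulation,
)
from hubnet.graphs import Network


def build_go_map(
    records: pd.DataFrame, parent_edges: list[tuple[str, str]]
) -> Network:
    """Directed map of significant GO terms linked child -> ancestor.

    Parameters
    ----------
    records
        Enrichment records (all directions) from :func:`hubnet.enrichment.enrich`.
    parent_edges
        (child, parent) term pairs; must form a DAG.

    An edge u -> v is drawn when v is a significant ancestor of the
    significant term u and some hierarchy path from u to v passes through no
    other significant term, i.e. each term points at its nearest significant
    ancestors.
    """
    dag = nx.DiGraph()
    dag.add_edges_from(parent_edges)
    if not nx.is_directed_acyclic_graph(dag):
        cycle = nx.find_cycle(dag)
        raise ValueError(f"parent_edges contain a cycle through {cycle[0][0]!r}")

    sig = significant_terms(records, category="GO")
    sig_ids = sorted(set(sig["term_id"]))
    g = nx.DiGraph()
    g.add_nodes_from(sig_ids)
    sig_set = set(sig_ids)
    for term in sig_ids:
        if term not in dag:
            continue
        # BFS upward, stopping at the first significant term on each branch
        frontier = [p for _, p in dag.out_edges(term)]
        seen = set()
        while frontier:
            node = frontier.pop()
            if node in seen:
                continue
            seen.add(node)
            if node in sig_set:
                g.add_edge(term, node)
                continue
            frontier.extend(p for _, p in dag.out_edges(node))

    net = Network(g)
    net.set_regulation(term_regulation(records))
    net.annotate()
    return net


def sub_networks(network: Network, min_size: int = 2) -> list[set[str]]:
    """Weakly connected components of at least ``min_size`` nodes."""
    g = network.graph
    comps = (
        nx.weakly_connected_components(g)
        if network.directed
        else nx.connected_components(g)
    )
    out = [set(c) for c in comps if len(c) >= min_size]
    return sorted(out, key=lambda c: (-len(c), min(c)))


def write_subnetwork_summary(components: list[set[str]], path: str | Path) -> None:
    rows = [
        {"component": i + 1, "size": len(comp), "members": ";".join(sorted(comp))}
        for i, comp in enumerate(components)
    ]
    pd.DataFrame(rows, columns=["component", "size", "members"]).to_csv(
        path, sep="\t", index=False
    )


def build_pathway_network(
    records: pd.DataFrame, pathway_adjacency: list[tuple[str, str]]
) -> Network:
    """Undirected network of significant pathways over a curated adjacency."""
    sig = significant_terms(records, category="pathway")
    sig_ids = sorted(set(sig["term_id"]))
    sig_set = set(sig_ids)
    known = set(records.loc[records["category"].isin(PATHWAY_CATEGORIES), "term_id"])
    g = nx.Graph()
    g.add_nodes_from(sig_ids)
    for a, b in pathway_adjacency:
        if a not in known or b not in known:
            raise ValueError(f"adjacency references unknown pathway: {(a, b)}")
        if a == b:
            continue
        if a in sig_set and b in sig_set:
            g.add_edge(a, b, sign="+")
    net = Network(g)
    net.set_regulation(term_regulation(records))
    net.annotate()
    return net


def hub_pathway(network: Network) -> pd.DataFrame:
    """Pathways ranked by descending degree (lexicographic tie-break)."""
    if network.n_nodes == 0:
        return pd.DataFrame(columns=["term_id", "degree"])
    from hubnet.graphs import degree_stats

    stats = degree_stats(network)
    out = (
        stats.reset_index(names="term_id")[["term_id", "degree"]]
        .sort_values(["degree", "term_id"], ascending=[False, True])
        .reset_index(drop=True)
    )
    return out


def adjacency_from_shared_genes(
    collection: GeneSetCollection, min_shared: int = 1
) -> list[tuple[str, str]]:
    """Derive pathway adjacency: pairs sharing >= ``min_shared`` genes."""
    pathways = [
        (tid, set(members))
        for tid, _, cat, members in collection.terms
        if cat in PATHWAY_CATEGORIES
    ]
    pairs = []
    for (a, ga), (b, gb) in itertools.combinations(sorted(pathways), 2):
        if len(ga & gb) >= min_shared:
            pairs.append((a, b))
    return pairs
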