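"""Per-group Pearson co-expression networks with k-core annotation.

Within one sample group, every gene pair is scored by the Pearson
correlation R of its log2 intensities across the group's samples. A signed
undirected edge is drawn when |R| >= ``r_threshold`` AND the two-sided
correlation test (t with n - 2 df) gives p < ``p_threshold``; the edge sign
is the sign of R (positive vs negative regulation). Genes that are constant
within the group carry no usable correlation and stay isolated.

With very few samples per group (the motivating design has three) the p
gate is extremely conservative — at n = 3 it effectively requires
|R| > 0.997 — which is why the magnitude gate exists and both thresholds
are exposed. Comparing the control-group and experimental-group networks
per gene (degree, k-core, signed partner sets) flags status-changed genes.
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from hubnet.diffexpr import ExpressionMatrix
from hubnet.graphs import Network

logger = logging.getLogger(__name__)

COMPARE_COLUMNS = [
    "gene",
    "degree_ctrl",
    "degree_exp",
    "k_core_ctrl",
    "k_core_exp",
    "pos_partners_ctrl",
    "neg_partners_ctrl",
    "pos_partners_exp",
    "neg_partners_exp",
    "status_change",
]


def pearson_edges(
    log_values: np.ndarray, genes: list[str], r_threshold: float, p_threshold: float
) -> list[tuple[str, str, float]]:
    """Significant correlation pairs (gene_a, gene_b, R) for a gene x sample block."""
    n = log_values.shape[1]
    if n < 3:
        raise ValueError("correlation test needs >= 3 samples (df = n - 2 > 0)")
    sd = log_values.std(axis=1)
    # numerically-constant profiles (float jitter from exp/log round trips)
    # carry no correlation information and would otherwise score |R| = 1
    usable = sd > 1e-8 * (1.0 + np.abs(log_values).max(axis=1))
    n_dropped = int((~usable).sum())
    if n_dropped:
        logger.info("%d constant genes excluded from correlation", n_dropped)
    idx = np.flatnonzero(usable)
    if idx.size < 2:
        return []
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(log_values[idx])
    df = n - 2
    edges = []
    for a in range(len(idx)):
        for b in range(a + 1, len(idx)):
            r = float(np.clip(corr[a, b], -1.0, 1.0))
            if abs(r) < r_threshold:
                continue
            if abs(r) == 1.0:
                p = 0.0
            else:
                t = abs(r) * np.sqrt(df / (1.0 - r * r))
                p = 2.0 * float(stats.t.sf(t, df))
            if p < p_threshold:
                edges.append((genes[idx[a]], genes[idx[b]], r))
    return edges


def build_coexpression_network(
    matrix: ExpressionMatrix,
    group: str,
    genes=None,
    r_threshold: float = 0.8,
    p_threshold: float = 0.05,
) -> Network:
    """Signed undirected co-expression network for one group's samples.

    ``genes`` restricts the network to a subset (typically the genes of the
    significant GO terms); by default all genes in the matrix are used.
    """
    samples = matrix.samples_of(group)
    if len(samples) < 3:
        raise ValueError(f"group {group!r} has {len(samples)} samples; need >= 3")
    data = matrix.log2()[samples]
    if genes is not None:
        keep = [g for g in matrix.gene_ids if g in set(genes)]
        data = data.loc[keep]
    gene_list = list(data.index)
    g = nx.Graph()
    g.add_nodes_from(gene_list)
    for u, v, r in pearson_edges(data.to_numpy(), gene_list, r_threshold, p_threshold):
        g.add_edge(u, v, sign="+" if r > 0 else "-", r=float(r))
    net = Network(g)
    net.annotate()
    return net


def _signed_partners(net: Network, gene: str) -> tuple[set[str], set[str]]:
    if gene not in net.graph:
        return set(), set()
    pos, neg = set(), set()
    for nb in net.graph.neighbors(gene):
        (pos if net.graph.edges[gene, nb].get("sign", "+") == "+" else neg).add(nb)
    return pos, neg


def compare_group_networks(net_ctrl: Network, net_exp: Network) -> pd.DataFrame:
    """Per-gene cross-group comparison of degree, k-core and signed partners.

    A gene absent from one network contributes degree/k-core 0 there.
    ``status_change`` flags any difference in degree, core index or signed
    partner sets between the two group networks.
    """
    genes = sorted(set(net_ctrl.graph.nodes) | set(net_exp.graph.nodes))
    rows = []
    for gene in genes:
        pos_c, neg_c = _signed_partners(net_ctrl, gene)
        pos_e, neg_e = _signed_partners(net_exp, gene)
        deg_c, deg_e = len(pos_c) + len(neg_c), len(pos_e) + len(neg_e)
        kc_c = int(net_ctrl.graph.nodes[gene].get("k_core", 0)) if gene in net_ctrl.graph else 0
        kc_e = int(net_exp.graph.nodes[gene].get("k_core", 0)) if gene in net_exp.graph else 0
        rows.append(
            {
                "gene": gene,
                "degree_ctrl": deg_c,
                "degree_exp": deg_e,
                "k_core_ctrl": kc_c,
                "k_core_exp": kc_e,
                "pos_partners_ctrl": ";".join(sorted(pos_c)),
                "neg_partners_ctrl": ";".join(sorted(neg_c)),
                "pos_partners_exp": ";".join(sorted(pos_e)),
                "neg_partners_exp": ";".join(sorted(neg_e)),
                "status_change": (pos_c, neg_c) != (pos_e, neg_e) or kc_c != kc_e,
            }
        )
    return pd.DataFrame(rows, columns=COMPARE_COLUMNS)
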