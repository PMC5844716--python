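"""Hub-gene nomination by intersecting the three evidence streams.

A differential gene accumulates one evidence point per stream:

(a) membership in at least one significantly enriched pathway;
(b) signal-network betweenness within the top K ranked genes (zero
    betweenness never counts as centrality evidence);
(c) co-expression core status — k-core at or above a threshold in either
    group network, or a status change between the two group networks.

A gene is called a hub when at least ``min_evidence`` streams fire. Every
threshold is a :class:`HubConfig` field; the defaults (K = 10, the length
of a typical published hub table; min_evidence = 2; k-core >= 5) formalize
the narrative "member of hub pathways AND central in the gene networks"
intersection as an explicit, tunable rule.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from hubnet.enrichment import GeneSetCollection, significant_terms

REPORT_COLUMNS = [
    "gene",
    "in_significant_pathway",
    "pathway_ids",
    "signal_betweenness_rank",
    "signal_betweenness",
    "coexpr_k_core_ctrl",
    "coexpr_k_core_exp",
    "coexpr_status_change",
    "evidence_pathway",
    "evidence_centrality",
    "evidence_coexpression",
    "composite_evidence_count",
    "final_call",
]


@dataclass
class HubConfig:
    top_k: int = 10
    min_evidence: int = 2
    k_core_min: int = 5

    def validate(self) -> None:
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")
        if not 1 <= self.min_evidence <= 3:
            raise ValueError("min_evidence must be in 1..3")
        if self.k_core_min < 1:
            raise ValueError("k_core_min must be >= 1")


def integrate(
    enrichment_records: pd.DataFrame,
    gene_sets: GeneSetCollection,
    signal_rank: pd.DataFrame,
    coexpr_comparison: pd.DataFrame,
    differential_genes,
    config: HubConfig | None = None,
) -> pd.DataFrame:
    """Combine the evidence streams into a ranked hub report.

    Parameters
    ----------
    enrichment_records
        Output of :func:`hubnet.enrichment.enrich` (pathway categories used).
    gene_sets
        The annotation collection, for pathway membership lookups.
    signal_rank
        Output of :func:`hubnet.signal_network.rank_hub_genes`.
    coexpr_comparison
        Output of :func:`hubnet.coexpression.compare_group_networks`.
    differential_genes
        The candidate universe; hubs are always differential genes.
    """
    config = config or HubConfig()
    config.validate()
    de = sorted(set(differential_genes))
    de_set = set(de)

    stray = sorted(set(signal_rank["gene"]) - de_set) if len(signal_rank) else []
    stray += sorted(set(coexpr_comparison["gene"]) - de_set) if len(coexpr_comparison) else []
    if stray:
        raise ValueError(f"genes outside the differential universe: {sorted(set(stray))[:10]}")

    sig_pathways = significant_terms(enrichment_records, category="pathway")
    membership: dict[str, set[str]] = {}
    for term_id in set(sig_pathways["term_id"]):
        for gene in gene_sets.members_of(term_id):
            membership.setdefault(gene, set()).add(term_id)

    rank_of: dict[str, int] = {}
    bc_of: dict[str, float] = {}
    for i, row in enumerate(signal_rank.itertuples(index=False), start=1):
        bc_of[row.gene] = float(row.betweenness)
        if row.betweenness > 0 and i <= config.top_k:
            rank_of[row.gene] = i

    coexpr = coexpr_comparison.set_index("gene") if len(coexpr_comparison) else pd.DataFrame()

    rows = []
    for gene in de:
        pathways = sorted(membership.get(gene, set()))
        in_pathway = bool(pathways)
        rank = rank_of.get(gene)
        if gene in getattr(coexpr, "index", []):
            kc_ctrl = int(coexpr.loc[gene, "k_core_ctrl"])
            kc_exp = int(coexpr.loc[gene, "k_core_exp"])
            status = bool(coexpr.loc[gene, "status_change"])
        else:
            kc_ctrl = kc_exp = 0
            status = False
        ev_a = in_pathway
        ev_b = rank is not None
        ev_c = max(kc_ctrl, kc_exp) >= config.k_core_min or status
        count = int(ev_a) + int(ev_b) + int(ev_c)
        rows.append(
            {
                "gene": gene,
                "in_significant_pathway": in_pathway,
                "pathway_ids": ";".join(pathways),
                "signal_betweenness_rank": rank if rank is not None else 0,
                "signal_betweenness": bc_of.get(gene, 0.0),
                "coexpr_k_core_ctrl": kc_ctrl,
                "coexpr_k_core_exp": kc_exp,
                "coexpr_status_change": status,
                "evidence_pathway": ev_a,
                "evidence_centrality": ev_b,
                "evidence_coexpression": ev_c,
                "composite_evidence_count": count,
                "final_call": count >= config.min_evidence,
            }
        )
    report = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    return report.sort_values(
        ["composite_evidence_count", "signal_betweenness", "gene"],
        ascending=[False, False, True],
    ).reset_index(drop=True)


def called_hubs(report: pd.DataFrame) -> list[str]:
    return sorted(report.loc[report["final_call"], "gene"])


def write_hub_report(report: pd.DataFrame, tsv_path: str | Path, json_path: str | Path | None = None) -> None:
    report.to_csv(tsv_path, sep="\t", index=False)
    if json_path is not None:
        payload = {
            "hubs": called_hubs(report),
            "candidates": report.to_dict(orient="records"),
        }
        with open(json_path, "w") as fh:
            json.dump(payload, fh, indent=2, default=str)
            fh.write("\n")
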