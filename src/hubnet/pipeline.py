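"""End-to-end orchestration: simulate -> screen -> enrich -> networks -> hubs.

One :class:`PipelineConfig` (loadable from a YAML file with per-stage
sections) carries every threshold: the differential cutoffs (p < 0.05 and
FDR < 0.05), the enrichment cutoffs, the co-expression gates, the GO-map
component size, and the hub-evidence rule. :func:`run_pipeline` executes the
stages into a run directory, logs every fallback / dropped-input event, and
writes a structured ``report.json`` with the headline counts (differential
up/down, significant functions up/down, sub-networks, hub calls), the stage
tables, and the fully resolved configuration. Under a fixed seed the run is
bit-reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from hubnet import coexpression, enrichment, hubs, qpcr, signal_network, term_networks
from hubnet.diffexpr import CONTROL, EXPERIMENTAL, DifferentialExpression
from hubnet.hubs import HubConfig
from hubnet.simulate import ConfigurationError, SimulationConfig, write_simulation
from hubnet import io

logger = logging.getLogger("hubnet.pipeline")


def _check_prob(value: float, name: str) -> None:
    if not 0.0 < value <= 1.0:
        raise ConfigurationError(f"{name} must lie in (0, 1], got {value}")


@dataclass
class PipelineConfig:
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    p_cut: float = 0.05
    fdr_cut: float = 0.05
    enrich_p_cut: float = 0.05
    enrich_fdr_cut: float = 0.05
    r_threshold: float = 0.8
    coexpr_p_threshold: float = 0.05
    use_all_differential: bool = False
    min_component_size: int = 2
    hub: HubConfig = field(default_factory=HubConfig)
    qpcr_reference: str = "Actb"

    def validate(self) -> None:
        for name in ("p_cut", "fdr_cut", "enrich_p_cut", "enrich_fdr_cut", "coexpr_p_threshold"):
            _check_prob(getattr(self, name), name)
        if not 0.0 <= self.r_threshold <= 1.0:
            raise ConfigurationError("r_threshold must lie in [0, 1]")
        if self.min_component_size < 1:
            raise ConfigurationError("min_component_size must be >= 1")
        self.hub.validate()
        self.simulation.validate()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        sim_raw = dict(raw.get("simulation", {}))
        if "seed" in raw:
            sim_raw.setdefault("seed", int(raw["seed"]))
        if "hub_spec" in sim_raw:
            sim_raw["hub_spec"] = [tuple(entry) for entry in sim_raw["hub_spec"]]
        if "fold_change_range" in sim_raw:
            sim_raw["fold_change_range"] = tuple(sim_raw["fold_change_range"])
        if "term_size_range" in sim_raw:
            sim_raw["term_size_range"] = tuple(sim_raw["term_size_range"])
        known = {f.name for f in dataclasses.fields(SimulationConfig)}
        unknown = set(sim_raw) - known
        if unknown:
            raise ConfigurationError(f"unknown simulation keys: {sorted(unknown)}")
        config = cls(simulation=SimulationConfig(**sim_raw))
        de = raw.get("diffexpr", {})
        config.p_cut = float(de.get("p_cut", config.p_cut))
        config.fdr_cut = float(de.get("fdr_cut", config.fdr_cut))
        en = raw.get("enrichment", {})
        config.enrich_p_cut = float(en.get("p_cut", config.enrich_p_cut))
        config.enrich_fdr_cut = float(en.get("fdr_cut", config.enrich_fdr_cut))
        co = raw.get("coexpression", {})
        config.r_threshold = float(co.get("r_threshold", config.r_threshold))
        config.coexpr_p_threshold = float(co.get("p_threshold", config.coexpr_p_threshold))
        config.use_all_differential = bool(
            co.get("use_all_differential", config.use_all_differential)
        )
        gm = raw.get("go_map", {})
        config.min_component_size = int(
            gm.get("min_component_size", config.min_component_size)
        )
        hb = raw.get("hubs", {})
        config.hub = HubConfig(
            top_k=int(hb.get("top_k", 10)),
            min_evidence=int(hb.get("min_evidence", 2)),
            k_core_min=int(hb.get("k_core_min", 5)),
        )
        config.qpcr_reference = str(raw.get("qpcr", {}).get("reference_gene", "Actb"))
        config.validate()
        return config

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _setup_logging(outdir: Path) -> logging.Handler:
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("hubnet")
    root.setLevel(logging.INFO)
    root.addHandler(handler)
    return handler


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Execute every stage into ``outdir`` and return the report dict."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = _setup_logging(outdir)
    try:
        return _run(config, outdir)
    finally:
        logging.getLogger("hubnet").removeHandler(handler)
        handler.close()


def _run(config: PipelineConfig, outdir: Path) -> dict:
    # ------------------------------------------------------------------ simulate
    inputs = write_simulation(config.simulation, outdir / "inputs")
    logger.info("simulated inputs under %s", inputs["matrix"].parent)

    # ------------------------------------------------------------------ screen
    model = DifferentialExpression.from_files(inputs["matrix"], inputs["groups"])
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        results = model.fit(p_cut=config.p_cut, fdr_cut=config.fdr_cut)
        for w in caught:
            logger.warning("diffexpr: %s", w.message)
    results.to_tsv(outdir / "differential.tsv")
    results.volcano().to_csv(outdir / "volcano.tsv", sep="\t", index=False)
    up = list(results.up["gene"])
    down = list(results.down["gene"])
    de_genes = results.significant_genes
    trend_of = results.trend_of()

    # ------------------------------------------------------------------ enrich
    collection = enrichment.GeneSetCollection.from_gmt(inputs["gmt"])
    records = enrichment.enrich(
        collection, up, down, p_cut=config.enrich_p_cut, fdr_cut=config.enrich_fdr_cut
    )
    enrichment.write_enrichment_tsv(records, outdir / "enrichment.tsv")

    # ------------------------------------------------------------------ GO map
    parent_edges = io.read_parent_edges_tsv(inputs["go_hierarchy"])
    go_map = term_networks.build_go_map(records, parent_edges)
    go_map.write_graphml(outdir / "go_map.graphml")
    components = term_networks.sub_networks(go_map, config.min_component_size)
    term_networks.write_subnetwork_summary(components, outdir / "go_subnetworks.tsv")

    # ------------------------------------------------------------------ pathways
    adjacency = io.read_adjacency_tsv(inputs["pathway_adjacency"])
    path_net = term_networks.build_pathway_network(records, adjacency)
    path_net.write_graphml(outdir / "pathway_network.graphml")
    pathway_rank = term_networks.hub_pathway(path_net)
    pathway_rank.to_csv(outdir / "pathway_rank.tsv", sep="\t", index=False)

    # ------------------------------------------------------------------ signal
    interactions = io.read_edges_tsv(inputs["interactions"])
    signal = signal_network.build_signal_network(de_genes, interactions, trend_of)
    signal.write_graphml(outdir / "signal_network.graphml")
    signal_rank = signal_network.rank_hub_genes(signal)
    signal_network.write_hub_table(signal_rank, outdir / "signal_hubs.tsv")

    # ------------------------------------------------------------------ coexpr
    if config.use_all_differential:
        subset = set(de_genes)
    else:
        sig_go = enrichment.significant_terms(records, category="GO")
        subset = set()
        for term_id in set(sig_go["term_id"]):
            subset |= collection.members_of(term_id)
        subset &= set(de_genes)
        if not subset:
            logger.warning("no significant GO genes; co-expression falls back to all differential genes")
            subset = set(de_genes)
    net_ctrl = coexpression.build_coexpression_network(
        model.matrix, CONTROL, subset, config.r_threshold, config.coexpr_p_threshold
    )
    net_exp = coexpression.build_coexpression_network(
        model.matrix, EXPERIMENTAL, subset, config.r_threshold, config.coexpr_p_threshold
    )
    net_ctrl.write_graphml(outdir / "coexpression_ctrl.graphml")
    net_exp.write_graphml(outdir / "coexpression_exp.graphml")
    comparison = coexpression.compare_group_networks(net_ctrl, net_exp)
    comparison.to_csv(outdir / "coexpression_comparison.tsv", sep="\t", index=False)

    # ------------------------------------------------------------------ hubs
    report_df = hubs.integrate(
        records, collection, signal_rank, comparison, de_genes, config.hub
    )
    hubs.write_hub_report(report_df, outdir / "hub_report.tsv", outdir / "hub_report.json")
    hub_list = hubs.called_hubs(report_df)

    # ------------------------------------------------------------------ qPCR
    ct = qpcr.CtTable(io.read_ct_csv(inputs["ct"]), reference_gene=config.qpcr_reference)
    ratios = qpcr.all_ratios(ct)
    qpcr.write_ratio_tsv(ratios, outdir / "qpcr_ratios.tsv")
    concordance_df, concordance_fraction = qpcr.concordance(results.records, ratios)
    concordance_df.to_csv(outdir / "qpcr_concordance.tsv", sep="\t", index=False)

    report = {
        "config": config.to_dict(),
        "counts": {
            "genes": config.simulation.n_genes,
            "differential": len(de_genes),
            "differential_up": len(up),
            "differential_down": len(down),
            "significant_functions_up": int(
                (enrichment.significant_terms(records, "GO")["direction"] == "up").sum()
            ),
            "significant_functions_down": int(
                (enrichment.significant_terms(records, "GO")["direction"] == "down").sum()
            ),
            "go_subnetworks": len(components),
            "signal_nodes": signal.n_nodes,
            "signal_edges": signal.n_edges,
        },
        "hubs": hub_list,
        "top_pathways": pathway_rank.head(5).to_dict(orient="records"),
        "top_signal_genes": signal_rank.head(10).to_dict(orient="records"),
        "qpcr_concordance": concordance_fraction,
    }
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    logger.info("pipeline complete: %d differential genes, hubs: %s", len(de_genes), hub_list)
    return report
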