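"""Seeded synthetic data with planted differential, enrichment and hub structure.

The generator emulates a small-replicate two-group intensity study (the
motivating design: three experimental vs three control arrays):

* intensities are log-normal — log2 values are Gaussian around per-gene
  baselines, so ratios of geometric means are the natural effect scale;
* a planted fraction of genes is differential, with log-uniform fold
  changes spanning a configurable range (default 2 to 47.26, the span seen
  in strongly responding genes) and a configurable up/down split;
* gene sets draw their members preferentially from the differential genes
  at a configurable odds multiplier when planted as enriched;
* hub genes get a correlation block (hub + spokes share a per-sample latent
  factor scaled so the expected pairwise Pearson correlation reaches the
  configured strength) and dominate the interaction edge list with
  ``n_spokes`` incoming and outgoing edges each.

All randomness flows from one integer seed through independent
``numpy.random.Generator`` streams per artifact, so every emitted file is
bit-identical across re-runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from hubnet import io
from hubnet.diffexpr import CONTROL, EXPERIMENTAL, ExpressionMatrix
from hubnet.enrichment import GeneSetCollection


class ConfigurationError(ValueError):
    """Invalid simulation configuration; the message names the field."""


#: default hub plan: (gene id or None for auto-pick, n_spokes, correlation)
DEFAULT_HUBS: list[tuple[str | None, int, float]] = [
    (None, 16, 0.95),
    (None, 10, 0.9),
    (None, 8, 0.9),
]


@dataclass
class SimulationConfig:
    n_genes: int = 2000
    n_samples_per_group: int = 3
    de_fraction: float = 0.1
    fold_change_range: tuple[float, float] = (2.0, 47.26)
    up_fraction: float = 0.4
    noise_sd_log2: float = 0.25
    baseline_log2_mean: float = 8.0
    baseline_log2_sd: float = 1.5
    n_terms: int = 30
    enriched_terms: int = 6
    term_size_range: tuple[int, int] = (15, 40)
    enrichment_odds: float = 15.0
    random_edge_rate: float = 0.5
    hub_spec: list[tuple[str | None, int, float]] = field(
        default_factory=lambda: list(DEFAULT_HUBS)
    )
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ConfigurationError("n_genes must be >= 1")
        if self.n_samples_per_group < 2:
            raise ConfigurationError("n_samples_per_group must be >= 2")
        for name in ("de_fraction", "up_fraction"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        lo, hi = self.fold_change_range
        if lo <= 1.0 or hi < lo:
            raise ConfigurationError(
                "fold_change_range lower bound must exceed 1 and not exceed the upper bound"
            )
        if self.noise_sd_log2 < 0:
            raise ConfigurationError("noise_sd_log2 must be >= 0")
        if self.baseline_log2_sd < 0:
            raise ConfigurationError("baseline_log2_sd must be >= 0")
        if self.n_terms < 0 or self.enriched_terms < 0 or self.enriched_terms > self.n_terms:
            raise ConfigurationError("enriched_terms must lie in [0, n_terms]")
        tlo, thi = self.term_size_range
        if tlo < 1 or thi < tlo:
            raise ConfigurationError("term_size_range must satisfy 1 <= lo <= hi")
        if self.n_terms > 0 and thi > self.n_genes:
            raise ConfigurationError("term_size_range upper bound exceeds the gene universe")
        if self.enrichment_odds <= 0:
            raise ConfigurationError("enrichment_odds must be positive")
        if self.random_edge_rate < 0:
            raise ConfigurationError("random_edge_rate must be >= 0")
        for gene, n_spokes, rho in self.hub_spec:
            if n_spokes < 1:
                raise ConfigurationError("hub_spec n_spokes must be >= 1")
            if n_spokes >= self.n_genes:
                raise ConfigurationError("hub_spec n_spokes must be < n_genes")
            if not 0.0 < rho < 1.0:
                raise ConfigurationError("hub_spec correlation strength must lie in (0, 1)")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent generator for one artifact stream."""
        return np.random.default_rng([self.seed, stream])


@dataclass
class GroundTruth:
    """Planted structure: what a perfect analysis should recover."""

    de_genes: dict[str, tuple[str, float]]  # gene -> (trend, true fold change)
    enriched_term_ids: set[str] = field(default_factory=set)
    hub_genes: set[str] = field(default_factory=set)
    hub_blocks: dict[str, list[str]] = field(default_factory=dict)  # hub -> spokes

    @property
    def de_set(self) -> set[str]:
        return set(self.de_genes)

    def to_dict(self) -> dict:
        return {
            "de_genes": {g: [t, f] for g, (t, f) in sorted(self.de_genes.items())},
            "enriched_term_ids": sorted(self.enriched_term_ids),
            "hub_genes": sorted(self.hub_genes),
            "hub_blocks": {h: sorted(s) for h, s in sorted(self.hub_blocks.items())},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(
            de_genes={g: (t, float(f)) for g, (t, f) in d["de_genes"].items()},
            enriched_term_ids=set(d["enriched_term_ids"]),
            hub_genes=set(d["hub_genes"]),
            hub_blocks={h: list(s) for h, s in d.get("hub_blocks", {}).items()},
        )


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"g{i:0{width}d}" for i in range(n)]


def simulate_expression(config: SimulationConfig) -> tuple[ExpressionMatrix, GroundTruth]:
    """Generate the intensity matrix and the planted ground truth.

    Non-differential genes share their group means exactly; differential
    genes have the experimental-group log2 mean shifted by +/- log2(fold).
    Hub blocks (hub + correlation spokes, always differential genes) share a
    per-sample latent factor whose loading is scaled against the iid noise
    so the expected within-block Pearson correlation equals the configured
    strength; with zero noise the latent loading is zero too, keeping the
    noise-free matrix an exact rendition of the planted means.
    """
    config.validate()
    rng = config.rng(0)
    n = config.n_genes
    genes = _gene_ids(n)
    n_per = config.n_samples_per_group
    samples = [f"ctrl_{i+1}" for i in range(n_per)] + [f"exp_{i+1}" for i in range(n_per)]
    groups = pd.Series(
        [CONTROL] * n_per + [EXPERIMENTAL] * n_per, index=samples, name="group"
    )

    n_de = round(config.de_fraction * n)
    de_idx = rng.choice(n, size=n_de, replace=False) if n_de else np.array([], dtype=int)
    n_up = round(config.up_fraction * n_de)
    lo, hi = config.fold_change_range
    magnitudes = 2.0 ** rng.uniform(math.log2(lo), math.log2(hi), size=n_de)

    de_genes: dict[str, tuple[str, float]] = {}
    shift = np.zeros(n)
    for j, idx in enumerate(de_idx):
        up = j < n_up
        fold = float(magnitudes[j]) if up else float(1.0 / magnitudes[j])
        de_genes[genes[idx]] = ("up" if up else "down", fold)
        shift[idx] = math.log2(fold)

    hub_genes, hub_blocks, hub_rho = _resolve_hubs(config, genes, de_genes, rng)

    baseline = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, size=n)
    log2_vals = np.tile(baseline[:, None], (1, 2 * n_per))
    log2_vals[:, n_per:] += shift[:, None]
    if config.noise_sd_log2 > 0:
        gene_pos = {g: i for i, g in enumerate(genes)}
        for hub, spokes in hub_blocks.items():
            rho = hub_rho[hub]
            lam = config.noise_sd_log2 * math.sqrt(rho / (1.0 - rho))
            z = rng.normal(size=2 * n_per)
            for g in [hub, *spokes]:
                log2_vals[gene_pos[g]] += lam * z
        log2_vals += rng.normal(0.0, config.noise_sd_log2, size=log2_vals.shape)

    data = pd.DataFrame(2.0 ** log2_vals, index=genes, columns=samples)
    matrix = ExpressionMatrix(data, groups)
    truth = GroundTruth(
        de_genes=de_genes,
        hub_genes=set(hub_genes),
        hub_blocks=hub_blocks,
    )
    return matrix, truth


def _resolve_hubs(config, genes, de_genes, rng):
    """Pick hub genes and disjoint correlation-spoke sets among DE genes."""
    if not config.hub_spec:
        return [], {}, {}
    de_list = sorted(de_genes)
    needed = len(config.hub_spec) + sum(s for _, s, _ in config.hub_spec)
    if needed > len(de_list):
        raise ConfigurationError(
            f"hub_spec needs {needed} differential genes but only {len(de_list)} are planted"
        )
    pool = [str(g) for g in rng.permutation(de_list)]
    hubs: list[str] = []
    for gene, _, _ in config.hub_spec:
        if gene is None:
            gene = pool.pop()
        else:
            if gene not in de_genes:
                raise ConfigurationError(f"hub_spec gene {gene!r} is not a planted DE gene")
            pool.remove(gene)
        hubs.append(gene)
    blocks: dict[str, list[str]] = {}
    rho_of: dict[str, float] = {}
    for hub, (_, n_spokes, rho) in zip(hubs, config.hub_spec):
        blocks[hub] = [pool.pop() for _ in range(n_spokes)]
        rho_of[hub] = rho
    return hubs, blocks, rho_of


# ---------------------------------------------------------------------------
# annotations


def simulate_annotations(config: SimulationConfig, truth: GroundTruth) -> GeneSetCollection:
    """Gene sets with planted over-representation among the DE genes.

    Terms alternate between the GO and KEGG categories. Planted-enriched
    terms sample members with an ``enrichment_odds``-fold weight on the
    differential genes; the remaining terms sample uniformly. Each hub block
    (hub + spokes) is appended to one enriched GO term — hubs must surface
    in the significant-GO gene subset used by the co-expression stage — and
    each hub to one enriched KEGG term (pathway-membership evidence).
    """
    config.validate()
    rng = config.rng(1)
    genes = np.array(_gene_ids(config.n_genes))
    de_mask = np.isin(genes, sorted(truth.de_set))
    term_ids, names, categories = [], [], []
    for i in range(config.n_terms):
        cat = "GO" if i % 2 == 0 else "KEGG"
        term_ids.append(f"{'GO' if cat == 'GO' else 'PW'}{i:04d}")
        names.append(f"synthetic {cat.lower()} term {i}")
        categories.append(cat)

    enriched = (
        sorted(rng.choice(config.n_terms, size=config.enriched_terms, replace=False))
        if config.enriched_terms
        else []
    )
    enriched_set = set(enriched)

    weights = np.where(de_mask, config.enrichment_odds, 1.0)
    weights = weights / weights.sum()
    uniform = np.full(len(genes), 1.0 / len(genes))

    members_by_term: list[list[str]] = []
    for i in range(config.n_terms):
        size = int(rng.integers(config.term_size_range[0], config.term_size_range[1] + 1))
        if size > len(genes):
            raise ConfigurationError("term size exceeds the gene universe")
        p = weights if i in enriched_set else uniform
        members = [str(g) for g in rng.choice(genes, size=size, replace=False, p=p)]
        members_by_term.append(members)

    enriched_go = [i for i in enriched if categories[i] == "GO"]
    enriched_kegg = [i for i in enriched if categories[i] == "KEGG"]
    for j, (hub, spokes) in enumerate(sorted(truth.hub_blocks.items())):
        if enriched_go:
            slot = enriched_go[j % len(enriched_go)]
            members_by_term[slot] = sorted(set(members_by_term[slot]) | {hub, *spokes})
        if enriched_kegg:
            slot = enriched_kegg[j % len(enriched_kegg)]
            members_by_term[slot] = sorted(set(members_by_term[slot]) | {hub})

    truth.enriched_term_ids = {term_ids[i] for i in enriched}
    terms = [
        (term_ids[i], names[i], categories[i], sorted(members_by_term[i]))
        for i in range(config.n_terms)
    ]
    return GeneSetCollection(terms, universe=set(genes))


def simulate_go_hierarchy(
    config: SimulationConfig, collection: GeneSetCollection, attach_prob: float = 0.7
) -> list[tuple[str, str]]:
    """Random forest of child -> parent edges over the GO terms.

    Each GO term (in id order) attaches to one earlier GO term with
    probability ``attach_prob``, which yields an acyclic hierarchy whose
    roots are unattached terms.
    """
    rng = config.rng(2)
    go_terms = [tid for tid, _, cat, _ in collection.terms if cat == "GO"]
    edges = []
    for i, term in enumerate(go_terms[1:], start=1):
        if rng.random() < attach_prob:
            parent = go_terms[int(rng.integers(0, i))]
            edges.append((term, parent))
    return edges


def simulate_pathway_adjacency(
    config: SimulationConfig,
    truth: GroundTruth,
    collection: GeneSetCollection,
    enriched_pair_prob: float = 0.8,
    background_pair_prob: float = 0.2,
) -> list[tuple[str, str]]:
    """Curated-style pathway-pathway pairs, dense among planted-enriched ones."""
    rng = config.rng(3)
    pathways = [tid for tid, _, cat, _ in collection.terms if cat != "GO"]
    enriched = truth.enriched_term_ids
    pairs = []
    for i, a in enumerate(pathways):
        for b in pathways[i + 1 :]:
            prob = (
                enriched_pair_prob
                if a in enriched and b in enriched
                else background_pair_prob
            )
            if rng.random() < prob:
                pairs.append((a, b))
    return pairs


# ---------------------------------------------------------------------------
# interaction edges


def simulate_interaction_edges(config: SimulationConfig, truth: GroundTruth) -> pd.DataFrame:
    """Signed directed edges with each hub given n_spokes in- and out-edges.

    Spokes and background edges are drawn among the differential genes (the
    curated interaction input only matters on the screened list, where the
    signal network lives). Each hub's spokes are its own correlation-block
    members: all n_spokes point at the hub, and the hub points back at all
    but one of them plus one fresh gene — n_spokes reciprocal-but-one wiring
    that gives the hub n_spokes + 1 distinct neighbors with indegree =
    outdegree = n_spokes, the pattern seen in published hub tables. Because
    block memberships are disjoint and spokes touch only their own hub,
    every non-hub node has zero betweenness until background edges
    (``random_edge_rate`` per differential gene) add chains.
    """
    config.validate()
    rng = config.rng(4)
    de_list = sorted(truth.de_set)
    edges: dict[tuple[str, str], str] = {}

    def _sign() -> str:
        return "+" if rng.random() < 0.5 else "-"

    used = set(truth.hub_blocks) | {g for s in truth.hub_blocks.values() for g in s}
    fresh_pool = [g for g in de_list if g not in used]
    for hub in sorted(truth.hub_blocks):
        spokes = sorted(truth.hub_blocks[hub])
        for u in spokes:
            edges[(u, hub)] = _sign()
        out_nb = spokes[:-1]
        if fresh_pool:
            out_nb = out_nb + [fresh_pool.pop()]
        else:
            out_nb = spokes
        for v in out_nb:
            edges[(hub, v)] = _sign()

    n_background = round(config.random_edge_rate * len(de_list))
    added = 0
    attempts = 0
    while added < n_background and attempts < 20 * max(n_background, 1):
        attempts += 1
        if len(de_list) < 2:
            break
        u, v = rng.choice(de_list, size=2, replace=False)
        key = (str(u), str(v))
        if key not in edges:
            edges[key] = _sign()
            added += 1
    rows = [
        {"source": u, "target": v, "sign": s} for (u, v), s in sorted(edges.items())
    ]
    return pd.DataFrame(rows, columns=["source", "target", "sign"])


# ---------------------------------------------------------------------------
# qPCR


def simulate_ct_table(
    fold_changes: dict[str, float],
    noise_sd: float = 0.0,
    n_replicates: int = 3,
    reference_gene: str = "Actb",
    seed: int = 0,
    reference_ct: float = 18.0,
    target_base_ct: float = 25.0,
) -> pd.DataFrame:
    """Ct table whose 2^-ddCt ratios equal the planted folds when noise is 0.

    The reference gene amplifies at ``reference_ct`` in every sample; each
    target amplifies at ``target_base_ct`` in controls and at
    ``target_base_ct - log2(fold)`` in the experimental group (one fewer
    cycle per doubling of transcript). Gaussian cycle noise is optional.
    """
    rng = np.random.default_rng(seed)
    rows = []
    samples = [(f"ctrl_{i+1}", CONTROL) for i in range(n_replicates)] + [
        (f"exp_{i+1}", EXPERIMENTAL) for i in range(n_replicates)
    ]
    for sample, group in samples:
        rows.append(
            {
                "gene": reference_gene,
                "sample": sample,
                "group": group,
                "ct": reference_ct + (rng.normal(0, noise_sd) if noise_sd else 0.0),
            }
        )
        for gene, fold in sorted(fold_changes.items()):
            if fold <= 0:
                raise ConfigurationError(f"fold change for {gene!r} must be positive")
            ct = target_base_ct
            if group == EXPERIMENTAL:
                ct -= math.log2(fold)
            if noise_sd:
                ct += rng.normal(0, noise_sd)
            rows.append({"gene": gene, "sample": sample, "group": group, "ct": ct})
    return pd.DataFrame(rows, columns=["gene", "sample", "group", "ct"])


# ---------------------------------------------------------------------------
# one-call bundle


def write_simulation(config: SimulationConfig, outdir: str | Path) -> dict[str, Path]:
    """Run every generator and write the full input bundle to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    matrix, truth = simulate_expression(config)
    collection = simulate_annotations(config, truth)
    hierarchy = simulate_go_hierarchy(config, collection)
    adjacency = simulate_pathway_adjacency(config, truth, collection)
    interactions = simulate_interaction_edges(config, truth)
    hub_folds = {g: truth.de_genes[g][1] for g in sorted(truth.hub_genes)}
    ct = simulate_ct_table(
        hub_folds, noise_sd=0.1 if config.noise_sd_log2 > 0 else 0.0, seed=config.seed
    )
    paths = {
        "matrix": outdir / "expression.tsv",
        "groups": outdir / "groups.tsv",
        "gmt": outdir / "annotations.gmt",
        "go_hierarchy": outdir / "go_parents.tsv",
        "pathway_adjacency": outdir / "pathway_adjacency.tsv",
        "interactions": outdir / "interactions.tsv",
        "ct": outdir / "ct_table.csv",
        "truth": outdir / "ground_truth.json",
    }
    io.write_expression_tsv(matrix.data, paths["matrix"])
    io.write_groups_tsv(matrix.groups, paths["groups"])
    collection.to_gmt(paths["gmt"])
    io.write_parent_edges_tsv(hierarchy, paths["go_hierarchy"])
    io.write_adjacency_tsv(adjacency, paths["pathway_adjacency"])
    io.write_edges_tsv(interactions, paths["interactions"])
    io.write_ct_csv(ct, paths["ct"])
    io.write_ground_truth_json(truth.to_dict(), paths["truth"])
    return paths
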