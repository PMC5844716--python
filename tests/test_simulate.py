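import json
import math

import numpy as np
import pandas as pd
import pytest

from hubnet import io
from hubnet.diffexpr import CONTROL, EXPERIMENTAL
from hubnet.enrichment import GeneSetCollection
from hubnet.qpcr import CtTable, ddct_ratio
from hubnet.simulate import (
    ConfigurationError,
    GroundTruth,
    SimulationConfig,
    simulate_annotations,
    simulate_ct_table,
    simulate_expression,
    simulate_go_hierarchy,
    simulate_interaction_edges,
    simulate_pathway_adjacency,
    write_simulation,
)
from oracles import brute_force_betweenness


class TestConfigValidation:
    @pytest.mark.parametrize(
        "field, value",
        [
            ("de_fraction", 1.5),
            ("up_fraction", -0.1),
            ("fold_change_range", (0.5, 3.0)),
            ("fold_change_range", (3.0, 2.0)),
            ("noise_sd_log2", -1.0),
            ("n_samples_per_group", 1),
            ("enriched_terms", 99),
            ("random_edge_rate", -0.5),
        ],
    )
    def test_invalid_field_named_in_error(self, field, value):
        config = SimulationConfig()
        setattr(config, field, value)
        with pytest.raises(ConfigurationError, match=field.split("_")[0]):
            config.validate()

    def test_hub_spec_spokes_bounded_by_universe(self):
        config = SimulationConfig(
            n_genes=10, n_terms=0, enriched_terms=0, hub_spec=[(None, 10, 0.9)]
        )
        with pytest.raises(ConfigurationError, match="n_spokes"):
            config.validate()


class TestSimulateExpression:
    def test_no_signal_no_noise_means_identical(self):
        config = SimulationConfig(
            n_genes=50,
            de_fraction=0.0,
            noise_sd_log2=0.0,
            hub_spec=[],
            n_terms=0,
            enriched_terms=0,
            seed=3,
        )
        matrix, truth = simulate_expression(config)
        gm_exp = matrix.group_values(EXPERIMENTAL).apply(
            lambda r: np.exp(np.mean(np.log(r))), axis=1
        )
        gm_ctrl = matrix.group_values(CONTROL).apply(
            lambda r: np.exp(np.mean(np.log(r))), axis=1
        )
        assert np.allclose(gm_exp, gm_ctrl)
        assert truth.de_genes == {}

    def test_byte_identical_rerun(self):
        config = SimulationConfig(n_genes=1000, de_fraction=0.1, seed=7)
        m1, t1 = simulate_expression(config)
        m2, t2 = simulate_expression(config)
        assert m1.data.equals(m2.data)
        assert t1.to_dict() == t2.to_dict()

    def test_planted_fold_reproduces_reference_intensity_pair(self):
        # one gene at fold 47.26 over a 56.08 control geometric mean
        config = SimulationConfig(
            n_genes=1,
            de_fraction=1.0,
            up_fraction=1.0,
            fold_change_range=(47.26, 47.26),
            noise_sd_log2=0.0,
            baseline_log2_mean=math.log2(56.08),
            baseline_log2_sd=0.0,
            n_terms=0,
            enriched_terms=0,
            hub_spec=[],
            seed=0,
        )
        matrix, truth = simulate_expression(config)
        gm_ctrl = float(matrix.group_values(CONTROL).iloc[0].iloc[0])
        gm_exp = float(matrix.group_values(EXPERIMENTAL).iloc[0].iloc[0])
        assert gm_ctrl == pytest.approx(56.08, abs=1e-9)
        assert abs(gm_exp - 2650.31) < 0.05

    def test_de_shift_matches_planted_fold_without_noise(self):
        config = SimulationConfig(
            n_genes=100, de_fraction=0.2, noise_sd_log2=0.0, hub_spec=[], seed=5
        )
        matrix, truth = simulate_expression(config)
        gm_exp = np.exp(np.log(matrix.group_values(EXPERIMENTAL)).mean(axis=1))
        gm_ctrl = np.exp(np.log(matrix.group_values(CONTROL)).mean(axis=1))
        for gene, (trend, fold) in truth.de_genes.items():
            assert gm_exp[gene] / gm_ctrl[gene] == pytest.approx(fold, rel=1e-9)
            assert (fold > 1) == (trend == "up")

    def test_hub_blocks_are_correlated(self):
        config = SimulationConfig(
            n_genes=400,
            de_fraction=0.3,
            n_samples_per_group=30,
            hub_spec=[(None, 8, 0.95)],
            seed=21,
        )
        matrix, truth = simulate_expression(config)
        (hub,) = truth.hub_genes
        block = [hub, *truth.hub_blocks[hub]]
        # correlation is planted within a group (group mean shifts differ per
        # gene, so the pooled-sample correlation is not the planted quantity)
        ctrl = matrix.group_values(CONTROL)
        log2 = np.log2(ctrl.loc[block].to_numpy())
        corr = np.corrcoef(log2)
        off_diag = corr[np.triu_indices_from(corr, k=1)]
        assert off_diag.min() > 0.8  # expectation 0.95, n=30 samples


class TestSimulateAnnotations:
    def test_deterministic_gmt_bytes(self, tmp_path):
        config = SimulationConfig(seed=13)
        _, truth = simulate_expression(config)
        coll1 = simulate_annotations(config, truth)
        coll2 = simulate_annotations(config, truth)
        p1, p2 = tmp_path / "a.gmt", tmp_path / "b.gmt"
        coll1.to_gmt(p1)
        coll2.to_gmt(p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_term_size_exceeding_universe_rejected(self):
        config = SimulationConfig(n_genes=10, term_size_range=(15, 20), hub_spec=[])
        with pytest.raises(ConfigurationError):
            config.validate()

    def test_hub_genes_annotated_in_enriched_terms(self):
        config = SimulationConfig(seed=2)
        _, truth = simulate_expression(config)
        coll = simulate_annotations(config, truth)
        enriched_members = set()
        for tid in truth.enriched_term_ids:
            enriched_members |= coll.members_of(tid)
        assert truth.hub_genes <= enriched_members


class TestInteractionEdges:
    def test_planted_hub_has_maximum_betweenness(self):
        config = SimulationConfig(
            n_genes=80,
            de_fraction=0.5,
            hub_spec=[(None, 8, 0.9)],
            random_edge_rate=0.3,
            seed=17,
        )
        _, truth = simulate_expression(config)
        edges = simulate_interaction_edges(config, truth)
        (hub,) = truth.hub_genes
        nodes = sorted(set(edges["source"]) | set(edges["target"]))
        bc = brute_force_betweenness(
            nodes, list(zip(edges["source"], edges["target"])), directed=True
        )
        assert bc[hub] == max(bc.values())

    def test_hub_degree_pattern(self):
        config = SimulationConfig(
            n_genes=200, de_fraction=0.3, hub_spec=[(None, 16, 0.9)], random_edge_rate=0.0, seed=3
        )
        _, truth = simulate_expression(config)
        edges = simulate_interaction_edges(config, truth)
        (hub,) = truth.hub_genes
        indeg = (edges["target"] == hub).sum()
        outdeg = (edges["source"] == hub).sum()
        neighbors = set(edges.loc[edges["target"] == hub, "source"]) | set(
            edges.loc[edges["source"] == hub, "target"]
        )
        assert (len(neighbors), indeg, outdeg) == (17, 16, 16)

    def test_no_hubs_no_background_is_empty(self):
        config = SimulationConfig(hub_spec=[], random_edge_rate=0.0, seed=1)
        _, truth = simulate_expression(config)
        assert simulate_interaction_edges(config, truth).empty

    def test_reproducible_under_seed(self):
        config = SimulationConfig(seed=23)
        _, truth = simulate_expression(config)
        e1 = simulate_interaction_edges(config, truth)
        e2 = simulate_interaction_edges(config, truth)
        assert e1.equals(e2)


class TestCtSimulation:
    def test_planted_fold_one_gives_unit_ratio(self):
        table = CtTable(simulate_ct_table({"gene": 1.0}))
        assert ddct_ratio(table, "gene") == pytest.approx(1.0)

    def test_planted_fold_four_noise_free(self):
        table = CtTable(simulate_ct_table({"gene": 4.0}))
        assert ddct_ratio(table, "gene") == pytest.approx(4.0)

    def test_noisy_replicates_recover_fold_approximately(self):
        table = CtTable(simulate_ct_table({"gene": 8.0}, noise_sd=0.1, n_replicates=3, seed=5))
        ratio = ddct_ratio(table, "gene")
        assert abs(math.log2(ratio / 8.0)) < 0.5


class TestBundleRoundTrip:
    def test_every_file_round_trips(self, tmp_path, noisefree_config):
        paths = write_simulation(noisefree_config, tmp_path)
        matrix = io.read_expression_tsv(paths["matrix"])
        fresh, truth = simulate_expression(noisefree_config)
        assert np.allclose(matrix.to_numpy(), fresh.data.to_numpy(), rtol=1e-9)
        groups = io.read_groups_tsv(paths["groups"])
        assert groups.equals(fresh.groups)
        coll = GeneSetCollection.from_gmt(paths["gmt"])
        assert len(coll.terms) == noisefree_config.n_terms
        truth_back = GroundTruth.from_dict(io.read_ground_truth_json(paths["truth"]))
        coll_fresh = simulate_annotations(noisefree_config, truth)
        assert truth_back.to_dict() == truth.to_dict()
        edges = io.read_edges_tsv(paths["interactions"])
        assert edges.equals(simulate_interaction_edges(noisefree_config, truth))
        adj = io.read_adjacency_tsv(paths["pathway_adjacency"])
        assert adj == simulate_pathway_adjacency(noisefree_config, truth, coll_fresh)
        hier = io.read_parent_edges_tsv(paths["go_hierarchy"])
        assert hier == simulate_go_hierarchy(noisefree_config, coll_fresh)
        ct = io.read_ct_csv(paths["ct"])
        assert {"gene", "sample", "group", "ct"} <= set(ct.columns)

    def test_hub_genes_have_enough_edges(self, tmp_path, noisefree_config):
        matrix, truth = simulate_expression(noisefree_config)
        edges = simulate_interaction_edges(noisefree_config, truth)
        for hub, spokes in truth.hub_blocks.items():
            n_edges = ((edges["source"] == hub) | (edges["target"] == hub)).sum()
            assert n_edges >= len(spokes)
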