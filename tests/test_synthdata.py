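"""Synthetic-data generators: planted structure, feasibility checks, determinism."""

import numpy as np
import pytest

from diseasomics.deg import call_degs
from diseasomics.diseasome import intersect_pair
from diseasomics.enrichment import enrich
from diseasomics.netanalysis import rank_regulators
from diseasomics.preprocess import log2_transform
from diseasomics.synthdata import (
    DesignError,
    SimulationTruth,
    simulate_condition_family,
    simulate_disease_genes,
    simulate_drug_targets,
    simulate_gmt,
    simulate_ppi,
    simulate_regulator_tables,
    write_workspace,
)


class TestConditionFamily:
    def test_planted_overlap_recovered_end_to_end(self):
        design = {(0, 1): 10}
        mats, truth = simulate_condition_family(
            n_conditions=2,
            n_genes=400,
            n_deg_per_condition=20,
            overlap_design=design,
            effect_size=3.0,
            noise_sd=0.3,
            seed=11,
        )
        degsets = [call_degs(log2_transform(m)) for m in mats]
        pair = intersect_pair(degsets[0], degsets[1])
        planted = truth.planted_shared("cond1", "cond2")
        recovered = (pair.shared_up | pair.shared_down) & planted
        assert len(recovered) >= 9

    def test_zero_effect_gives_null_rate(self):
        mats, truth = simulate_condition_family(
            n_conditions=1, n_genes=500, n_deg_per_condition=20, effect_size=0.0, seed=2
        )
        ds = call_degs(log2_transform(mats[0]))
        assert len(ds.degs & truth.degs("cond1")) <= 2
        assert len(ds.degs) <= 0.05 * 500

    def test_same_seed_bit_identical(self):
        m1, t1 = simulate_condition_family(n_conditions=2, n_genes=100, seed=9)
        m2, t2 = simulate_condition_family(n_conditions=2, n_genes=100, seed=9)
        for a, b in zip(m1, m2):
            assert a.data.equals(b.data)
        assert t1.up == t2.up and t1.blocks == t2.blocks

    def test_infeasible_design_names_offender(self):
        with pytest.raises(DesignError, match="cond1"):
            simulate_condition_family(
                n_conditions=2, n_deg_per_condition=5, overlap_design={(0, 1): 6}
            )

    def test_asymmetric_matrix_rejected(self):
        mat = np.zeros((2, 2), dtype=int)
        mat[0, 1] = 3
        with pytest.raises(DesignError, match="symmetric"):
            simulate_condition_family(n_conditions=2, overlap_design=mat)

    def test_matrix_and_dict_designs_agree(self):
        mat = np.zeros((3, 3), dtype=int)
        mat[0, 1] = mat[1, 0] = 4
        mat[0, 2] = mat[2, 0] = 2
        _, t_mat = simulate_condition_family(n_conditions=3, overlap_design=mat, seed=5)
        _, t_dict = simulate_condition_family(
            n_conditions=3, overlap_design={(0, 1): 4, (0, 2): 2}, seed=5
        )
        assert t_mat.blocks == t_dict.blocks

    def test_shared_blocks_have_matching_direction(self):
        _, truth = simulate_condition_family(
            n_conditions=3, overlap_design={(0, 1, 2): 5}, seed=4
        )
        blk = truth.blocks[0]
        for g in blk["genes"]:
            for cond in blk["conditions"]:
                target = truth.up if blk["direction"] == "up" else truth.down
                assert g in target[cond]

    def test_truth_round_trips_through_json(self, tmp_path):
        _, truth = simulate_condition_family(n_conditions=2, overlap_design={(0, 1): 3}, seed=1)
        truth.save(tmp_path / "t.json")
        back = SimulationTruth.load(tmp_path / "t.json")
        assert back.up == truth.up and back.blocks == truth.blocks


class TestSimulatePPI:
    def test_reproducible_and_loop_free(self):
        n1 = simulate_ppi(n_nodes=80, seed=3)
        n2 = simulate_ppi(n_nodes=80, seed=3)
        assert n1.edge_set() == n2.edge_set()
        assert all(a != b for a, b in n1.graph.edges())

    def test_planted_hub_reaches_requested_degree(self):
        net = simulate_ppi(n_nodes=120, planted_hub_degree=35, seed=6)
        hub = net.meta["planted_hubs"][0]
        assert net.graph.degree(hub) >= 35
        others = [d for n, d in net.graph.degree() if n != hub]
        assert net.graph.degree(hub) > max(others)

    def test_connected(self):
        import networkx as nx

        net = simulate_ppi(n_nodes=60, seed=8)
        assert nx.is_connected(net.graph)


class TestSimulateGMT:
    def test_planted_term_top_ranked(self):
        genes = [f"G{i:04d}" for i in range(500)]
        planted = genes[:25]
        lib, term = simulate_gmt(
            n_terms=30, term_size_range=(10, 30), planted_genes=planted,
            universe=genes, seed=12,
        )
        results = enrich(planted[:20], lib)
        assert results[0].term_id == term

    def test_universe_covers_all_terms(self):
        genes = [f"G{i:04d}" for i in range(200)]
        lib, _ = simulate_gmt(n_terms=10, term_size_range=(5, 20), universe=genes, seed=1)
        assert lib.universe == frozenset(genes)
        for t in lib.terms:
            assert lib.genes(t) <= lib.universe

    def test_reproducible(self):
        genes = [f"G{i:04d}" for i in range(100)]
        l1, _ = simulate_gmt(n_terms=8, term_size_range=(5, 10), universe=genes, seed=7)
        l2, _ = simulate_gmt(n_terms=8, term_size_range=(5, 10), universe=genes, seed=7)
        assert l1.sets == l2.sets


class TestSimulateRegulators:
    def test_planted_regulator_rank_one(self):
        genes = [f"G{i:04d}" for i in range(800)]
        degs = genes[:40]
        for seed in range(5):
            net, planted = simulate_regulator_tables(
                degs=degs, universe=genes, seed=seed
            )
            ranking = rank_regulators(net, degs, top_n=1)
            assert ranking.entries[0][0] == planted

    def test_empty_deg_query_empty_ranking(self):
        genes = [f"G{i:04d}" for i in range(100)]
        net, _ = simulate_regulator_tables(degs=genes[:10], universe=genes, seed=2)
        with pytest.warns(UserWarning):
            ranking = rank_regulators(net, set())
        assert ranking.entries == ()

    def test_mirna_names_used_for_mirna_class(self):
        genes = [f"G{i:04d}" for i in range(100)]
        net, planted = simulate_regulator_tables(
            degs=genes[:10], universe=genes, seed=2, regulator_class="miRNA"
        )
        assert planted.startswith("mir-")


def test_drug_and_disease_tables_reproducible_and_consistent():
    genes = [f"G{i:04d}" for i in range(300)]
    planted = genes[:20]
    d1 = simulate_drug_targets(universe=genes, planted_genes=planted, seed=5)
    d2 = simulate_drug_targets(universe=genes, planted_genes=planted, seed=5)
    assert d1.edge_set() == d2.edge_set()
    assert set(d1.graph.neighbors("DRUG00")) & set(planted)
    disease = simulate_disease_genes(genes, associated=planted, seed=5)
    assert disease <= frozenset(genes)
    assert disease & frozenset(planted)


def test_workspace_round_trips_through_dataio(tmp_path):
    from diseasomics.dataio import read_edge_list, read_expression, read_gmt

    truth = write_workspace(tmp_path, seed=4, n_genes=300, n_conditions=3,
                            n_deg_per_condition=20,
                            overlap_design={(0, 1): 5, (0, 2): 3})
    M = read_expression(tmp_path / "expr_TARGET.tsv", tmp_path / "groups_TARGET.tsv")
    assert M.shape == (300, 20)
    lib = read_gmt(tmp_path / "library.gmt")
    assert truth.enriched_term in lib.sets
    ppi = read_edge_list(tmp_path / "ppi.tsv", kind="ppi_undirected")
    assert truth.hubs[0] in ppi.graph
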