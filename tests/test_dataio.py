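"""I/O round-trips and input validation for matrices, GMT and edge lists."""

import numpy as np
import pytest

from diseasomics.dataio import (
    DataError,
    GeneSetLibrary,
    build_network,
    read_edge_list,
    read_expression,
    read_gene_list,
    read_gmt,
    write_expression,
    write_gmt,
    write_network,
)


class TestReadExpression:
    def test_shape_and_uppercasing(self, tiny_expression_files):
        expr, groups = tiny_expression_files
        M = read_expression(expr, groups)
        assert M.shape == (3, 4)
        assert M.gene_ids == ["TP53", "BRCA1", "EGFR"]
        assert M.scale == "raw"
        assert M.groups == {"S1": "case", "S2": "case", "S3": "control", "S4": "control"}

    def test_missing_sample_in_group_map_names_it(self, tmp_path, tiny_expression_files):
        expr, _ = tiny_expression_files
        groups = tmp_path / "partial.tsv"
        groups.write_text("S1\tcase\nS2\tcase\nS4\tcontrol\n")
        with pytest.raises(DataError, match="S3"):
            read_expression(expr, groups)

    def test_duplicate_gene_rows_kept_as_probe_keys(self, tmp_path):
        expr = tmp_path / "dup.tsv"
        expr.write_text("gene\tA\tB\nTP53\t1\t2\nTP53\t3\t4\nEGFR\t5\t6\n")
        groups = tmp_path / "g.tsv"
        groups.write_text("A\tcase\nB\tcontrol\n")
        M = read_expression(expr, groups)
        assert M.needs_collapse
        assert set(M.gene_ids) == {"TP53@1", "TP53@2", "EGFR"}
        assert M.probe_to_gene["TP53@2"] == "TP53"
        # both rows retained with their values intact
        assert M.data.loc["TP53@1"].tolist() == [1.0, 2.0]
        assert M.data.loc["TP53@2"].tolist() == [3.0, 4.0]

    def test_non_numeric_cell_located(self, tmp_path):
        expr = tmp_path / "bad.tsv"
        expr.write_text("gene\tA\tB\nTP53\t1\toops\n")
        (tmp_path / "g.tsv").write_text("A\tcase\nB\tcontrol\n")
        with pytest.raises(DataError, match="TP53.*B|B.*TP53"):
            read_expression(expr, tmp_path / "g.tsv")

    def test_na_cell_rejected(self, tmp_path):
        expr = tmp_path / "na.tsv"
        expr.write_text("gene\tA\tB\nTP53\t1\t\n")
        (tmp_path / "g.tsv").write_text("A\tcase\nB\tcontrol\n")
        with pytest.raises(DataError, match="missing"):
            read_expression(expr, tmp_path / "g.tsv")

    def test_empty_file_rejected(self, tmp_path):
        expr = tmp_path / "empty.tsv"
        expr.write_text("")
        (tmp_path / "g.tsv").write_text("A\tcase\n")
        with pytest.raises(DataError):
            read_expression(expr, tmp_path / "g.tsv")

    def test_duplicate_sample_ids_rejected(self, tmp_path):
        expr = tmp_path / "dup.tsv"
        expr.write_text("gene\tA\tA\nTP53\t1\t2\n")
        (tmp_path / "g.tsv").write_text("A\tcase\n")
        with pytest.raises(DataError, match="duplicate sample"):
            read_expression(expr, tmp_path / "g.tsv")

    def test_write_read_round_trip(self, tiny_expression_files, tmp_path):
        expr, groups = tiny_expression_files
        M = read_expression(expr, groups)
        write_expression(M, tmp_path / "out.tsv", tmp_path / "out_groups.tsv")
        M2 = read_expression(tmp_path / "out.tsv", tmp_path / "out_groups.tsv")
        assert M2.gene_ids == M.gene_ids
        assert M2.groups == M.groups
        np.testing.assert_allclose(M2.data.to_numpy(), M.data.to_numpy())


class TestGMT:
    def test_universe_is_union(self, tmp_path):
        p = tmp_path / "x.gmt"
        p.write_text("t1\tdesc\ta\tb\nt2\tdesc\tb\tc\n")
        lib = read_gmt(p)
        assert lib.universe == frozenset({"A", "B", "C"})
        assert lib.genes("t1") == frozenset({"A", "B"})

    def test_short_line_errors_with_line_number(self, tmp_path):
        p = tmp_path / "x.gmt"
        p.write_text("t1\tdesc\ta\nt2\tdesc\n")
        with pytest.raises(DataError, match="line 2"):
            read_gmt(p)

    def test_empty_gene_list_errors(self, tmp_path):
        p = tmp_path / "x.gmt"
        p.write_text("t1\tdesc\t\t\n")
        with pytest.raises(DataError):
            read_gmt(p)

    def test_round_trip_modulo_case(self, tmp_path):
        p = tmp_path / "x.gmt"
        p.write_text("t1\tfirst\tGeneA\tgeneB\nt2\tsecond\tGENEC\tgenea\n")
        lib = read_gmt(p)
        write_gmt(lib, tmp_path / "y.gmt")
        lib2 = read_gmt(tmp_path / "y.gmt", name=lib.name)
        assert lib2.sets == lib.sets
        assert lib2.universe == lib.universe

    def test_set_must_be_subset_of_explicit_universe(self):
        with pytest.raises(DataError, match="subset"):
            GeneSetLibrary(
                name="x",
                sets={"t": ("d", frozenset({"A", "Z"}))},
                universe=frozenset({"A", "B"}),
            )


class TestEdgeList:
    def test_dedup_and_self_loop_drop(self, tmp_path):
        p = tmp_path / "e.tsv"
        p.write_text("A\tB\t0.9\nB\tA\t0.9\nC\tC\t0.5\n")
        net = read_edge_list(p, kind="ppi_undirected")
        assert net.n_edges == 1
        assert net.meta["self_loops_dropped"] == 1
        assert net.edge_set() == frozenset({("A", "B")})

    def test_threshold_filters(self, tmp_path):
        p = tmp_path / "e.tsv"
        p.write_text("A\tB\t0.9\nC\tD\t0.5\n")
        net = read_edge_list(p, kind="ppi_undirected", weight_threshold=0.7)
        assert net.edge_set() == frozenset({("A", "B")})

    def test_threshold_matches_linear_scan(self, tmp_path, rng):
        rows, expected = [], {}
        for i in range(100):
            a, b, w = f"N{i}", f"M{i}", round(float(rng.uniform(0, 1)), 3)
            rows.append(f"{a}\t{b}\t{w}")
            expected[(a, b)] = w
        p = tmp_path / "e.tsv"
        p.write_text("\n".join(rows) + "\n")
        t = 0.6
        net = read_edge_list(p, kind="ppi_undirected", weight_threshold=t)
        brute = sum(1 for w in expected.values() if w >= t)
        assert net.n_edges == brute

    def test_string_score_autodetect(self, tmp_path):
        p = tmp_path / "e.tsv"
        p.write_text("A\tB\t900\nC\tD\t400\n")
        net = read_edge_list(p, kind="ppi_undirected", weight_threshold=0.5)
        assert net.edge_set() == frozenset({("A", "B")})

    def test_ppi_weight_out_of_range_rejected(self):
        with pytest.raises(DataError, match=r"\[0,1\]"):
            build_network("ppi_undirected", [("A", "B", 1.5)])

    def test_bipartite_same_class_edge_rejected(self, tmp_path):
        # regulator appearing as a target creates a cross-class conflict
        import networkx as nx

        from diseasomics.dataio import InteractionNetwork

        g = nx.Graph()
        g.add_node("TF1", node_class="regulator")
        g.add_node("TF2", node_class="regulator")
        g.add_edge("TF1", "TF2")
        with pytest.raises(DataError, match="regulator"):
            InteractionNetwork(kind="regulator_bipartite", graph=g)


class TestWriteNetwork:
    @pytest.fixture
    def ppi(self):
        return build_network(
            "ppi_undirected", [("B", "A", 0.9), ("C", "B", 0.5), ("D", "A", 0.7)]
        )

    def test_tsv_round_trip_lossless(self, ppi, tmp_path):
        write_network(ppi, tmp_path / "n.tsv", format="tsv")
        back = read_edge_list(tmp_path / "n.tsv", kind="ppi_undirected")
        assert back.edge_set() == ppi.edge_set()

    def test_bipartite_tsv_round_trip_preserves_classes(self, tmp_path):
        net = build_network("drug_bipartite", [("aspirin", "PTGS2", 1.0), ("aspirin", "PTGS1", 1.0)])
        write_network(net, tmp_path / "d.tsv", format="tsv")
        back = read_edge_list(tmp_path / "d.tsv", kind="drug_bipartite")
        assert back.edge_set() == net.edge_set()
        assert back.nodes_of_class("drug") == frozenset({"aspirin"})

    def test_canonicalization_idempotent(self, ppi, tmp_path):
        write_network(ppi, tmp_path / "1.tsv", format="tsv")
        once = read_edge_list(tmp_path / "1.tsv", kind="ppi_undirected")
        write_network(once, tmp_path / "2.tsv", format="tsv")
        twice = read_edge_list(tmp_path / "2.tsv", kind="ppi_undirected")
        assert (tmp_path / "1.tsv").read_text() == (tmp_path / "2.tsv").read_text()
        assert twice.edge_set() == once.edge_set()

    def test_graphml_round_trip_via_networkx(self, ppi, tmp_path):
        import networkx as nx

        write_network(ppi, tmp_path / "n.graphml", format="graphml")
        g = nx.read_graphml(tmp_path / "n.graphml")
        assert frozenset(tuple(sorted(e)) for e in g.edges()) == ppi.edge_set()

    def test_sif_format(self, ppi, tmp_path):
        write_network(ppi, tmp_path / "n.sif", format="sif")
        lines = (tmp_path / "n.sif").read_text().splitlines()
        assert "A\tinteracts\tB" in lines

    def test_unknown_format_errors(self, ppi, tmp_path):
        with pytest.raises(DataError, match="format"):
            write_network(ppi, tmp_path / "n.xyz", format="xyz")


def test_read_gene_list_uppercases_and_skips_comments(tmp_path):
    p = tmp_path / "genes.txt"
    p.write_text("# disease genes\ntp53\nBRCA1\n\n")
    assert read_gene_list(p) == frozenset({"TP53", "BRCA1"})
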