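import itertools

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hapnetrec import build_median_network, export_network, external_branch
from hapnetrec.mednet import DimensionalityError

from conftest import make_binary


class TestBuildMedianNetwork:
    def test_two_haplotypes_single_edge(self):
        b = make_binary({"og": "00000000", "h1": "00100010"}, "og")
        net = build_median_network(b)
        assert len(net.graph) == 2
        assert net.edge_sites("og", "h1") == (3, 7)

    def test_fig1_rectangle_structure(self, fig1_binary):
        net = build_median_network(fig1_binary)
        rects = net.rectangles()
        assert len(rects) == 1
        corners = sorted(set().union(*rects[0]))
        # all four corners are latent medians; haplotypes hang off them
        assert all(c.startswith("m") for c in corners)
        labels = sorted(
            tuple(net.edge_sites(u, v))
            for u, v in itertools.combinations(corners, 2)
            if net.graph.has_edge(u, v)
        )
        assert labels == [(2, 4, 5), (2, 4, 5), (8, 11), (8, 11)]

    def test_duplicate_rows_rejected(self):
        b = make_binary({"og": "000", "h1": "010", "h2": "010"}, "og")
        with pytest.raises(ValueError, match="duplicate"):
            build_median_network(b)

    def test_dimensionality_overflow_names_haplotypes(self):
        # two mutually incompatible characters need a rectangle: max_dim=1
        b = make_binary(
            {"og": "0000", "a": "1100", "b": "0011", "c": "1111"}, "og"
        )
        with pytest.raises(DimensionalityError) as err:
            build_median_network(b, max_dim=1)
        assert set(err.value.haplotypes) >= {"a", "b", "c"}

    def test_compatible_data_is_cycle_free(self):
        b = make_binary(
            {"og": "000000", "a": "110000", "b": "110110", "c": "000001"}, "og"
        )
        net = build_median_network(b)
        assert net.rectangles() == []
        assert nx.cycle_basis(net.graph) == []

    def test_hamming_conservation_on_reconstruction(self, abo54_binary):
        # shortest-path label counts equal raw Hamming distances: the network
        # hides no homoplasy between observed haplotypes
        net = build_median_network(abo54_binary)
        g = net.graph
        w = {(u, v): len(d["sites"]) for u, v, d in g.edges(data=True)}
        w.update({(v, u): c for (u, v), c in w.items()})
        for a, b in itertools.combinations(abo54_binary.names, 2):
            ham = int(np.sum(abo54_binary.row(a) != abo54_binary.row(b)))
            sp = nx.shortest_path_length(
                g, a, b, weight=lambda u, v, d: len(d["sites"])
            )
            assert sp == ham

    @given(st.integers(0, 10**6))
    @settings(max_examples=15, deadline=None)
    def test_hamming_conservation_random(self, seed):
        rng = np.random.default_rng(seed)
        n, L = 4, 8
        rows = {"og": "0" * L}
        for i in range(n):
            rows[f"h{i}"] = "".join(map(str, rng.integers(0, 2, L)))
        if len(set(rows.values())) < len(rows):
            return  # duplicates are rejected by construction; nothing to test
        b = make_binary(rows, "og")
        try:
            net = build_median_network(b, max_dim=4)
        except DimensionalityError:
            return
        for a, c in itertools.combinations(rows, 2):
            ham = sum(x != y for x, y in zip(rows[a], rows[c]))
            sp = nx.shortest_path_length(
                net.graph, a, c, weight=lambda u, v, d: len(d["sites"])
            )
            assert sp == ham

    def test_every_site_labels_an_edge(self, abo54_binary):
        net = build_median_network(abo54_binary)
        on_edges = set()
        for _, _, d in net.graph.edges(data=True):
            on_edges.update(d["sites"])
        segregating = {
            j + 1
            for j in range(abo54_binary.n_sites)
            if 0 < int(abo54_binary.data[:, j].sum()) < len(abo54_binary.names)
        }
        assert on_edges == segregating


class TestExternalBranch:
    def test_fig1_branches(self, fig1_binary):
        net = build_median_network(fig1_binary)
        assert sorted(external_branch(net, "p1").sites) == [9, 13, 15]
        assert sorted(external_branch(net, "p2").sites) == [1, 6, 12]
        assert external_branch(net, "r1").sites == [7]
        assert external_branch(net, "r1").length == 1

    def test_branching_vertex_has_zero_length(self):
        # h2 sits directly on the junction of two branches
        b = make_binary(
            {"og": "0000", "h1": "1100", "h2": "1000", "h3": "1011"}, "og"
        )
        net = build_median_network(b)
        eb = external_branch(net, "h2")
        assert eb.length == 0 and eb.note is not None


class TestParallelSites:
    def test_independent_origins_flagged(self):
        # lone site 9 conflicts with the two-site clades of W and X:
        # more parsimoniously two parallel hits than a transferred segment
        rows = {
            "og": "000000000",
            "W": "110100001",
            "A": "110000000",
            "X": "000011101",
            "B": "000011000",
        }
        b = make_binary(rows, "og")
        net = build_median_network(b, max_dim=3)
        flagged = net.candidate_parallel_sites()
        assert 9 in flagged and flagged[9] == 2

    def test_clean_splits_not_flagged(self, fig1_binary):
        net = build_median_network(fig1_binary)
        assert net.candidate_parallel_sites() == {}


class TestExport:
    def test_graphml_two_node(self, tmp_path):
        b = make_binary({"og": "000", "h1": "011"}, "og")
        net = build_median_network(b)
        p = export_network(net, tmp_path / "n.graphml", "graphml")
        g = nx.read_graphml(p)
        assert len(g) == 2 and g.size() == 1
        (u, v), = g.edges()
        assert g.edges[u, v]["sites"] == "2,3"

    def test_dot_shows_rectangle_cycle(self, fig1_binary, tmp_path):
        net = build_median_network(fig1_binary)
        p = export_network(net, tmp_path / "n.dot", "dot")
        text = p.read_text()
        g = nx.Graph()
        for line in text.splitlines():
            if " -- " in line:
                u, v = [x.strip().strip('"') for x in
                        line.split("[")[0].split("--")]
                g.add_edge(u, v)
        assert any(len(c) == 4 for c in nx.cycle_basis(g))

    def test_empty_network_rejected(self, tmp_path):
        import hapnetrec.mednet as mednet

        net = mednet.MedianNetwork(nx.Graph(), [], None, {})
        with pytest.raises(ValueError, match="empty"):
            export_network(net, tmp_path / "n.graphml")
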