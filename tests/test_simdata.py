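from collections import Counter

import numpy as np
import pytest

from hapnetrec import (
    RecoveryDesign,
    abo_scenario,
    build_median_network,
    detect_rectangle_recombinants,
    encode_binary,
    fig1_config,
    fig1_fixture,
    pnarec_scan,
    explain_scan,
    simulate,
)
from hapnetrec.mednet import DimensionalityError
from hapnetrec.simdata import Event, LineageSpec, SimulationConfig


class TestFig1Fixture:
    def test_state_vectors(self, fig1_binary):
        # derived sets relative to the ancestor, re-polarised against o'
        assert fig1_binary.derived_sites("r1") == [2, 3, 4, 5, 7, 8, 10, 11, 14]
        assert fig1_binary.derived_sites("o_prime") == []

    def test_reciprocal_recombinant_absent(self, fig1):
        matrix, _ = fig1
        assert "r2" not in matrix.names

    def test_pairwise_hamming_distances(self, fig1_binary):
        def d(a, b):
            return int(np.sum(fig1_binary.row(a) != fig1_binary.row(b)))

        # r1 differs from p1 by p1's 3'-side changes {9,13,15} plus r1's
        # 3'-segment content {7,8,11}; from p2 by {1,6,12} + {2,4,5,7}
        assert d("p1", "r1") == 6
        assert d("p2", "r1") == 7
        assert d("p1", "p2") == 11

    def test_truth_record(self, fig1):
        _, truth = fig1
        assert truth.recombinant == "r1"
        assert (truth.parent_forward, truth.parent_backward) == ("p1", "p2")
        assert truth.breakpoint == (6, 7)


class TestSimulate:
    def test_deterministic_given_seed(self):
        cfg = fig1_config(seed=7)
        m1, t1 = simulate(cfg)
        m2, t2 = simulate(cfg)
        assert m1.rows == m2.rows and t1 == t2

    def test_no_events_yields_no_calls(self):
        cfg = SimulationConfig(
            n_sites=20,
            lineages=[
                LineageSpec("anc", None, 0),
                LineageSpec("a", "anc", 3),
                LineageSpec("b", "anc", 3),
                LineageSpec("c", "anc", 3),
            ],
            outgroup_subs=2,
            seed=5,
        )
        matrix, truth = simulate(cfg)
        assert truth == []
        binary = encode_binary(matrix)
        net = build_median_network(binary)
        assert detect_rectangle_recombinants(net, binary) == []
        assert pnarec_scan(binary, selection=["a", "b", "c"]) == []

    def test_fig1_schedule_matches_fixture_up_to_relabelling(self):
        fixture, _ = fig1_fixture()
        sim, [truth] = simulate(fig1_config(seed=11))
        assert truth.recombinant == "r1"
        order_fix = ["o_prime", "p1", "p2", "r1"]
        order_sim = ["outgroup", "p1", "p2", "r1"]
        fb, sb = encode_binary(fixture), encode_binary(sim)
        pat_fix = Counter(
            tuple(int(fb.row(n)[j]) for n in order_fix)
            for j in range(fb.n_sites)
        )
        pat_sim = Counter(
            tuple(int(sb.row(n)[j]) for n in order_sim)
            for j in range(sb.n_sites)
        )
        assert pat_fix == pat_sim

    def test_infinite_sites_one_origin_per_site(self):
        cfg = fig1_config(seed=3)
        matrix, _ = simulate(cfg)
        binary = encode_binary(matrix)
        # total substitutions drawn == segregating site count: no site is
        # ever hit twice
        n_seg = sum(
            1
            for j in range(binary.n_sites)
            if 0 < int(binary.data[:, j].sum())
        )
        budget = 3 + 2 + 3 + 3 + 1 + 3  # lineage + post-event + outgroup draws
        assert n_seg == budget

    def test_budget_overflow_rejected(self):
        cfg = SimulationConfig(
            n_sites=4,
            lineages=[LineageSpec("anc", None, 0), LineageSpec("a", "anc", 5)],
            seed=0,
        )
        with pytest.raises(ValueError, match="budget"):
            simulate(cfg)

    def test_gene_conversion_tract(self):
        cfg = SimulationConfig(
            n_sites=12,
            lineages=[
                LineageSpec("anc", None, 0),
                LineageSpec("donor", "anc", 4, window=(1, 8)),
                LineageSpec("acceptor", "anc", 2, window=(9, 12)),
            ],
            events=[
                Event("gene_conversion", "mosaic", "donor", "acceptor",
                      tract=(3, 6))
            ],
            seed=2,
        )
        matrix, [truth] = simulate(cfg)
        assert truth.event == "gene_conversion" and truth.tract == (3, 6)
        b = encode_binary(matrix, outgroup_id="anc")
        donor, acceptor, mosaic = (
            b.row("donor"), b.row("acceptor"), b.row("mosaic")
        )
        assert (mosaic[2:6] == donor[2:6]).all()
        outside = [j for j in range(12) if not 2 <= j < 6]
        assert all(mosaic[j] == acceptor[j] for j in outside)


@pytest.fixture(scope="module")
def scenario():
    matrix, truth = simulate(abo_scenario(seed=1))
    return matrix, truth, encode_binary(matrix)


class TestAboScenario:
    def test_truth_records(self, scenario):
        _, truth, _ = scenario
        events = {t.recombinant: t for t in truth}
        assert events["A101"].parent_forward == "B101"
        assert events["A101"].parent_backward == "O01"
        assert events["XV"].parent_forward == "O02"

    def test_marker_transfer(self, scenario):
        matrix, _, _ = scenario
        carriers = matrix.marker("Δ261").carriers
        assert carriers == frozenset({"O02", "O01", "XV"})  # not A101

    def test_full_set_needs_curation(self, scenario):
        # all five lineages produce reticulation beyond three dimensions,
        # mirroring the need to exclude haplotypes before drawing a network
        _, _, binary = scenario
        with pytest.raises(DimensionalityError):
            build_median_network(binary)

    def test_network_calls_recombinant_a(self, scenario):
        _, truth, binary = scenario
        sub = binary.subset(["A101", "B101", "O01", "O02", "chimp"])
        net = build_median_network(sub)
        calls = {c.recombinant: c for c in detect_rectangle_recombinants(net, sub)}
        a = calls["A101"]
        assert (a.parent_forward, a.parent_backward) == ("B101", "O01")
        tr = next(t for t in truth if t.recombinant == "A101")
        assert a.interval[0] <= tr.breakpoint[0] <= tr.breakpoint[1] <= a.interval[1]

    def test_network_calls_recombinant_xv(self, scenario):
        _, truth, binary = scenario
        sub = binary.subset(["B101", "O02", "XV", "chimp"])
        net = build_median_network(sub)
        calls = {c.recombinant: c for c in detect_rectangle_recombinants(net, sub)}
        xv = calls["XV"]
        assert {xv.parent_forward, xv.parent_backward} == {"O02", "B101"}
        tr = next(t for t in truth if t.recombinant == "XV")
        assert xv.interval[0] <= tr.breakpoint[0] <= tr.breakpoint[1] <= xv.interval[1]

    def test_quartet_scan_rejects_o01_at_empty_split_step(self, scenario):
        matrix, _, binary = scenario
        ingroup = [n for n in matrix.names if n != "chimp"]
        audits = {a.trio: a for a in explain_scan(binary, selection=ingroup)}
        assert audits[("B101", "O01", "O02")].rejected_at == "C"
        calls = pnarec_scan(binary, selection=ingroup)
        assert [c.recombinant for c in calls] == ["A101"]


class TestRecoveryDesign:
    def test_null_design_has_no_reticulation(self):
        matrix, truth = simulate(RecoveryDesign(event=False).config(seed=9))
        assert truth == []
        binary = encode_binary(matrix)
        net = build_median_network(binary)
        assert net.rectangles() == []
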