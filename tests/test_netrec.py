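import numpy as np
import pytest

from hapnetrec import (
    breakpoint_interval,
    build_median_network,
    describe_interval,
    detect_rectangle_recombinants,
    parallel_substitution_cost,
    refine_call_with_marker,
    refine_with_marker,
)
from hapnetrec.model import Marker, RecombinationCall

from conftest import make_binary


def call_with(support_forward, support_backward, **kw):
    defaults = dict(
        recombinant="r",
        parent_forward="p1",
        parent_backward="p2",
        interval=(max(support_forward), min(support_backward))
        if support_forward and support_backward
        else (0, 0),
        support_forward=tuple(support_forward),
        support_backward=tuple(support_backward),
        method="network",
    )
    defaults.update(kw)
    return RecombinationCall(**defaults)


class TestDetect:
    def test_worked_model_call(self, fig1_binary):
        net = build_median_network(fig1_binary)
        [call] = detect_rectangle_recombinants(net, fig1_binary)
        assert call.recombinant == "r1"
        assert (call.parent_forward, call.parent_backward) == ("p1", "p2")
        assert call.support_forward == (2, 4, 5)
        assert call.support_backward == (8, 11)
        assert call.interval == (5, 8)
        assert call.alt_cost == (2, 3)
        assert not call.low_confidence

    def test_treelike_network_yields_no_calls(self):
        b = make_binary(
            {"og": "000000", "a": "110000", "b": "001100", "c": "000011"}, "og"
        )
        net = build_median_network(b)
        assert detect_rectangle_recombinants(net, b) == []

    def test_reconstruction_reproduces_published_calls(self, abo54_binary):
        net = build_median_network(abo54_binary)
        calls = {c.recombinant: c for c in
                 detect_rectangle_recombinants(net, abo54_binary)}
        assert set(calls) == {"A101-A201-O09", "O01"}
        o01 = calls["O01"]
        assert (o01.parent_forward, o01.parent_backward) == ("B101", "O02")
        assert o01.support_forward == (11, 19, 20, 21, 23, 25, 28, 29, 30, 31, 32)
        assert o01.support_backward == (42, 47, 48, 49)
        assert o01.interval == (32, 42)
        a = calls["A101-A201-O09"]
        assert (a.parent_forward, a.parent_backward) == ("O01", "B101")
        assert a.support_forward == (9, 13, 15)
        assert a.support_backward == (36, 37, 46, 50, 51, 52, 53)
        assert a.interval == (15, 36)

    def test_missing_parental_lineage_not_called(self, abo54_binary):
        # a known recombinant whose parent lineage is absent from the data
        # (the O47 situation) must stay uncalled rather than be guessed
        net = build_median_network(abo54_binary)
        calls = detect_rectangle_recombinants(net, abo54_binary)
        assert all(c.recombinant != "O47" for c in calls)

    def test_single_site_support_flagged_low_confidence(self):
        b = make_binary(
            {
                "og": "000000000",
                "p1": "110000110",
                "p2": "001100001",
                "r": "100100000",
            },
            "og",
        )
        net = build_median_network(b)
        [call] = detect_rectangle_recombinants(net, b)
        assert call.low_confidence

    def test_row_order_invariance(self, abo54_binary):
        perm = ["O47", "O01", "chimp", "B101", "A101-A201-O09", "O02"]
        shuffled = abo54_binary.subset(perm)
        net_a = build_median_network(abo54_binary)
        net_b = build_median_network(shuffled)
        as_tuples = lambda calls: sorted(
            (c.recombinant, c.parent_forward, c.parent_backward, c.interval)
            for c in calls
        )
        assert as_tuples(detect_rectangle_recombinants(net_a, abo54_binary)) == (
            as_tuples(detect_rectangle_recombinants(net_b, shuffled))
        )


class TestBreakpointInterval:
    def test_published_interval(self):
        call = call_with((11, 19, 20, 21, 23, 25, 28, 29, 30, 31, 32),
                         (42, 47, 48, 49))
        assert breakpoint_interval(call) == (32, 42)

    def test_worked_model_contains_true_breakpoint(self):
        call = call_with((2, 4, 5), (8, 11))
        left, right = breakpoint_interval(call)
        assert (left, right) == (5, 8)
        assert left <= 6 and 7 <= right

    def test_interleaved_supports_rejected_as_mosaic(self):
        call = call_with((2, 9), (5, 11), interval=(9, 5))
        with pytest.raises(ValueError, match="mosaic"):
            breakpoint_interval(call)

    def test_feature_description(self, abo54_binary):
        assert describe_interval((32, 42), abo54_binary) == (
            "between intron 1 and intron 3"
        )
        assert describe_interval((15, 36), abo54_binary) == (
            "between intron 2 and exon 6"
        )


class TestMarkerRefinement:
    def test_recombinant_lacking_marker_narrows_right(self):
        # forward parent carries the deletion, recombinant does not: the
        # crossover must lie 5' of the marker
        mk = Marker("Δ261", 15, 16)
        assert refine_with_marker((15, 36), mk, False, True, False) == (15, "Δ261")

    def test_recombinant_carrying_marker_narrows_right(self):
        # the backward parent carries the deletion and so does the
        # recombinant: the marker segment came from the 3' side, so the
        # crossover is 5' of the marker
        mk = Marker("Δ261", 15, 16)
        assert refine_with_marker((12, 16), mk, True, False, True) == (12, "Δ261")

    def test_marker_from_forward_parent_narrows_left(self):
        mk = Marker("Δ261", 15, 16)
        assert refine_with_marker((12, 20), mk, True, True, False) == ("Δ261", 20)
        assert refine_with_marker((12, 20), mk, False, True, False) == (12, "Δ261")

    def test_marker_outside_interval_is_noop(self):
        mk = Marker("Δ261", 25, 26)
        with pytest.warns(UserWarning, match="outside"):
            assert refine_with_marker((20, 24), mk, True, True, False) == (20, 24)

    def test_parents_agreeing_is_uninformative(self):
        mk = Marker("Δ261", 15, 16)
        with pytest.warns(UserWarning, match="uninformative"):
            assert refine_with_marker((12, 20), mk, True, True, True) == (12, 20)

    def test_call_refinement_uses_carrier_sets(self, abo54_binary):
        net = build_median_network(abo54_binary)
        calls = {c.recombinant: c for c in
                 detect_rectangle_recombinants(net, abo54_binary)}
        refined = refine_call_with_marker(
            calls["A101-A201-O09"], abo54_binary.marker("Δ261")
        )
        assert refined.interval == (15, "Δ261")


class TestParallelCost:
    def test_reconstruction_costs(self, abo54_binary):
        net = build_median_network(abo54_binary)
        calls = {c.recombinant: c for c in
                 detect_rectangle_recombinants(net, abo54_binary)}
        assert parallel_substitution_cost(calls["A101-A201-O09"]) == (7, 3)
        assert parallel_substitution_cost(calls["O01"]) == (4, 11)

    def test_worked_model_cost(self, fig1_binary):
        net = build_median_network(fig1_binary)
        [call] = detect_rectangle_recombinants(net, fig1_binary)
        assert parallel_substitution_cost(call) == (2, 3)
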