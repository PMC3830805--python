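"""Recombinant detection from the median-network rectangle signature.

A single crossover between two diverged haplotypes leaves a characteristic
reticulation: a rectangle whose opposing vertices carry the two parental
lineages (each with a long external branch of post-event private
substitutions), while the recombinant sits on the vertex opposing the path
toward the outgroup and carries a short external branch. The two parallel
edge pairs of the rectangle are labelled by the sites the recombinant shares
with each parent; the crossover must lie between the 5′-most class and the
3′-most class, which bounds the breakpoint interval.
"""

from __future__ import annotations

import itertools
import warnings
from typing import Optional, Sequence

from .mednet import MedianNetwork, external_branch
from .model import BinaryMatrix, Endpoint, Marker, RecombinationCall

__all__ = [
    "detect_rectangle_recombinants",
    "breakpoint_interval",
    "describe_interval",
    "refine_with_marker",
    "refine_call_with_marker",
    "parallel_substitution_cost",
]


def _char_distance(net: MedianNetwork, a: tuple[int, ...], b: tuple[int, ...]) -> int:
    """Site-weighted Hamming distance between character-state vectors."""
    return sum(
        ch.weight for ch, x, y in zip(net.characters, a, b) if x != y
    )


def detect_rectangle_recombinants(
    net: MedianNetwork,
    matrix: Optional[BinaryMatrix] = None,
    outgroup: Optional[str] = None,
) -> list[RecombinationCall]:
    """Scan every rectangle of ``net`` for the recombinant signature.

    A call is emitted for a rectangle iff (a) exactly one vertex is nearest
    the outgroup, (b) the observed haplotype anchored on the opposing vertex
    has a strictly shorter external branch than both parents', and (c) the
    remaining opposing vertex pair anchors the two parents. Forward/backward
    parents are assigned by site order of the shared edge labels; rectangles
    whose support classes interleave are skipped with a warning (conversion-
    like mosaic). Sites flagged as candidate parallel substitutions are
    removed from support lists and reported separately on the call.
    """
    og = outgroup or net.outgroup
    if og is None or og not in net.graph:
        raise ValueError(f"outgroup {og!r} not present in network")
    g = net.graph
    vec = {n: d["vector"] for n, d in g.nodes(data=True)}
    observed = [
        n for n, d in g.nodes(data=True) if d["observed"] and n != og
    ]
    parallel = net.candidate_parallel_sites()
    ext_len = {h: external_branch(net, h).length for h in observed}

    calls: dict[tuple[str, frozenset], RecombinationCall] = {}
    for diag1, diag2 in net.rectangles():
        u, v = sorted(diag1)
        x, y = sorted(diag2)
        corners = [u, x, v, y]
        d_og = {c: _char_distance(net, vec[c], vec[og]) for c in corners}
        ranked = sorted(corners, key=lambda c: d_og[c])
        if d_og[ranked[0]] == d_og[ranked[1]]:
            continue  # no unique vertex toward the outgroup
        og_corner = ranked[0]
        rec_corner = v if og_corner == u else u if og_corner == v else (
            y if og_corner == x else x
        )
        parent_corners = [c for c in corners if c not in (og_corner, rec_corner)]

        def host(corner: str) -> tuple[Optional[str], int]:
            if corner in observed:
                return corner, 0
            best, best_d = None, 0
            for h in observed:
                d_here = _char_distance(net, vec[h], vec[corner])
                others = min(
                    _char_distance(net, vec[h], vec[c])
                    for c in corners
                    if c != corner
                )
                if d_here >= others:
                    continue  # h is not uniquely anchored to this corner
                if best is None or d_here < best_d:
                    best, best_d = h, d_here
                elif d_here == best_d:
                    best = None  # ambiguous anchoring
            return best, best_d

        r, d_r = host(rec_corner)
        p1, d_p1 = host(parent_corners[0])
        p2, d_p2 = host(parent_corners[1])
        if r is None or p1 is None or p2 is None:
            continue
        anchor_cost = d_r + d_p1 + d_p2
        if len({r, p1, p2}) < 3:
            continue
        if not (ext_len[r] < ext_len[p1] and ext_len[r] < ext_len[p2]):
            continue  # recombinant must have the strictly shorter branch

        sup = {}
        excluded: list[int] = []
        for p, corner in ((p1, parent_corners[0]), (p2, parent_corners[1])):
            sites = list(net.edge_sites(og_corner, corner))
            keep = [s for s in sites if s not in parallel]
            excluded += [s for s in sites if s in parallel]
            sup[p] = sorted(keep)
        if not sup[p1] or not sup[p2]:
            continue
        if max(sup[p1]) < min(sup[p2]):
            fwd, bwd = p1, p2
        elif max(sup[p2]) < min(sup[p1]):
            fwd, bwd = p2, p1
        else:
            warnings.warn(
                f"rectangle around {r}: support classes interleave "
                "(conversion-like mosaic); no simple crossover called",
                stacklevel=2,
            )
            continue
        call = RecombinationCall(
            recombinant=r,
            parent_forward=fwd,
            parent_backward=bwd,
            interval=(max(sup[fwd]), min(sup[bwd])),
            support_forward=tuple(sup[fwd]),
            support_backward=tuple(sup[bwd]),
            method="network",
            alt_cost=(len(sup[bwd]), len(sup[fwd])),
            excluded_parallel_sites=tuple(sorted(excluded)),
            low_confidence=min(len(sup[fwd]), len(sup[bwd])) < 2,
        )
        # stacked rectangles from nested characters can imply the same event;
        # keep the rectangle anchored closest to the named haplotypes
        key = (r, frozenset((fwd, bwd)))
        if key not in calls or anchor_cost < calls[key][0]:
            calls[key] = (anchor_cost, call)
    return [calls[k][1] for k in sorted(calls, key=lambda k: k[0])]


def breakpoint_interval(
    call: RecombinationCall, matrix: Optional[BinaryMatrix] = None
) -> tuple[Endpoint, Endpoint]:
    """(largest 5′ supporting site, smallest 3′ supporting site).

    Raises ``ValueError`` when the two support distributions interleave —
    the hallmark of a conversion-like mosaic rather than a single crossover.
    """
    if not call.support_forward or not call.support_backward:
        raise ValueError("both support lists must be non-empty")
    left = max(call.support_forward)
    right = min(call.support_backward)
    if left >= right:
        raise ValueError(
            f"support distributions overlap (5' max {left} >= 3' min {right}): "
            "non-simple, conversion-like mosaic"
        )
    return (left, right)


def describe_interval(
    interval: tuple[Endpoint, Endpoint], matrix: BinaryMatrix
) -> str:
    """Human-readable location, e.g. ``between intron 1 and intron 3``."""

    def name(e: Endpoint) -> str:
        if isinstance(e, str):
            return e
        feat = matrix.sites[e - 1].feature
        return feat if feat else f"site {e}"

    return f"between {name(interval[0])} and {name(interval[1])}"


def refine_with_marker(
    interval: tuple[Endpoint, Endpoint],
    marker: Marker,
    recombinant_carries: bool,
    forward_carries: bool,
    backward_carries: bool,
) -> tuple[Endpoint, Endpoint]:
    """Narrow a breakpoint interval using a non-SNP landmark inside it.

    The recombinant's marker state reveals which parent donated the segment
    containing the marker: matching the backward parent places the crossover
    5′ of the marker (right endpoint becomes the marker), matching the
    forward parent places it 3′ (left endpoint becomes the marker). A marker
    outside the interval, or one on which the parents agree, is uninformative
    and leaves the interval unchanged with a warning.
    """
    left, right = interval
    pos = marker.left + 0.5
    if not (isinstance(left, int) and isinstance(right, int)):
        warnings.warn("interval endpoint already a marker; not refined", stacklevel=2)
        return interval
    if not left < pos < right:
        warnings.warn(
            f"marker {marker.name!r} at {marker.left}/{marker.right} lies "
            f"outside interval ({left}, {right}); not refined",
            stacklevel=2,
        )
        return interval
    if forward_carries == backward_carries:
        warnings.warn(
            f"parents agree on marker {marker.name!r}; uninformative",
            stacklevel=2,
        )
        return interval
    if recombinant_carries == backward_carries:
        return (left, marker.name)
    return (marker.name, right)


def refine_call_with_marker(
    call: RecombinationCall, marker: Marker
) -> RecombinationCall:
    """Apply :func:`refine_with_marker` using the marker's carrier set.

    Inapplicable markers (outside the interval, or already-refined
    endpoints) leave the call unchanged without warning, so a marker list
    can be applied across all calls wholesale.
    """
    left, right = call.interval
    if not (isinstance(left, int) and isinstance(right, int)):
        return call
    if not left < marker.left + 0.5 < right:
        return call
    new_interval = refine_with_marker(
        call.interval,
        marker,
        call.recombinant in marker.carriers,
        call.parent_forward in marker.carriers,
        call.parent_backward in marker.carriers,
    )
    if new_interval == call.interval:
        return call
    return RecombinationCall(
        recombinant=call.recombinant,
        parent_forward=call.parent_forward,
        parent_backward=call.parent_backward,
        interval=new_interval,
        support_forward=call.support_forward,
        support_backward=call.support_backward,
        method=call.method,
        alt_cost=call.alt_cost,
        excluded_parallel_sites=call.excluded_parallel_sites,
        low_confidence=call.low_confidence,
        notes=call.notes + (f"interval refined with marker {marker.name}",),
    )


def parallel_substitution_cost(
    call: RecombinationCall, matrix: Optional[BinaryMatrix] = None
) -> tuple[int, int]:
    """Parallel substitutions needed to explain the data without recombination.

    Clustering the recombinant with its forward parent forces every backward
    supporting site to arise twice, and vice versa.
    """
    return (len(call.support_backward), len(call.support_forward))
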