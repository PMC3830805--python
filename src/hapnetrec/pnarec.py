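"""The five-step quartet algorithm for recombinant-descendant detection.

For every triple of ingroup haplotypes plus the outgroup, the biallelic
sites are classified by which of the three possible quartet splits they
support (a site is phylogenetically informative when exactly two quartet
members share one allele and the other two share the other). A quartet
containing a simple recombinant shows a diagnostic pattern: the split
grouping the two parents together is empty, while the two splits pairing the
recombinant with each parent are populated by sites occupying disjoint
positional ranges — the crossover lies between them.

Steps: (A) count singleton sites per haplotype; (B) classify informative
sites for every quartet; (C) keep quartets with exactly one empty split —
the candidate recombinant is the member grouped with the outgroup in that
split; (D) keep quartets whose two populated splits occupy disjoint site
ranges; (E) among survivors choose the quartet whose candidate has the
fewest singletons, breaking ties by the largest parental singleton sum
(i.e. prefer parents with longer external branches).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .model import BinaryMatrix, RecombinationCall

__all__ = [
    "SingletonProfile",
    "SplitCounts",
    "QuartetAudit",
    "singleton_profile",
    "split_counts",
    "pnarec_scan",
    "explain_scan",
]


@dataclass
class SingletonProfile:
    """Per-haplotype counts of sites whose derived allele is private to it."""

    counts: dict[str, int]
    sites: dict[str, list[int]]


@dataclass
class SplitCounts:
    """Informative-site classes for one quartet (three ingroup + outgroup).

    ``classes`` maps each ingroup pair (a, b) — meaning the split
    {a, b | c, outgroup} — to the ordinals supporting it.
    """

    quartet: tuple[str, str, str, str]
    classes: dict[tuple[str, str], list[int]]


@dataclass
class QuartetAudit:
    """Why one quartet survived or fell at each step."""

    trio: tuple[str, str, str]
    class_sizes: dict[tuple[str, str], int]
    rejected_at: Optional[str]  # "C", "D", "E" or None (selected)
    reason: Optional[str] = None
    candidate: Optional[str] = None
    candidate_singletons: Optional[int] = None
    parental_singleton_sum: Optional[int] = None
    selected: bool = False


def singleton_profile(
    matrix: BinaryMatrix, selection: Optional[Sequence[str]] = None
) -> SingletonProfile:
    """Count derived alleles private to one haplotype in selection + outgroup."""
    og = matrix.outgroup_id
    if og is None:
        raise ValueError("matrix has no outgroup")
    if selection is None:
        selection = [n for n in matrix.names if n != og]
    selection = [n for n in selection if n != og]
    if not selection:
        raise ValueError("empty selection")
    universe = list(selection) + [og]
    rows = {n: matrix.row(n) for n in universe}
    counts = {n: 0 for n in universe}
    sites: dict[str, list[int]] = {n: [] for n in universe}
    for j in range(matrix.n_sites):
        carriers = [n for n in universe if rows[n][j] == 1]
        if len(carriers) == 1:
            counts[carriers[0]] += 1
            sites[carriers[0]].append(j + 1)
    return SingletonProfile(counts, sites)


def split_counts(
    matrix: BinaryMatrix,
    trio: Sequence[str],
    outgroup: Optional[str] = None,
) -> SplitCounts:
    """Classify informative sites for the quartet trio + outgroup."""
    og = outgroup or matrix.outgroup_id
    if og is None:
        raise ValueError("no outgroup given")
    names = list(trio)
    if len(set(names) | {og}) != 4:
        raise ValueError(f"quartet members must be four distinct rows: {names} + {og}")
    rows = {n: matrix.row(n) for n in names + [og]}
    x, y, z = names
    pairs = [(x, y), (x, z), (y, z)]
    classes: dict[tuple[str, str], list[int]] = {p: [] for p in pairs}
    for j in range(matrix.n_sites):
        states = {n: int(rows[n][j]) for n in names + [og]}
        if sum(states.values()) != 2:
            continue  # monomorphic, singleton or triple: not informative
        ones = tuple(sorted(n for n, s in states.items() if s == 1))
        for a, b in pairs:
            c = next(n for n in names if n not in (a, b))
            if ones == tuple(sorted((a, b))) or ones == tuple(sorted((c, og))):
                classes[(a, b)].append(j + 1)
                break
    return SplitCounts((x, y, z, og), classes)


def _range(sites: Sequence[int]) -> tuple[int, int]:
    return (min(sites), max(sites))


def explain_scan(
    matrix: BinaryMatrix,
    outgroup: Optional[str] = None,
    selection: Optional[Sequence[str]] = None,
) -> list[QuartetAudit]:
    """Run Steps A-E over all quartets, recording every decision."""
    og = outgroup or matrix.outgroup_id
    if og is None or og not in matrix.names:
        raise ValueError(f"outgroup {og!r} not in matrix")
    if selection is None:
        selection = [n for n in matrix.names if n != og]
    selection = [n for n in selection if n != og]
    if len(selection) < 3:
        raise ValueError("need at least three ingroup haplotypes")
    profile = singleton_profile(matrix, selection)
    uncertain = set(matrix.uncertain_sites)

    audits: list[QuartetAudit] = []
    for trio in itertools.combinations(sorted(selection), 3):
        sc = split_counts(matrix, trio, og)
        # polarity-uncertain sites cannot be trusted in the empty-split test
        classes = {
            pair: [s for s in sites if s not in uncertain]
            for pair, sites in sc.classes.items()
        }
        sizes = {pair: len(sites) for pair, sites in classes.items()}
        audit = QuartetAudit(trio, sizes, rejected_at=None)
        empties = [pair for pair, sites in classes.items() if not sites]
        if len(empties) != 1:
            audit.rejected_at = "C"
            audit.reason = (
                "no empty split" if not empties else
                f"{len(empties)} empty splits: star-like, candidate not unique"
            )
            audits.append(audit)
            continue
        empty_pair = empties[0]
        candidate = next(n for n in trio if n not in empty_pair)
        audit.candidate = candidate
        full = [(pair, classes[pair]) for pair in classes if classes[pair]]
        (pa, sa), (pb, sb) = full
        ra, rb = _range(sa), _range(sb)
        if not (ra[1] < rb[0] or rb[1] < ra[0]):
            audit.rejected_at = "D"
            audit.reason = f"class ranges {ra} and {rb} overlap"
            audits.append(audit)
            continue
        audit.candidate_singletons = profile.counts[candidate]
        parents = [n for n in trio if n != candidate]
        audit.parental_singleton_sum = sum(profile.counts[p] for p in parents)
        audits.append(audit)

    survivors = [a for a in audits if a.rejected_at is None]
    if survivors:
        best = min(
            (a.candidate_singletons, -a.parental_singleton_sum) for a in survivors
        )
        for a in survivors:
            if (a.candidate_singletons, -a.parental_singleton_sum) == best:
                a.selected = True
            else:
                a.rejected_at = "E"
                a.reason = "outranked by quartet with better singleton scores"
    return audits


def pnarec_scan(
    matrix: BinaryMatrix,
    outgroup: Optional[str] = None,
    selection: Optional[Sequence[str]] = None,
) -> list[RecombinationCall]:
    """Steps A-E; returns the winning quartet(s) as recombination calls.

    Normally a single call; ties after both Step E criteria yield one call
    per tied quartet, each flagged. No surviving quartet yields an empty
    list.
    """
    og = outgroup or matrix.outgroup_id
    audits = explain_scan(matrix, og, selection)
    uncertain = set(matrix.uncertain_sites)
    calls = []
    selected = [a for a in audits if a.selected]
    for audit in selected:
        sc = split_counts(matrix, audit.trio, og)
        classes = {
            pair: [s for s in sites if s not in uncertain]
            for pair, sites in sc.classes.items()
        }
        full = [(pair, sites) for pair, sites in classes.items() if sites]
        (pa, sa), (pb, sb) = full
        if max(sa) < min(sb):
            (fwd_pair, fwd_sites), (bwd_pair, bwd_sites) = (pa, sa), (pb, sb)
        else:
            (fwd_pair, fwd_sites), (bwd_pair, bwd_sites) = (pb, sb), (pa, sa)
        cand = audit.candidate
        parent_fwd = next(n for n in fwd_pair if n != cand)
        parent_bwd = next(n for n in bwd_pair if n != cand)
        notes = ()
        if len(selected) > 1:
            notes = ("tied with other quartets at Step E",)
        calls.append(
            RecombinationCall(
                recombinant=cand,
                parent_forward=parent_fwd,
                parent_backward=parent_bwd,
                interval=(max(fwd_sites), min(bwd_sites)),
                support_forward=tuple(sorted(fwd_sites)),
                support_backward=tuple(sorted(bwd_sites)),
                method="pnarec",
                alt_cost=(len(bwd_sites), len(fwd_sites)),
                low_confidence=min(len(fwd_sites), len(bwd_sites)) < 2,
                notes=notes,
            )
        )
    return sorted(calls, key=lambda c: c.recombinant)
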