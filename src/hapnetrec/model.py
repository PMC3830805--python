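"""Core in-memory containers shared by every stage of the pipeline.

The analysis operates on phased, biallelic SNP haplotypes laid out as a
matrix: one row per haplotype, one ordered column per segregating site.
Site coordinates are 1-based ordinals (the convention of haplotype-network
figures), with genomic positions optional. Non-SNP landmarks such as the
ABO exon-6 deletion Δ261 cannot occupy a column of a SNP matrix; they are
"markers" pinned *between* two SNP ordinals, together with the set of
haplotypes known to carry them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Union

import numpy as np

__all__ = [
    "Site",
    "Marker",
    "HaplotypeMatrix",
    "BinaryMatrix",
    "HaplogroupAssignment",
    "RecombinationCall",
    "TruthRecord",
    "Endpoint",
]

#: An interval endpoint: a 1-based site ordinal, or a marker name (e.g. "Δ261").
Endpoint = Union[int, str]


@dataclass(frozen=True)
class Site:
    """One SNP column: 1-based ordinal, optional genomic position and feature."""

    index: int
    position: Optional[int] = None
    feature: Optional[str] = None


@dataclass(frozen=True)
class Marker:
    """A non-SNP landmark placed between two adjacent SNP ordinals.

    ``left`` and ``right`` are the flanking site ordinals (right = left + 1).
    ``carriers`` names the haplotypes that carry the landmark; markers are
    bookkeeping attached to the matrix, never a matrix column.
    """

    name: str
    left: int
    right: int
    carriers: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.right <= self.left:
            raise ValueError(
                f"marker {self.name!r}: right flank {self.right} must exceed "
                f"left flank {self.left}"
            )


@dataclass
class HaplotypeMatrix:
    """Named haplotype rows of single-character allele states over ordered sites."""

    names: list[str]
    rows: list[str]  # one string of allele symbols per haplotype
    sites: list[Site]
    populations: dict[str, str] = field(default_factory=dict)
    outgroup_id: Optional[str] = None
    markers: list[Marker] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.names) != len(self.rows):
            raise ValueError("names and rows differ in length")
        if len(set(self.names)) != len(self.names):
            dupes = sorted({n for n in self.names if self.names.count(n) > 1})
            raise ValueError(f"duplicate haplotype names: {dupes}")
        L = len(self.sites)
        for name, row in zip(self.names, self.rows):
            if len(row) != L:
                raise ValueError(
                    f"haplotype {name!r} has {len(row)} states, expected {L}"
                )
        for k, site in enumerate(self.sites, start=1):
            if site.index != k:
                raise ValueError("site indices must be contiguous from 1")
        positions = [s.position for s in self.sites if s.position is not None]
        if positions != sorted(positions):
            raise ValueError("site positions must be monotone along index order")
        for j in range(L):
            states = {row[j] for row in self.rows} - set("N?-.")
            if len(states) > 2:
                raise ValueError(
                    f"site {j + 1} is not biallelic: states {sorted(states)}"
                )

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_haplotypes(self) -> int:
        return len(self.names)

    def row(self, name: str) -> str:
        return self.rows[self.names.index(name)]

    def marker(self, name: str) -> Marker:
        for m in self.markers:
            if m.name == name:
                return m
        raise KeyError(f"no marker named {name!r}")

    def subset(self, names: Sequence[str]) -> "HaplotypeMatrix":
        keep = list(names)
        missing = [n for n in keep if n not in self.names]
        if missing:
            raise KeyError(f"unknown haplotypes: {missing}")
        rows = [self.row(n) for n in keep]
        pops = {n: self.populations[n] for n in keep if n in self.populations}
        og = self.outgroup_id if self.outgroup_id in keep else None
        markers = [
            replace(m, carriers=frozenset(m.carriers & set(keep)))
            for m in self.markers
        ]
        return HaplotypeMatrix(keep, rows, list(self.sites), pops, og, markers)


@dataclass
class BinaryMatrix:
    """Outgroup-polarised 0/1 matrix: 0 = outgroup (ancestral) allele, 1 = derived.

    ``allele_map[j] = (ancestral, derived)`` records the symbol each code stands
    for at site j, so the encoding is reversible. ``uncertain_sites`` lists
    1-based ordinals where the outgroup state was missing and the ingroup major
    allele was used as the ancestral stand-in; ``monomorphic_sites`` lists
    ordinals invariant among ingroup rows.
    """

    names: list[str]
    data: np.ndarray  # shape (n_haplotypes, n_sites), dtype int8
    sites: list[Site]
    allele_map: list[tuple[str, str]]
    populations: dict[str, str] = field(default_factory=dict)
    outgroup_id: Optional[str] = None
    markers: list[Marker] = field(default_factory=list)
    uncertain_sites: frozenset[int] = frozenset()
    monomorphic_sites: frozenset[int] = frozenset()

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def row(self, name: str) -> np.ndarray:
        return self.data[self.names.index(name)]

    def derived_sites(self, name: str) -> list[int]:
        """1-based ordinals at which ``name`` carries the derived allele."""
        return [int(j) + 1 for j in np.flatnonzero(self.row(name))]

    def marker(self, name: str) -> Marker:
        for m in self.markers:
            if m.name == name:
                return m
        raise KeyError(f"no marker named {name!r}")

    def subset(self, names: Sequence[str]) -> "BinaryMatrix":
        keep = list(names)
        idx = [self.names.index(n) for n in keep]
        pops = {n: self.populations[n] for n in keep if n in self.populations}
        og = self.outgroup_id if self.outgroup_id in keep else None
        markers = [
            replace(m, carriers=frozenset(m.carriers & set(keep)))
            for m in self.markers
        ]
        return BinaryMatrix(
            keep,
            self.data[idx].copy(),
            list(self.sites),
            list(self.allele_map),
            pops,
            og,
            markers,
            self.uncertain_sites,
            self.monomorphic_sites,
        )


@dataclass(frozen=True)
class HaplogroupAssignment:
    haplotype: str
    label: str
    matched_sites: tuple[int, ...] = ()
    note: Optional[str] = None


@dataclass
class RecombinationCall:
    """One inferred recombination event.

    ``parent_forward`` shares the 5′ (smaller-ordinal) segment with the
    recombinant, ``parent_backward`` the 3′ segment. ``interval`` brackets the
    crossover; endpoints are site ordinals or marker names. ``alt_cost`` is the
    pair (parallel substitutions needed if the recombinant were clustered with
    the forward parent, ditto backward) — the price of explaining the data
    without recombination.
    """

    recombinant: str
    parent_forward: str
    parent_backward: str
    interval: tuple[Endpoint, Endpoint]
    support_forward: tuple[int, ...]
    support_backward: tuple[int, ...]
    method: str  # "network" | "pnarec"
    alt_cost: tuple[int, int] = (0, 0)
    excluded_parallel_sites: tuple[int, ...] = ()
    low_confidence: bool = False
    notes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.method not in ("network", "pnarec"):
            raise ValueError(f"unknown method {self.method!r}")


@dataclass(frozen=True)
class TruthRecord:
    """Simulator ground truth for one event."""

    event: str  # "recombination" | "gene_conversion"
    recombinant: str
    parent_forward: str
    parent_backward: str
    breakpoint: Optional[tuple[int, int]] = None  # crossover between these sites
    tract: Optional[tuple[int, int]] = None  # conversion tract, inclusive
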