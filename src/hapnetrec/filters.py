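"""Dataset-preparation filters against artificial (mis-phased) recombinants.

Haplotypes statistically phased from genotypes can contain switch errors
that masquerade as recombinants. Two complementary guards are provided:
keep only haplotypes from individuals whose phase is certain (homozygous, or
a single heterozygous site), or keep only haplotypes observed repeatedly
across all populations — a switch error is unlikely to recur identically.
"""

from __future__ import annotations

import logging
from collections import Counter, OrderedDict
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence, Union

from .model import HaplotypeMatrix, Marker, Site

__all__ = [
    "GenotypePair",
    "read_genotype_pairs",
    "select_confident_individuals",
    "select_recurrent_haplotypes",
    "collapse_unique",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GenotypePair:
    """The two phased haplotypes of one individual."""

    individual: str
    hapA: str
    hapB: str
    population: str = ""

    def __post_init__(self) -> None:
        if len(self.hapA) != len(self.hapB):
            raise ValueError(
                f"individual {self.individual!r}: haplotypes differ in length"
            )

    @property
    def n_heterozygous(self) -> int:
        return sum(a != b for a, b in zip(self.hapA, self.hapB))


def read_genotype_pairs(path: Union[str, Path]) -> list[GenotypePair]:
    """TSV with columns individual, population, then one state per site;
    two consecutive rows per individual."""
    path = Path(path)
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if len(lines) < 2:
        raise ValueError(f"{path}: no genotype rows")
    header = lines[0].split("\t")
    rows: "OrderedDict[str, list[tuple[str, str]]]" = OrderedDict()
    for ln in lines[1:]:
        fields = ln.split("\t")
        if len(fields) != len(header):
            raise ValueError(f"{path}: ragged row {fields[0]!r}")
        ind, pop = fields[0], fields[1]
        rows.setdefault(ind, []).append((pop, "".join(fields[2:])))
    pairs = []
    for ind, entries in rows.items():
        if len(entries) != 2:
            raise ValueError(
                f"{path}: individual {ind!r} has {len(entries)} rows, expected 2"
            )
        (pop, hapA), (_, hapB) = entries
        pairs.append(GenotypePair(ind, hapA, hapB, pop))
    return pairs


def select_confident_individuals(
    pairs: Sequence[GenotypePair], max_heterozygous: int = 1
) -> HaplotypeMatrix:
    """Keep both haplotypes of individuals with <= ``max_heterozygous``
    heterozygous sites (phase certain up to that single site)."""
    names: list[str] = []
    rows: list[str] = []
    pops: dict[str, str] = {}
    for pair in pairs:
        het = pair.n_heterozygous
        if het > max_heterozygous:
            logger.info(
                "drop %s: %d heterozygous sites (> %d)",
                pair.individual,
                het,
                max_heterozygous,
            )
            continue
        logger.info("keep %s: %d heterozygous sites", pair.individual, het)
        for suffix, hap in (("_a", pair.hapA), ("_b", pair.hapB)):
            name = pair.individual + suffix
            names.append(name)
            rows.append(hap)
            if pair.population:
                pops[name] = pair.population
    L = len(rows[0]) if rows else 0
    return HaplotypeMatrix(
        names, rows, [Site(index=j + 1) for j in range(L)], pops
    )


def select_recurrent_haplotypes(
    matrix: HaplotypeMatrix, min_count: int = 3
) -> HaplotypeMatrix:
    """Keep haplotypes whose allele string occurs >= ``min_count`` times over
    all populations jointly. The outgroup row, if any, is always retained."""
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    counts = Counter(
        row
        for name, row in zip(matrix.names, matrix.rows)
        if name != matrix.outgroup_id
    )
    keep = [
        name
        for name, row in zip(matrix.names, matrix.rows)
        if name == matrix.outgroup_id or counts[row] >= min_count
    ]
    dropped = len(matrix.names) - len(keep)
    logger.info(
        "recurrent filter (min_count=%d): kept %d of %d haplotypes (%d dropped)",
        min_count,
        len(keep),
        len(matrix.names),
        dropped,
    )
    return matrix.subset(keep)


def collapse_unique(
    matrix: HaplotypeMatrix,
) -> tuple[HaplotypeMatrix, dict[str, int], dict[str, dict[str, int]]]:
    """One row per distinct allele string (first-seen name kept).

    Returns the collapsed matrix, per-unique-row multiplicities, and the
    per-population composition of each collapsed class.
    """
    first: "OrderedDict[str, str]" = OrderedDict()  # row string -> kept name
    mult: dict[str, int] = {}
    comp: dict[str, dict[str, int]] = {}
    members: dict[str, list[str]] = {}
    for name, row in zip(matrix.names, matrix.rows):
        if row not in first:
            first[row] = name
            mult[name] = 0
            comp[name] = {}
            members[name] = []
        kept = first[row]
        mult[kept] += 1
        members[kept].append(name)
        pop = matrix.populations.get(name)
        if pop is not None:
            comp[kept][pop] = comp[kept].get(pop, 0) + 1
    keep_names = list(first.values())
    rows = [matrix.row(n) for n in keep_names]
    pops = {n: matrix.populations[n] for n in keep_names if n in matrix.populations}
    og = matrix.outgroup_id
    if og is not None and og not in keep_names:
        # the outgroup collapsed into another row; point at the kept name
        og = next(k for k, mem in members.items() if og in mem)
    markers = [
        Marker(
            m.name,
            m.left,
            m.right,
            frozenset(
                kept
                for kept, mem in members.items()
                if any(x in m.carriers for x in mem)
            ),
        )
        for m in matrix.markers
    ]
    collapsed = HaplotypeMatrix(
        keep_names, rows, list(matrix.sites), pops, og, markers
    )
    return collapsed, mult, comp
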