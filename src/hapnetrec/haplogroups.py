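"""Haplogroup assignment from a diagnostic-SNP panel.

A panel maps haplogroup labels to required (site, allele) pairs; the panel
itself is data supplied by the user (e.g. from published haplogroup-defining
variants), not code. Haplotypes matching no entry fall back to a sentinel
label ("X"), so every haplotype is assigned exactly once. Because SNP panels
cannot see indels, labels that differ only by an indel are expected to be
supplied as merged entries (e.g. "A101-A201-O09").
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import yaml

from .model import HaplogroupAssignment, HaplotypeMatrix

__all__ = [
    "DiagnosticPanel",
    "load_panel",
    "classify",
    "classify_all",
    "representative",
]


@dataclass
class DiagnosticPanel:
    """Haplogroup label -> required (1-based site ordinal, allele symbol)."""

    entries: dict[str, list[tuple[int, str]]]
    priority: list[str] = field(default_factory=list)
    fallback: str = "X"

    def __post_init__(self) -> None:
        if not self.priority:
            self.priority = list(self.entries)
        unknown = set(self.priority) - set(self.entries)
        if unknown:
            raise ValueError(f"priority lists unknown labels: {sorted(unknown)}")
        seen: dict[frozenset, str] = {}
        for label, reqs in self.entries.items():
            key = frozenset(reqs)
            if key in seen:
                raise ValueError(
                    f"labels {seen[key]!r} and {label!r} have identical "
                    "requirement sets"
                )
            seen[key] = label

    @classmethod
    def from_dict(cls, doc: dict) -> "DiagnosticPanel":
        entries = {
            label: [(int(site), str(allele)) for site, allele in reqs]
            for label, reqs in doc["labels"].items()
        }
        return cls(
            entries,
            list(doc.get("priority", [])),
            doc.get("fallback", "X"),
        )


def load_panel(path: Union[str, Path]) -> DiagnosticPanel:
    """Read a YAML panel: {labels: {name: [[site, allele], ...]}, priority,
    fallback}."""
    doc = yaml.safe_load(Path(path).read_text())
    return DiagnosticPanel.from_dict(doc)


def classify(
    matrix: HaplotypeMatrix, haplotype: str, panel: DiagnosticPanel
) -> HaplogroupAssignment:
    """Assign the highest-priority label whose required alleles all match."""
    L = matrix.n_sites
    for label, reqs in panel.entries.items():
        for site, _ in reqs:
            if not 1 <= site <= L:
                raise ValueError(
                    f"panel label {label!r} references missing site {site}"
                )
    row = matrix.row(haplotype)
    matched = []
    for label in panel.priority:
        reqs = panel.entries[label]
        if all(row[site - 1] == allele for site, allele in reqs):
            matched.append(label)
    if not matched:
        return HaplogroupAssignment(
            haplotype, panel.fallback, (), note="no diagnostic pattern matched"
        )
    label = matched[0]
    note = None
    if len(matched) > 1:
        note = f"also matched lower-priority labels: {', '.join(matched[1:])}"
    sites = tuple(site for site, _ in panel.entries[label])
    return HaplogroupAssignment(haplotype, label, sites, note)


def classify_all(
    matrix: HaplotypeMatrix, panel: DiagnosticPanel
) -> list[HaplogroupAssignment]:
    """Classify every ingroup haplotype (the outgroup is left unassigned)."""
    return [
        classify(matrix, name, panel)
        for name in matrix.names
        if name != matrix.outgroup_id
    ]


def representative(
    matrix: HaplotypeMatrix,
    assignments: Sequence[HaplogroupAssignment],
    label: str,
    multiplicities: Optional[dict[str, int]] = None,
) -> str:
    """The modal haplotype of a haplogroup; ties break by name order.

    Multiplicity is the count of identical allele strings within the group
    (or the supplied collapsed-matrix multiplicities).
    """
    members = [a.haplotype for a in assignments if a.label == label]
    if not members:
        raise ValueError(f"no haplotype carries label {label!r}")
    if multiplicities is None:
        string_counts = Counter(matrix.row(n) for n in members)
        weight = {n: string_counts[matrix.row(n)] for n in members}
    else:
        weight = {n: multiplicities.get(n, 1) for n in members}
    best = max(weight.values())
    return min(n for n in members if weight[n] == best)
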