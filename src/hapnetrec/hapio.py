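"""Reading, writing and outgroup-polarised encoding of haplotype matrices.

Two input dialects are supported:

* ``tsv`` — header row of site IDs, first column the haplotype name, optional
  ``population`` column; one single-character allele state per site column.
* ``fasta`` — a FASTA alignment of single-character states, one record per
  haplotype; an optional ``pop=XXX`` token in the description carries the
  population label.

Reports (recombination calls + haplogroup assignments) serialise to JSON or
TSV; interval endpoints that are markers (e.g. "Δ261") stay strings.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import replace
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
from Bio import SeqIO

from .model import (
    BinaryMatrix,
    HaplogroupAssignment,
    HaplotypeMatrix,
    Marker,
    RecombinationCall,
    Site,
)

__all__ = [
    "read_haplotype_table",
    "write_haplotype_table",
    "attach_annotations",
    "encode_binary",
    "decode_binary",
    "write_report",
    "read_report",
]


def _sniff_dialect(path: Path) -> str:
    with open(path) as fh:
        for line in fh:
            if line.strip():
                return "fasta" if line.startswith(">") else "tsv"
    raise ValueError(f"{path}: empty file")


def read_haplotype_table(
    path: Union[str, Path],
    dialect: Optional[str] = None,
    outgroup_id: Optional[str] = None,
) -> HaplotypeMatrix:
    """Parse a haplotype alignment into a :class:`HaplotypeMatrix`.

    Sites are numbered 1..L in column order. Raises ``ValueError`` on ragged
    rows, more than two alleles at a site, or an empty file.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect is None:
        dialect = _sniff_dialect(path)
    if dialect == "tsv":
        names, rows, pops = _read_tsv(path)
    elif dialect in ("fasta", "fasta-like"):
        names, rows, pops = _read_fasta(path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    if not names:
        raise ValueError(f"{path}: no haplotype rows")
    L = len(rows[0])
    for name, row in zip(names, rows):
        if len(row) != L:
            raise ValueError(
                f"{path}: haplotype {name!r} has {len(row)} states, expected {L}"
            )
    for j in range(L):
        states = {row[j] for row in rows}
        if len(states) > 2:
            raise ValueError(
                f"{path}: site {j + 1} has {len(states)} alleles "
                f"{sorted(states)}; only biallelic sites are supported"
            )
    sites = [Site(index=j + 1) for j in range(L)]
    return HaplotypeMatrix(names, rows, sites, pops, outgroup_id)


def _read_tsv(path: Path) -> tuple[list[str], list[str], dict[str, str]]:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise ValueError(f"{path}: empty file")
    header = lines[0].split("\t")
    pop_col = None
    for i, col in enumerate(header[1:], start=1):
        if col.strip().lower() == "population":
            pop_col = i
    names, rows, pops = [], [], {}
    for ln in lines[1:]:
        fields = ln.split("\t")
        if len(fields) != len(header):
            raise ValueError(
                f"{path}: row {fields[0]!r} has {len(fields)} columns, "
                f"header has {len(header)}"
            )
        name = fields[0]
        states = [f for i, f in enumerate(fields) if i != 0 and i != pop_col]
        for s in states:
            if len(s) != 1:
                raise ValueError(
                    f"{path}: row {name!r} has multi-character state {s!r}"
                )
        names.append(name)
        rows.append("".join(states))
        if pop_col is not None:
            pops[name] = fields[pop_col]
    return names, rows, pops


def _read_fasta(path: Path) -> tuple[list[str], list[str], dict[str, str]]:
    names, rows, pops = [], [], {}
    for rec in SeqIO.parse(str(path), "fasta"):
        names.append(rec.id)
        rows.append(str(rec.seq))
        for token in rec.description.split():
            if token.startswith("pop="):
                pops[rec.id] = token[4:]
    return names, rows, pops


def write_haplotype_table(matrix: HaplotypeMatrix, path: Union[str, Path]) -> None:
    """Export a matrix as the TSV dialect (round-trips through the reader)."""
    path = Path(path)
    header = ["haplotype"]
    if matrix.populations:
        header.append("population")
    header += [f"s{s.index}" for s in matrix.sites]
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for name, row in zip(matrix.names, matrix.rows):
            fields = [name]
            if matrix.populations:
                fields.append(matrix.populations.get(name, "NA"))
            fields += list(row)
            fh.write("\t".join(fields) + "\n")


def attach_annotations(
    matrix: HaplotypeMatrix, annotations: Iterable[dict]
) -> HaplotypeMatrix:
    """Return a copy of ``matrix`` with gene features and markers attached.

    Each annotation is a dict with either

    * ``{"site": <ordinal>, "feature": <label>}`` — or ``"sites": [..]`` — to
      tag SNP columns with a gene-feature label (e.g. "exon 6"); or
    * ``{"marker": <name>, "left": i, "right": i+1, "carriers": [...]}`` to
      place a non-SNP landmark between two adjacent SNP ordinals.
    """
    sites = list(matrix.sites)
    markers = list(matrix.markers)
    L = len(sites)

    def _check(idx: int) -> None:
        if not 1 <= idx <= L:
            raise ValueError(f"annotation references unknown site index {idx}")

    for ann in annotations:
        if "marker" in ann:
            left, right = int(ann["left"]), int(ann["right"])
            _check(left)
            _check(right)
            carriers = frozenset(ann.get("carriers", ()))
            unknown = carriers - set(matrix.names)
            if unknown:
                raise ValueError(
                    f"marker {ann['marker']!r} carriers not in matrix: "
                    f"{sorted(unknown)}"
                )
            markers.append(Marker(ann["marker"], left, right, carriers))
        else:
            idxs = ann.get("sites", [ann["site"]] if "site" in ann else [])
            if not idxs:
                raise ValueError(f"annotation without site or marker: {ann}")
            for idx in idxs:
                _check(int(idx))
                j = int(idx) - 1
                sites[j] = replace(sites[j], feature=ann.get("feature"))
    out = HaplotypeMatrix(
        list(matrix.names),
        list(matrix.rows),
        sites,
        dict(matrix.populations),
        matrix.outgroup_id,
        markers,
    )
    return out


def encode_binary(
    matrix: HaplotypeMatrix,
    outgroup_id: Optional[str] = None,
    missing_chars: str = "N?-.",
) -> BinaryMatrix:
    """Polarise alleles against the outgroup: 0 = outgroup allele, 1 = derived.

    At sites where the outgroup state is missing, the ingroup major allele is
    taken as ancestral and the site is flagged polarity-uncertain. Sites
    invariant among ingroup rows are flagged monomorphic.
    """
    og = outgroup_id or matrix.outgroup_id
    if og is None or og not in matrix.names:
        raise ValueError(f"outgroup {og!r} not present in matrix")
    L = matrix.n_sites
    og_row = matrix.row(og)
    ingroup = [n for n in matrix.names if n != og]
    uncertain: set[int] = set()
    monomorphic: set[int] = set()
    allele_map: list[tuple[str, str]] = []
    codes = np.zeros((matrix.n_haplotypes, L), dtype=np.int8)
    for j in range(L):
        ing_states = [matrix.row(n)[j] for n in ingroup]
        observed = sorted(set(s for s in ing_states if s not in missing_chars))
        og_state = og_row[j]
        if og_state in missing_chars:
            # no outgroup information: ingroup major allele stands in as ancestral
            counts = {s: ing_states.count(s) for s in observed}
            anc = max(observed, key=lambda s: (counts[s], s)) if observed else "N"
            uncertain.add(j + 1)
        else:
            anc = og_state
        others = [s for s in observed if s != anc]
        if len(others) > 1:
            raise ValueError(f"site {j + 1}: more than two alleles after polarising")
        der = others[0] if others else anc
        if not others:
            monomorphic.add(j + 1)
        allele_map.append((anc, der))
        for i, name in enumerate(matrix.names):
            s = matrix.row(name)[j]
            if s in missing_chars:
                if name != og:
                    raise ValueError(
                        f"missing state for ingroup haplotype {name!r} at "
                        f"site {j + 1}"
                    )
                codes[i, j] = 0  # unknown outgroup state: ancestral by definition
            else:
                codes[i, j] = 0 if s == anc else 1
    if len(uncertain) > L / 2:
        warnings.warn(
            f"outgroup state missing at {len(uncertain)}/{L} sites; "
            "polarity is unreliable",
            stacklevel=2,
        )
    return BinaryMatrix(
        names=list(matrix.names),
        data=codes,
        sites=list(matrix.sites),
        allele_map=allele_map,
        populations=dict(matrix.populations),
        outgroup_id=og,
        markers=list(matrix.markers),
        uncertain_sites=frozenset(uncertain),
        monomorphic_sites=frozenset(monomorphic),
    )


def decode_binary(binary: BinaryMatrix) -> HaplotypeMatrix:
    """Invert :func:`encode_binary` through the stored allele map."""
    rows = []
    for i in range(len(binary.names)):
        rows.append(
            "".join(
                binary.allele_map[j][int(binary.data[i, j])]
                for j in range(binary.n_sites)
            )
        )
    return HaplotypeMatrix(
        list(binary.names),
        rows,
        list(binary.sites),
        dict(binary.populations),
        binary.outgroup_id,
        list(binary.markers),
    )


# ---------------------------------------------------------------------------
# reports


def _call_record(call: RecombinationCall) -> dict:
    return {
        "recombinant": call.recombinant,
        "parent_forward": call.parent_forward,
        "parent_backward": call.parent_backward,
        "interval": list(call.interval),
        "support_forward": list(call.support_forward),
        "support_backward": list(call.support_backward),
        "method": call.method,
        "alt_cost": list(call.alt_cost),
        "excluded_parallel_sites": list(call.excluded_parallel_sites),
        "low_confidence": call.low_confidence,
        "notes": list(call.notes),
    }


def write_report(
    calls: Sequence[RecombinationCall],
    assignments: Optional[Sequence[HaplogroupAssignment]] = None,
    path: Union[str, Path] = "report.json",
    format: str = "json",
) -> Path:
    """Serialise calls (and optionally haplogroup assignments) to JSON or TSV."""
    path = Path(path)
    if format == "json":
        doc = {"calls": [_call_record(c) for c in calls]}
        if assignments is not None:
            doc["assignments"] = [
                {
                    "haplotype": a.haplotype,
                    "label": a.label,
                    "matched_sites": list(a.matched_sites),
                    "note": a.note,
                }
                for a in assignments
            ]
        path.write_text(json.dumps(doc, indent=2, ensure_ascii=False, sort_keys=True))
    elif format == "tsv":
        cols = [
            "recombinant",
            "parent_forward",
            "parent_backward",
            "interval_left",
            "interval_right",
            "support_forward",
            "support_backward",
            "method",
            "alt_cost_forward",
            "alt_cost_backward",
        ]
        lines = ["\t".join(cols)]
        for c in calls:
            lines.append(
                "\t".join(
                    [
                        c.recombinant,
                        c.parent_forward,
                        c.parent_backward,
                        str(c.interval[0]),
                        str(c.interval[1]),
                        ",".join(map(str, c.support_forward)),
                        ",".join(map(str, c.support_backward)),
                        c.method,
                        str(c.alt_cost[0]),
                        str(c.alt_cost[1]),
                    ]
                )
            )
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown report format {format!r}")
    return path


def read_report(path: Union[str, Path]) -> list[RecombinationCall]:
    """Load a JSON report back into :class:`RecombinationCall` objects."""
    doc = json.loads(Path(path).read_text())
    calls = []
    for rec in doc["calls"]:
        left, right = rec["interval"]
        calls.append(
            RecombinationCall(
                recombinant=rec["recombinant"],
                parent_forward=rec["parent_forward"],
                parent_backward=rec["parent_backward"],
                interval=(left, right),
                support_forward=tuple(rec["support_forward"]),
                support_backward=tuple(rec["support_backward"]),
                method=rec["method"],
                alt_cost=tuple(rec["alt_cost"]),
                excluded_parallel_sites=tuple(rec["excluded_parallel_sites"]),
                low_confidence=rec["low_confidence"],
                notes=tuple(rec["notes"]),
            )
        )
    return calls
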