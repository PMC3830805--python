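"""End-to-end orchestration: read → filter → classify → network → detect → report.

A run is driven by a :class:`RunConfig` (constructible from YAML) and writes
a reproducible report bundle: haplogroup assignments, network exports
(GraphML + DOT), recombination-call reports from both detectors, a run log
recording every filter decision, and the resolved configuration. Identical
config + input produce byte-identical bundles.
"""

from __future__ import annotations

import io
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import yaml

from . import filters, haplogroups, hapio, mednet, netrec, pnarec
from .model import HaplotypeMatrix

__all__ = ["RunConfig", "PipelineError", "run", "compare_runs"]

_FILTER_MODES = ("none", "confident_individuals", "recurrent")


class PipelineError(RuntimeError):
    """A stage failure, wrapped with the stage name."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage {stage!r} failed: {cause}")


@dataclass
class RunConfig:
    input_path: str
    outgroup: str
    dialect: Optional[str] = None  # sniffed when omitted
    filter_mode: str = "none"
    min_count: int = 3
    panel_path: Optional[str] = None
    exclude_path: Optional[str] = None
    annotations_path: Optional[str] = None
    outgroup_path: Optional[str] = None  # extra table merged in (outgroup row)
    max_dim: int = 3
    selection: Union[str, list[str]] = "representatives"
    outdir: str = "hapnetrec_out"
    report_format: str = "json"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.filter_mode not in _FILTER_MODES:
            raise ValueError(
                f"filter_mode {self.filter_mode!r} not in {_FILTER_MODES}"
            )

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


def _merge(matrix: HaplotypeMatrix, extra: HaplotypeMatrix) -> HaplotypeMatrix:
    if extra.n_sites != matrix.n_sites:
        raise ValueError("outgroup table has a different number of sites")
    return HaplotypeMatrix(
        matrix.names + extra.names,
        matrix.rows + extra.rows,
        list(matrix.sites),
        {**matrix.populations, **extra.populations},
        extra.outgroup_id or matrix.outgroup_id,
        matrix.markers + extra.markers,
    )


def run(config: RunConfig) -> dict:
    """Execute the pipeline; returns a summary dict of what was written."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    log_stream = io.StringIO()
    handler = logging.StreamHandler(log_stream)
    handler.setFormatter(logging.Formatter("%(name)s: %(message)s"))
    handler.setLevel(logging.INFO)
    root = logging.getLogger("hapnetrec")
    root.addHandler(handler)
    old_level = root.level
    root.setLevel(logging.INFO)
    log = logging.getLogger("hapnetrec.pipeline")

    def _fail(stage: str, err: Exception) -> PipelineError:
        for p in written:  # no partial bundles
            p.unlink(missing_ok=True)
        return PipelineError(stage, err)

    try:
        try:
            if config.filter_mode == "confident_individuals":
                pairs = filters.read_genotype_pairs(config.input_path)
                log.info("read %d genotype pairs", len(pairs))
                matrix = filters.select_confident_individuals(pairs)
            else:
                matrix = hapio.read_haplotype_table(
                    config.input_path, config.dialect
                )
                log.info(
                    "read %d haplotypes x %d sites",
                    matrix.n_haplotypes,
                    matrix.n_sites,
                )
            if config.outgroup_path:
                matrix = _merge(
                    matrix, hapio.read_haplotype_table(config.outgroup_path)
                )
            matrix.outgroup_id = config.outgroup
            if config.outgroup not in matrix.names:
                raise ValueError(f"outgroup {config.outgroup!r} not in input")
        except Exception as e:
            raise _fail("read", e)

        try:
            if config.annotations_path:
                anns = yaml.safe_load(Path(config.annotations_path).read_text())
                matrix = hapio.attach_annotations(matrix, anns)
                log.info("attached %d annotations", len(anns))
        except PipelineError:
            raise
        except Exception as e:
            raise _fail("annotations", e)

        try:
            if config.exclude_path:
                excluded = [
                    ln.strip()
                    for ln in Path(config.exclude_path).read_text().splitlines()
                    if ln.strip()
                ]
                keep = [n for n in matrix.names if n not in excluded]
                log.info("excluded %d haplotypes by list", len(excluded))
                matrix = matrix.subset(keep)
            if config.filter_mode == "recurrent":
                matrix = filters.select_recurrent_haplotypes(
                    matrix, config.min_count
                )
        except PipelineError:
            raise
        except Exception as e:
            raise _fail("filter", e)

        try:
            unique, mult, comp = filters.collapse_unique(matrix)
            log.info(
                "collapsed %d haplotypes into %d unique rows",
                matrix.n_haplotypes,
                unique.n_haplotypes,
            )
        except Exception as e:
            raise _fail("collapse", e)

        assignments = []
        try:
            if config.panel_path:
                panel = haplogroups.load_panel(config.panel_path)
                assignments = haplogroups.classify_all(unique, panel)
                log.info("classified %d haplotypes", len(assignments))
        except PipelineError:
            raise
        except Exception as e:
            raise _fail("classify", e)

        try:
            binary = hapio.encode_binary(unique)
            net = mednet.build_median_network(binary, config.max_dim)
            net.multiplicities = mult
            net.populations = comp
            for fmt in ("graphml", "dot"):
                written.append(
                    mednet.export_network(net, outdir / f"network.{fmt}", fmt)
                )
        except PipelineError:
            raise
        except Exception as e:
            raise _fail("network", e)

        try:
            net_calls = netrec.detect_rectangle_recombinants(net, binary)
            for m in unique.markers:
                net_calls = [
                    netrec.refine_call_with_marker(c, m) for c in net_calls
                ]
            log.info("network detector: %d call(s)", len(net_calls))
        except Exception as e:
            raise _fail("netrec", e)

        try:
            if config.selection == "representatives" and assignments:
                labels = sorted(
                    {
                        a.label
                        for a in assignments
                        if a.label != (panel.fallback if config.panel_path else "X")
                    }
                )
                selection = sorted(
                    haplogroups.representative(unique, assignments, lab, mult)
                    for lab in labels
                )
            elif isinstance(config.selection, (list, tuple)):
                selection = list(config.selection)
            else:
                selection = [
                    n for n in unique.names if n != unique.outgroup_id
                ]
            log.info("quartet scan over: %s", ", ".join(selection))
            pn_calls = pnarec.pnarec_scan(binary, selection=selection)
            audits = pnarec.explain_scan(binary, selection=selection)
            log.info("quartet detector: %d call(s)", len(pn_calls))
        except Exception as e:
            raise _fail("pnarec", e)

        try:
            fmt = config.report_format
            ext = "json" if fmt == "json" else "tsv"
            written.append(
                hapio.write_report(
                    net_calls, assignments, outdir / f"netrec_calls.{ext}", fmt
                )
            )
            written.append(
                hapio.write_report(
                    pn_calls, assignments, outdir / f"pnarec_calls.{ext}", fmt
                )
            )
            audit_lines = ["trio\trejected_at\treason\tcandidate\tselected"]
            for a in audits:
                audit_lines.append(
                    "\t".join(
                        [
                            "+".join(a.trio),
                            a.rejected_at or "-",
                            a.reason or "-",
                            a.candidate or "-",
                            str(a.selected),
                        ]
                    )
                )
            (outdir / "pnarec_audit.tsv").write_text("\n".join(audit_lines) + "\n")
            written.append(outdir / "pnarec_audit.tsv")
            if assignments:
                lines = ["haplotype\tlabel\tmultiplicity\tnote"]
                for a in assignments:
                    lines.append(
                        f"{a.haplotype}\t{a.label}\t{mult.get(a.haplotype, 1)}"
                        f"\t{a.note or '-'}"
                    )
                (outdir / "haplogroups.tsv").write_text("\n".join(lines) + "\n")
                written.append(outdir / "haplogroups.tsv")
            (outdir / "resolved_config.yaml").write_text(
                yaml.safe_dump(asdict(config), sort_keys=True)
            )
            written.append(outdir / "resolved_config.yaml")
            (outdir / "run.log").write_text(log_stream.getvalue())
            written.append(outdir / "run.log")
        except PipelineError:
            raise
        except Exception as e:
            raise _fail("report", e)
    finally:
        root.removeHandler(handler)
        root.setLevel(old_level)

    return {
        "outdir": str(outdir),
        "files": sorted(str(p.name) for p in written),
        "n_network_calls": len(net_calls),
        "n_pnarec_calls": len(pn_calls),
        "network_calls": net_calls,
        "pnarec_calls": pn_calls,
        "assignments": assignments,
    }


def compare_runs(bundle_a: Union[str, Path], bundle_b: Union[str, Path]) -> dict:
    """Align the calls of two report bundles; empty diff means agreement."""
    diffs: list[dict] = []
    a_dir, b_dir = Path(bundle_a), Path(bundle_b)
    for stem in ("netrec_calls", "pnarec_calls"):
        fa, fb = a_dir / f"{stem}.json", b_dir / f"{stem}.json"
        if not fa.exists() or not fb.exists():
            raise ValueError(f"bundle missing {stem}.json")
        calls_a = {c.recombinant: c for c in hapio.read_report(fa)}
        calls_b = {c.recombinant: c for c in hapio.read_report(fb)}
        for rec in sorted(set(calls_a) | set(calls_b)):
            ca, cb = calls_a.get(rec), calls_b.get(rec)
            if ca is None or cb is None:
                diffs.append(
                    {
                        "report": stem,
                        "recombinant": rec,
                        "kind": "only_in",
                        "which": "A" if cb is None else "B",
                    }
                )
                continue
            if tuple(ca.interval) != tuple(cb.interval):
                diffs.append(
                    {
                        "report": stem,
                        "recombinant": rec,
                        "kind": "interval",
                        "A": list(ca.interval),
                        "B": list(cb.interval),
                    }
                )
            parents_a = (ca.parent_forward, ca.parent_backward)
            parents_b = (cb.parent_forward, cb.parent_backward)
            if parents_a != parents_b:
                diffs.append(
                    {
                        "report": stem,
                        "recombinant": rec,
                        "kind": "parents",
                        "A": list(parents_a),
                        "B": list(parents_b),
                    }
                )
    return {"differences": diffs, "identical": not diffs}
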