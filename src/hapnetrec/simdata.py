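"""Synthetic haplotype histories under the binary infinite-sites model.

The generator emulates exactly the structure the detectors assume: an
ancestral haplotype, lineages accumulating private substitutions (each at a
previously unmutated site), one or more recombination events joining the 5′
segment of one lineage to the 3′ segment of another, optional fixed-endpoint
gene-conversion tracts, outgroup-private substitutions, and per-population
sampling multiplicities. Ground truth (event type, parents, true crossover)
is emitted alongside every matrix.

Also houses three deterministic fixtures:

* :func:`fig1_fixture` — the 15-site four-haplotype worked model (two parents,
  one surviving recombinant, an outgroup) used throughout as an exact oracle;
* :func:`synthetic_abo54_representatives` — a SYNTHETIC 54-site reconstruction
  of the ABO haplogroup representatives (A101-A201-O09, B101, O01, O02, O47
  plus chimpanzee outgroup). This is *not* HapMap data: it is constructed so
  that the representative haplotypes exhibit the published clustering
  patterns (support-site classes, Δ261 placement between sites 15 and 16,
  parallel changes eliminating O01 from quartet analysis);
* :func:`step_e_preference_fixture` — a minimal dataset in which two parental
  quartets survive filtering and the final selection prefers the parent pair
  with the larger singleton sum (the longer-external-branch parent).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .model import HaplotypeMatrix, Marker, Site, TruthRecord

__all__ = [
    "LineageSpec",
    "Event",
    "MarkerSpec",
    "SimulationConfig",
    "simulate",
    "fig1_fixture",
    "fig1_config",
    "abo_scenario",
    "synthetic_abo54_representatives",
    "synthetic_abo54_population",
    "synthetic_abo54_panel",
    "step_e_preference_fixture",
    "RecoveryDesign",
    "recovery_experiment",
]

_ANC = "ACGT"
_DER = "GTAC"


def _symbols(j: int) -> tuple[str, str]:
    """Deterministic (ancestral, derived) nucleotide pair for 0-based site j."""
    return _ANC[j % 4], _DER[j % 4]


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class LineageSpec:
    """A lineage created by splitting from ``parent`` with fresh substitutions.

    ``window`` restricts where its substitutions may land (1-based, inclusive)
    so that informative-site ranges stay positionally coherent; ``batches``
    adds further (count, window) substitution groups for lineages whose
    variants must straddle a future breakpoint.
    """

    name: str
    parent: Optional[str]
    n_subs: int = 0
    window: Optional[tuple[int, int]] = None
    batches: tuple[tuple[int, tuple[int, int]], ...] = ()


@dataclass(frozen=True)
class Event:
    """One reticulate event producing lineage ``child``.

    recombination: child = donor_forward[1..breakpoint] + donor_backward[breakpoint+1..L]
    gene_conversion: child = acceptor with donor_forward's states inside ``tract``
    (the acceptor is passed as ``donor_backward``).
    """

    kind: str  # "recombination" | "gene_conversion"
    child: str
    donor_forward: str
    donor_backward: str
    breakpoint: Optional[int] = None
    tract: Optional[tuple[int, int]] = None


@dataclass(frozen=True)
class MarkerSpec:
    """A tracked non-SNP landmark between sites ``left`` and ``left + 1``,
    originating on ``origin`` before any event uses that lineage."""

    name: str
    left: int
    origin: str


@dataclass
class SimulationConfig:
    n_sites: int
    lineages: list[LineageSpec]
    events: list[Event] = field(default_factory=list)
    post_subs: dict[str, int] = field(default_factory=dict)
    post_windows: dict[str, tuple[int, int]] = field(default_factory=dict)
    parallel_subs: list[tuple[tuple[str, ...], tuple[int, int]]] = field(
        default_factory=list
    )
    markers: list[MarkerSpec] = field(default_factory=list)
    outgroup_name: str = "outgroup"
    outgroup_subs: int = 0
    sampling: dict[str, dict[str, int]] = field(default_factory=dict)
    seed: int = 0


# ---------------------------------------------------------------------------
# the generator


def _draw_sites(
    rng: np.random.Generator,
    n: int,
    window: Optional[tuple[int, int]],
    used: set[int],
    n_sites: int,
) -> list[int]:
    lo, hi = window if window else (1, n_sites)
    free = [s for s in range(lo, hi + 1) if s not in used]
    if n > len(free):
        raise ValueError(
            f"substitution budget {n} exceeds {len(free)} free sites in "
            f"window ({lo}, {hi})"
        )
    chosen = [int(s) for s in rng.choice(free, size=n, replace=False)]
    used.update(chosen)
    return chosen


def simulate(config: SimulationConfig) -> tuple[HaplotypeMatrix, list[TruthRecord]]:
    """Run the generative history in ``config``; pure function of the config.

    Returns the raw-symbol haplotype matrix (outgroup row included) and the
    truth records for every reticulate event.
    """
    rng = np.random.default_rng(config.seed)
    L = config.n_sites
    used: set[int] = set()
    vectors: dict[str, np.ndarray] = {}
    marker_carriers: dict[str, set[str]] = {m.name: set() for m in config.markers}

    for spec in config.lineages:
        base = (
            np.zeros(L, dtype=np.int8)
            if spec.parent is None
            else vectors[spec.parent].copy()
        )
        for s in _draw_sites(rng, spec.n_subs, spec.window, used, L):
            base[s - 1] = 1
        for n, win in spec.batches:
            for s in _draw_sites(rng, n, win, used, L):
                base[s - 1] = 1
        vectors[spec.name] = base
        for m in config.markers:
            if m.origin == spec.name:
                marker_carriers[m.name].add(spec.name)
            elif spec.parent is not None and spec.parent in marker_carriers.get(
                m.name, set()
            ):
                marker_carriers[m.name].add(spec.name)

    truth: list[TruthRecord] = []
    for ev in config.events:
        fwd, bwd = vectors[ev.donor_forward], vectors[ev.donor_backward]
        if ev.kind == "recombination":
            k = ev.breakpoint
            if k is None or not 1 <= k < L:
                raise ValueError(f"breakpoint {k} outside 1..{L - 1}")
            child = np.concatenate([fwd[:k], bwd[k:]]).astype(np.int8)
            truth.append(
                TruthRecord(
                    "recombination",
                    ev.child,
                    ev.donor_forward,
                    ev.donor_backward,
                    breakpoint=(k, k + 1),
                )
            )
            for m in config.markers:
                # marker sits between sites m.left and m.left + 1
                donor = ev.donor_forward if m.left + 0.5 <= k else ev.donor_backward
                if donor in marker_carriers[m.name]:
                    marker_carriers[m.name].add(ev.child)
        elif ev.kind == "gene_conversion":
            if ev.tract is None:
                raise ValueError("gene_conversion requires a tract")
            a, b = ev.tract
            if not 1 <= a <= b <= L:
                raise ValueError(f"tract {ev.tract} outside 1..{L}")
            child = bwd.copy()
            child[a - 1 : b] = fwd[a - 1 : b]
            truth.append(
                TruthRecord(
                    "gene_conversion",
                    ev.child,
                    ev.donor_forward,
                    ev.donor_backward,
                    tract=(a, b),
                )
            )
            for m in config.markers:
                inside = a - 0.5 <= m.left + 0.5 <= b + 0.5
                donor = ev.donor_forward if inside else ev.donor_backward
                if donor in marker_carriers[m.name]:
                    marker_carriers[m.name].add(ev.child)
        else:
            raise ValueError(f"unknown event kind {ev.kind!r}")
        vectors[ev.child] = child

    for lineages, window in config.parallel_subs:
        (s,) = _draw_sites(rng, 1, window, used, L)
        for name in lineages:
            vectors[name][s - 1] = 1

    for name, n in config.post_subs.items():
        win = config.post_windows.get(name)
        for s in _draw_sites(rng, n, win, used, L):
            vectors[name][s - 1] = 1

    og = np.zeros(L, dtype=np.int8)
    for s in _draw_sites(rng, config.outgroup_subs, None, used, L):
        og[s - 1] = 1
    vectors[config.outgroup_name] = og

    # sampling: default one copy per lineage, no population label
    names: list[str] = []
    rows: list[str] = []
    pops: dict[str, str] = {}
    row_of: dict[str, list[str]] = {}

    def _symbol_row(vec: np.ndarray) -> str:
        return "".join(_symbols(j)[int(vec[j])] for j in range(L))

    for name, vec in vectors.items():
        plan = config.sampling.get(name)
        if plan is None:
            names.append(name)
            rows.append(_symbol_row(vec))
            row_of.setdefault(name, []).append(name)
        else:
            i = 0
            for pop, count in sorted(plan.items()):
                for _ in range(count):
                    i += 1
                    rid = f"{name}_{i:02d}"
                    names.append(rid)
                    rows.append(_symbol_row(vec))
                    pops[rid] = pop
                    row_of.setdefault(name, []).append(rid)

    markers = [
        Marker(
            m.name,
            m.left,
            m.left + 1,
            frozenset(
                rid
                for lineage in marker_carriers[m.name]
                for rid in row_of.get(lineage, [])
            ),
        )
        for m in config.markers
    ]
    og_rows = row_of[config.outgroup_name]
    matrix = HaplotypeMatrix(
        names,
        rows,
        [Site(index=j + 1) for j in range(L)],
        pops,
        og_rows[0],
        markers,
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# fixtures


#: Derived-site sets of the 15-site worked model (relative to the ancestor).
_FIG1_DERIVED = {
    "o_prime": (3, 10, 14),
    "p1": (2, 4, 5, 9, 13, 15),
    "p2": (1, 6, 8, 11, 12),
    "r1": (2, 4, 5, 7, 8, 11),
}


def fig1_fixture() -> tuple[HaplotypeMatrix, TruthRecord]:
    """The 15-site model history: p1 x p2 crossover between sites 6 and 7.

    p1 carries substitutions at 2,4,5,9,15 (plus post-event 13), p2 at
    1,6,8,11 (plus post-event 12), the surviving recombinant r1 joins p1's 5′
    segment to p2's 3′ segment and adds 7; the outgroup o′ accumulates
    3, 10 and 14. The reciprocal recombinant r2 is assumed lost.
    """
    L = 15
    rows = []
    names = ["o_prime", "p1", "p2", "r1"]
    for name in names:
        derived = set(_FIG1_DERIVED[name])
        rows.append(
            "".join(
                _symbols(j)[1 if (j + 1) in derived else 0] for j in range(L)
            )
        )
    matrix = HaplotypeMatrix(
        names, rows, [Site(index=j + 1) for j in range(L)], {}, "o_prime"
    )
    truth = TruthRecord(
        "recombination", "r1", "p1", "p2", breakpoint=(6, 7)
    )
    return matrix, truth


def fig1_config(seed: int = 0) -> SimulationConfig:
    """A generative schedule whose output equals the worked model up to
    site relabelling (same column-pattern multiset)."""
    return SimulationConfig(
        n_sites=15,
        lineages=[
            LineageSpec("o", None, 0),
            LineageSpec("p1", "o", 3, window=(1, 6)),
            LineageSpec("p2", "o", 2, window=(7, 15)),
        ],
        events=[Event("recombination", "r1", "p1", "p2", breakpoint=6)],
        post_subs={"p1": 3, "p2": 3, "r1": 1},
        outgroup_subs=3,
        seed=seed,
    )


# --- synthetic 54-site ABO reconstruction ---------------------------------

#: SYNTHETIC derived-site sets, engineered so the haplogroup representatives
#: reproduce the published clustering classes. Not HapMap data.
_ABO54_DERIVED: dict[str, tuple[int, ...]] = {
    "A101-A201-O09": (
        9, 11, 13, 15, 16, 19, 20, 21, 23, 25, 28, 29, 30, 31, 32,
        36, 37, 38, 46, 50, 51, 52, 53, 54,
    ),
    "B101": (
        11, 19, 20, 21, 22, 23, 24, 25, 27, 28, 29, 30, 31, 32,
        36, 37, 38, 46, 50, 51, 52, 53, 54,
    ),
    "O01": (
        9, 11, 13, 15, 19, 20, 21, 23, 25, 28, 29, 30, 31, 32,
        42, 44, 45, 47, 48, 49, 54,
    ),
    "O02": (38, 39, 40, 41, 42, 43, 47, 48, 49, 54),
    "O47": (1, 2, 5),
    "chimp": (),
}

#: site ordinal -> gene-feature label for the reconstruction (coarse).
_ABO54_FEATURES = {
    "intron 1": range(28, 36),
    "intron 2": range(12, 20),
    "intron 3": range(40, 44),
    "exon 6": range(36, 40),
    "exon 7": range(44, 55),
}


def synthetic_abo54_representatives() -> HaplotypeMatrix:
    """SYNTHETIC 54-site haplogroup representatives with chimpanzee outgroup.

    A constructed stand-in for the unavailable population reference data:
    allele states are chosen so that the five representatives show the
    reported informative-site classes (O01 with B101 at 11,19..32; O01 with
    O02 at 42,47..49; A101-A201-O09 with O01 at 9,13,15 and with B101 at
    36..53; site 54 homoplastic and hence outside every support class; site
    38 a parallel change that leaves O01 matching the outgroup where B101
    and O02 are derived).
    Δ261 lies between sites 15 and 16, carried by the O01 and O02 lineages.
    """
    L = 54
    names = list(_ABO54_DERIVED)
    rows = []
    for name in names:
        derived = set(_ABO54_DERIVED[name])
        rows.append(
            "".join(_symbols(j)[1 if (j + 1) in derived else 0] for j in range(L))
        )
    sites = [Site(index=j + 1) for j in range(L)]
    matrix = HaplotypeMatrix(
        names, rows, sites, {}, "chimp",
        [Marker("Δ261", 15, 16, frozenset({"O01", "O02"}))],
    )
    from .hapio import attach_annotations

    anns = [
        {"sites": list(rng), "feature": feat}
        for feat, rng in _ABO54_FEATURES.items()
    ]
    return attach_annotations(matrix, anns)


def synthetic_abo54_population() -> HaplotypeMatrix:
    """SYNTHETIC population sample built on the 54-site representatives.

    Copies per haplogroup follow a plausible three-population composition;
    two once-observed haplotypes (a private substitution on a common
    background each) are added so frequency filtering has something to drop.
    """
    reps = synthetic_abo54_representatives()
    counts = {
        "A101-A201-O09": {"YRI": 10, "CEU": 14, "JPT+CHB": 12},
        "B101": {"YRI": 6, "CEU": 3, "JPT+CHB": 5},
        "O01": {"YRI": 12, "CEU": 9, "JPT+CHB": 8},
        "O02": {"YRI": 6, "CEU": 2, "JPT+CHB": 2},
        "O47": {"YRI": 3, "CEU": 0, "JPT+CHB": 0},
    }
    names: list[str] = []
    rows: list[str] = []
    pops: dict[str, str] = {}
    carriers: dict[str, list[str]] = {m.name: [] for m in reps.markers}
    i = 0
    for group, per_pop in counts.items():
        base = reps.row(group)
        for pop, n in per_pop.items():
            for _ in range(n):
                i += 1
                rid = f"h{i:03d}"
                names.append(rid)
                rows.append(base)
                pops[rid] = pop
                for m in reps.markers:
                    if group in m.carriers:
                        carriers[m.name].append(rid)
    # two singleton haplotypes: a private substitution on common backgrounds
    for group, pop, site in (("O01", "YRI", 3), ("B101", "CEU", 4)):
        i += 1
        rid = f"h{i:03d}"
        base = list(reps.row(group))
        base[site - 1] = _symbols(site - 1)[1]
        names.append(rid)
        rows.append("".join(base))
        pops[rid] = pop
        if group == "O01":
            carriers["Δ261"].append(rid)
    names.append("chimp")
    rows.append(reps.row("chimp"))
    markers = [
        Marker(m.name, m.left, m.right, frozenset(carriers[m.name]))
        for m in reps.markers
    ]
    return HaplotypeMatrix(names, rows, list(reps.sites), pops, "chimp", markers)


def synthetic_abo54_panel() -> dict:
    """Illustrative diagnostic-SNP panel matching the synthetic 54-site data.

    Entries are (site ordinal, required allele symbol); this panel is an
    example for the reconstruction and the simulator's scenario, not a
    published reference panel.
    """

    def der(site: int) -> str:
        return _symbols(site - 1)[1]

    def anc(site: int) -> str:
        return _symbols(site - 1)[0]

    return {
        "labels": {
            "O47": [(1, der(1))],
            "B101": [(36, der(36)), (9, anc(9))],
            "A101-A201-O09": [(9, der(9)), (42, anc(42))],
            "O01": [(11, der(11)), (42, der(42))],
            "O02": [(42, der(42)), (11, anc(11))],
        },
        "priority": ["O47", "B101", "A101-A201-O09", "O01", "O02"],
        "fallback": "X",
    }


def step_e_preference_fixture() -> HaplotypeMatrix:
    """Five haplotypes where two parental quartets pass filtering and the
    winner is decided by the larger parental singleton sum.

    ``X`` is grouped with ``Pa`` at sites 3,4 and with ``Pb`` at 5,6; both
    share 10..12 with ``Pc``-free splits; singleton counts are Pa:1, Pb:3,
    Pc:2, X:1, so the quartet (X, Pc, Pb) beats (X, Pc, Pa): the parent with
    the longer external branch (more singletons) is preferred.
    """
    derived = {
        "X": (3, 4, 5, 6, 8, 10, 11, 12),
        "Pa": (3, 4, 20),
        "Pb": (5, 6, 21, 22, 23),
        "Pc": (10, 11, 12, 15, 16),
        "og": (),
    }
    L = 23
    names = list(derived)
    rows = [
        "".join(
            _symbols(j)[1 if (j + 1) in set(derived[n]) else 0] for j in range(L)
        )
        for n in names
    ]
    return HaplotypeMatrix(
        names, rows, [Site(index=j + 1) for j in range(L)], {}, "og"
    )


def abo_scenario(seed: int = 0) -> SimulationConfig:
    """Preset emulating the inferred ABO haplogroup history.

    Lineage plan (60 sites): an ancestral A-like allele; B101 diverges with
    private substitutions; O02 diverges carrying a Δ261-like marker between
    sites 30 and 31; O01 arises as a recombinant joining B101's 5′ segment to
    O02's 3′ segment (crossover after site 25, importing Δ261); A101 arises
    joining B101's 5′ (intact exon-6 analogue, no Δ261) to O01's 3′ (A-type
    exon-7 analogue) after site 32; XV joins O02's 5′ (with Δ261) to B101's 3′
    after site 35. A post-O01 parallel substitution shared by B101 and O02
    reproduces the outgroup-parallel pattern that removes O01 from quartet
    analysis at the empty-split step.
    """
    return SimulationConfig(
        n_sites=60,
        lineages=[
            LineageSpec("ancestor", None, 0),
            LineageSpec(
                "B101",
                "ancestor",
                3,
                window=(1, 25),
                batches=((3, (26, 32)), (2, (36, 60))),
            ),
            LineageSpec(
                "O02",
                "ancestor",
                3,
                window=(36, 60),
                batches=((2, (26, 32)), (2, (1, 25))),
            ),
        ],
        events=[
            Event("recombination", "O01", "B101", "O02", breakpoint=25),
            Event("recombination", "A101", "B101", "O01", breakpoint=32),
            Event("recombination", "XV", "O02", "B101", breakpoint=35),
        ],
        post_subs={
            "B101": 2,
            "O02": 2,
            "O01": 2,
            "A101": 1,
            "XV": 1,
        },
        parallel_subs=[(("B101", "O02"), (33, 35))],
        markers=[MarkerSpec("Δ261", 30, "O02")],
        outgroup_name="chimp",
        outgroup_subs=3,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# recovery experiments


@dataclass
class RecoveryDesign:
    """Study conditions for detector-validation replicates.

    One crossover between two diverged parents: each parent carries
    ``n_shared_*`` pre-event substitutions confined to its side of the
    breakpoint (these become the informative classes shared with the
    recombinant) plus post-event private substitutions; the recombinant adds
    ``n_private_r`` private substitutions, the outgroup ``n_outgroup``.
    """

    n_sites: int = 40
    breakpoint: int = 20
    n_shared_forward: int = 3
    n_shared_backward: int = 3
    n_private_p1: int = 3
    n_private_p2: int = 3
    n_private_r: int = 1
    n_outgroup: int = 3
    event: bool = True
    inject_outgroup_parallel: bool = False

    def config(self, seed: int) -> SimulationConfig:
        if self.event:
            return SimulationConfig(
                n_sites=self.n_sites,
                lineages=[
                    LineageSpec("anc", None, 0),
                    LineageSpec(
                        "p1", "anc", self.n_shared_forward, (1, self.breakpoint)
                    ),
                    LineageSpec(
                        "p2",
                        "anc",
                        self.n_shared_backward,
                        (self.breakpoint + 1, self.n_sites),
                    ),
                ],
                events=[
                    Event("recombination", "r", "p1", "p2", self.breakpoint)
                ],
                post_subs={
                    "p1": self.n_private_p1,
                    "p2": self.n_private_p2,
                    "r": self.n_private_r,
                },
                parallel_subs=(
                    [(("p1", "p2"), (1, self.n_sites))]
                    if self.inject_outgroup_parallel
                    else []
                ),
                outgroup_subs=self.n_outgroup,
                seed=seed,
            )
        # null history: nested tree, no reticulation
        return SimulationConfig(
            n_sites=self.n_sites,
            lineages=[
                LineageSpec("anc", None, 0),
                LineageSpec("x", "anc", 3),
                LineageSpec("p1", "x", 2),
                LineageSpec("p2", "x", 2),
                LineageSpec("r", "anc", 3),
            ],
            outgroup_subs=self.n_outgroup,
            seed=seed,
        )


def recovery_experiment(
    design: RecoveryDesign, n_reps: int, seed: int = 0
) -> dict:
    """Detection and interval-coverage rates over ``n_reps`` replicates.

    For each replicate both detectors run on the simulated matrix; a
    detection counts only if the called recombinant is the true one, and
    coverage only if the true crossover lies inside the reported interval.
    Returns aggregate rates plus per-replicate indicators.
    """
    from . import netrec, pnarec
    from .hapio import encode_binary
    from .mednet import build_median_network

    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rows = []
    rng = np.random.default_rng(seed)
    for rep in range(n_reps):
        cfg = design.config(int(rng.integers(0, 2**31 - 1)))
        matrix, truth = simulate(cfg)
        binary = encode_binary(matrix)
        ingroup = [n for n in matrix.names if n != matrix.outgroup_id]
        net = build_median_network(binary, max_dim=3)
        net_calls = netrec.detect_rectangle_recombinants(net, binary)
        pn_calls = pnarec.pnarec_scan(binary, selection=ingroup)
        rec = {"rep": rep}
        for tag, calls in (("network", net_calls), ("pnarec", pn_calls)):
            if design.event:
                tr = truth[0]
                hit = [c for c in calls if c.recombinant == tr.recombinant]
                det = len(hit) == 1 and len(calls) == 1
                cov = False
                if det:
                    left, right = hit[0].interval
                    cov = (
                        isinstance(left, int)
                        and isinstance(right, int)
                        and left <= tr.breakpoint[0]
                        and tr.breakpoint[1] <= right
                    )
                rec[f"{tag}_detected"] = det
                rec[f"{tag}_covered"] = cov
            else:
                rec[f"{tag}_false_positive"] = len(calls) > 0
        rows.append(rec)
    summary: dict = {"n_reps": n_reps, "replicates": rows}
    for key in rows[0]:
        if key == "rep":
            continue
        summary[f"{key}_rate"] = sum(r[key] for r in rows) / n_reps
    return summary
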