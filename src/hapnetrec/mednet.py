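"""Binary median networks over unique haplotypes.

A median network displays all most-parsimonious trees for a set of binary
haplotypes: the observed state vectors are closed under the coordinate-wise
majority (median) of every triple, latent (median) vectors not lying on any
shortest path between two observed haplotypes are discarded, and edges join
vectors differing by exactly one character. Mutually incompatible character
pairs (failing the four-gamete test) surface as rectangles — the reticulation
signature that downstream recombinant detection interprets.

Sites with identical 0/1 column patterns move together; they are grouped into
weighted *characters*, and every edge is labelled with the concrete site
ordinals of the character that changes across it.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import networkx as nx
import numpy as np

from .model import BinaryMatrix

__all__ = [
    "Character",
    "ExternalBranch",
    "MedianNetwork",
    "DimensionalityError",
    "build_median_network",
    "external_branch",
    "export_network",
]


@dataclass(frozen=True)
class Character:
    """A maximal group of sites sharing one 0/1 pattern across the input rows."""

    pattern: tuple[int, ...]  # one state per input row, row order of the matrix
    sites: tuple[int, ...]  # 1-based ordinals carrying this pattern

    @property
    def weight(self) -> int:
        return len(self.sites)


@dataclass
class ExternalBranch:
    """The pendant chain from a haplotype node to the nearest branching vertex."""

    node: str
    path: list[tuple[str, str]]
    sites: list[int]
    note: Optional[str] = None

    @property
    def length(self) -> int:
        return len(self.sites)


class DimensionalityError(ValueError):
    """Raised when reticulation would exceed the requested dimensionality."""

    def __init__(self, dim: int, max_dim: int, haplotypes: Sequence[str]):
        self.dim = dim
        self.max_dim = max_dim
        self.haplotypes = list(haplotypes)
        super().__init__(
            f"{dim} mutually incompatible characters exceed max_dim={max_dim}; "
            f"consider excluding haplotypes: {', '.join(self.haplotypes)}"
        )


@dataclass
class MedianNetwork:
    graph: nx.Graph
    characters: list[Character]
    outgroup: Optional[str]
    observed: dict[str, tuple[int, ...]]  # name -> character-state vector
    multiplicities: dict[str, int] = field(default_factory=dict)
    populations: dict[str, dict[str, int]] = field(default_factory=dict)

    @property
    def median_nodes(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if not d["observed"]]

    def edge_sites(self, u: str, v: str) -> tuple[int, ...]:
        return tuple(self.graph.edges[u, v]["sites"])

    def rectangles(self) -> list[tuple[frozenset, frozenset]]:
        """Chordless 4-cycles as pairs of opposing (diagonal) vertex pairs."""
        g = self.graph
        out = set()
        nodes = sorted(g.nodes)
        for u, v in itertools.combinations(nodes, 2):
            if g.has_edge(u, v):
                continue
            common = sorted(set(g[u]) & set(g[v]))
            for x, y in itertools.combinations(common, 2):
                if not g.has_edge(x, y):
                    diags = tuple(
                        sorted((frozenset((u, v)), frozenset((x, y))), key=sorted)
                    )
                    out.add(diags)
        return sorted(out, key=lambda r: (sorted(r[0]), sorted(r[1])))

    def candidate_parallel_sites(self) -> dict[int, int]:
        """Lone sites conflicting with multi-site characters.

        A median network turns homoplasy into reticulation, so a repeated
        substitution is indistinguishable per se from a recombination
        signal. Weight tips the balance: a class of several sites moving
        together is credible as a transferred segment, while a *single* site
        incompatible with such a class is more parsimoniously a parallel
        (or back) substitution. Flags each site carried by a weight-1
        character that is incompatible with at least one character of
        weight >= 2; returns {site ordinal: number of conflicting
        multi-site characters}.
        """
        flagged: dict[int, int] = {}
        heavy = [c for c in self.characters if c.weight >= 2]
        for ch in self.characters:
            if ch.weight != 1:
                continue
            n_conflicts = sum(1 for h in heavy if _incompatible(ch, h))
            if n_conflicts:
                flagged[ch.sites[0]] = n_conflicts
        return flagged


def _characters(matrix: BinaryMatrix) -> list[Character]:
    cols: dict[tuple[int, ...], list[int]] = {}
    for j in range(matrix.n_sites):
        pat = tuple(int(x) for x in matrix.data[:, j])
        if len(set(pat)) < 2:
            continue  # constant across all retained rows: no edge to label
        cols.setdefault(pat, []).append(j + 1)
    chars = [Character(pat, tuple(sites)) for pat, sites in cols.items()]
    chars.sort(key=lambda c: c.sites)
    return chars


def _incompatible(a: Character, b: Character) -> bool:
    gametes = set(zip(a.pattern, b.pattern))
    return len(gametes) == 4


def _max_incompatible_clique(chars: Sequence[Character]) -> list[int]:
    g = nx.Graph()
    g.add_nodes_from(range(len(chars)))
    for i, j in itertools.combinations(range(len(chars)), 2):
        if _incompatible(chars[i], chars[j]):
            g.add_edge(i, j)
    best: list[int] = []
    for clique in nx.find_cliques(g):
        if len(clique) > len(best):
            best = clique
    return sorted(best)


def build_median_network(
    matrix: BinaryMatrix, max_dim: int = 3
) -> MedianNetwork:
    """Median closure + geodesic pruning over the unique rows of ``matrix``.

    Raises :class:`DimensionalityError` when more than ``max_dim`` characters
    are pairwise incompatible (the reticulation would need a hypercube of
    higher dimension); the error names the haplotypes involved so the caller
    can exclude them, mirroring manual curation practice.
    Raises ``ValueError`` on duplicate rows — collapse them first.
    """
    rows = [tuple(int(x) for x in matrix.data[i]) for i in range(len(matrix.names))]
    if len(set(rows)) != len(rows):
        seen: dict[tuple, str] = {}
        dupes = []
        for name, r in zip(matrix.names, rows):
            if r in seen:
                dupes.append((seen[r], name))
            seen[r] = name
        raise ValueError(f"duplicate rows (collapse first): {dupes}")
    chars = _characters(matrix)
    clique = _max_incompatible_clique(chars)
    if len(clique) > max_dim:
        involved: set[str] = set()
        for i in clique:
            pat = chars[i].pattern
            derived = {matrix.names[k] for k, s in enumerate(pat) if s == 1}
            # haplotypes realising the conflicting (minority) gametes
            involved |= derived
        raise DimensionalityError(len(clique), max_dim, sorted(involved))

    # observed vectors in character space
    obs_vec = {
        name: tuple(ch.pattern[i] for ch in chars)
        for i, name in enumerate(matrix.names)
    }
    closure: set[tuple[int, ...]] = set(obs_vec.values())
    frontier = list(closure)
    while True:
        added = []
        pool = sorted(closure)
        for a, b, c in itertools.combinations(pool, 3):
            m = tuple(
                1 if (x + y + z) >= 2 else 0 for x, y, z in zip(a, b, c)
            )
            if m not in closure:
                closure.add(m)
                added.append(m)
        if not added:
            break

    # geodesic pruning: keep vectors on a shortest (Hamming) path between
    # two observed vectors; in a median-closed set graph distance equals
    # character Hamming distance, so the arithmetic test suffices.
    def ham(a: tuple[int, ...], b: tuple[int, ...]) -> int:
        return sum(x != y for x, y in zip(a, b))

    observed_vecs = list(obs_vec.values())
    kept = []
    for v in sorted(closure):
        on_geo = any(
            ham(a, v) + ham(v, b) == ham(a, b)
            for a, b in itertools.combinations(observed_vecs, 2)
        ) or v in observed_vecs
        if on_geo:
            kept.append(v)

    vec_name: dict[tuple[int, ...], str] = {}
    for name in matrix.names:  # deterministic: observed names first
        vec_name[obs_vec[name]] = name
    m_count = 0
    for v in kept:
        if v not in vec_name:
            m_count += 1
            vec_name[v] = f"m{m_count}"

    g = nx.Graph()
    for v in kept:
        name = vec_name[v]
        g.add_node(name, vector=v, observed=v in set(obs_vec.values()))
    for a, b in itertools.combinations(kept, 2):
        diff = [k for k in range(len(chars)) if a[k] != b[k]]
        if len(diff) == 1:
            g.add_edge(
                vec_name[a], vec_name[b], sites=list(chars[diff[0]].sites)
            )
    if len(g) and not nx.is_connected(g):
        raise AssertionError("median network is disconnected (internal error)")
    return MedianNetwork(
        graph=g,
        characters=chars,
        outgroup=matrix.outgroup_id,
        observed=dict(obs_vec),
    )


def external_branch(net: MedianNetwork, node: str) -> ExternalBranch:
    """Walk from ``node`` to the nearest vertex of degree >= 3 or observed node.

    The length is the number of site labels accumulated along the chain. A
    node sitting directly on a reticulation (degree >= 2 branching vertex)
    has an empty external branch (length 0, with a note).
    """
    g = net.graph
    if node not in g:
        raise KeyError(f"node {node!r} not in network")
    if g.degree[node] >= 2:
        return ExternalBranch(node, [], [], note="node lies on a branching vertex")
    path: list[tuple[str, str]] = []
    sites: list[int] = []
    prev, cur = None, node
    while True:
        nbrs = [n for n in g[cur] if n != prev]
        if not nbrs:
            break
        nxt = nbrs[0]
        path.append((cur, nxt))
        sites.extend(g.edges[cur, nxt]["sites"])
        if g.degree[nxt] >= 3 or g.nodes[nxt]["observed"]:
            break
        prev, cur = cur, nxt
    return ExternalBranch(node, path, sites)


def export_network(
    net: MedianNetwork, path: Union[str, Path], format: str = "graphml"
) -> Path:
    """Write the network as GraphML or DOT with node/edge annotations."""
    if len(net.graph) == 0:
        raise ValueError("cannot export an empty network")
    path = Path(path)
    g = nx.Graph()
    for n, d in net.graph.nodes(data=True):
        g.add_node(
            n,
            observed=bool(d["observed"]),
            multiplicity=int(net.multiplicities.get(n, 1 if d["observed"] else 0)),
            populations=";".join(
                f"{p}:{c}" for p, c in sorted(net.populations.get(n, {}).items())
            ),
        )
    for u, v, d in net.graph.edges(data=True):
        g.add_edge(u, v, sites=",".join(map(str, d["sites"])))
    if format == "graphml":
        nx.write_graphml(g, path)
    elif format == "dot":
        lines = ["graph hapnet {"]
        for n, d in sorted(g.nodes(data=True)):
            shape = "ellipse" if d["observed"] else "point"
            lines.append(
                f'  "{n}" [shape={shape}, multiplicity="{d["multiplicity"]}"];'
            )
        for u, v, d in sorted(g.edges(data=True)):
            lines.append(f'  "{u}" -- "{v}" [label="{d["sites"]}"];')
        lines.append("}")
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown export format {format!r}")
    return path
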