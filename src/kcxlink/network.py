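"""XL-PPI network assembly and interrogation.

Inter-protein linkages become edges between unordered protein pairs; every
cross-linked protein (including intra-only ones) is a node.  Edges can be
compared against reference edge sets (BioGRID/BioPlex/STRING exports),
protein complexes scored for subunit recovery (CORUM-style tables), and
multi-linker concordance tabulated.  Identifier reconciliation is the
caller's job (explicit mapping tables; no fuzzy matching).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .identify import UniqueLinkage


@dataclass
class PPIEdge:
    pair: tuple[str, str]  # sorted
    linkage_count: int = 0
    linkers: set[str] = field(default_factory=set)
    replicates: set[str] = field(default_factory=set)
    ambiguous: bool = False


@dataclass
class XLNetwork:
    graph: nx.Graph
    self_links: dict[str, int]  # homodimer-capable self-evidence, kept apart

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> list[PPIEdge]:
        return [data["edge"] for _, _, data in self.graph.edges(data=True)]


def build_network(
    linkages: Sequence[UniqueLinkage], include_ambiguous: bool = False
) -> XLNetwork:
    """One edge per unordered inter-protein pair; nodes are all cross-linked
    proteins.  Ambiguous linkages (peptides shared across proteins) are
    excluded from edge building unless ``include_ambiguous``; self-pairs are
    reported separately, never as edges."""
    g = nx.Graph()
    self_links: dict[str, int] = {}
    for lk in linkages:
        g.add_node(lk.protein_a)
        g.add_node(lk.protein_b)
        if lk.is_intra:
            self_links[lk.protein_a] = self_links.get(lk.protein_a, 0) + 1
            continue
        if lk.ambiguous and not include_ambiguous:
            continue
        pair = tuple(sorted((lk.protein_a, lk.protein_b)))
        if not g.has_edge(*pair):
            g.add_edge(*pair, edge=PPIEdge(pair=pair))
        edge: PPIEdge = g.edges[pair]["edge"]
        edge.linkage_count += 1
        edge.linkers |= lk.linkers
        edge.replicates |= {rep for _, rep in lk.support}
        edge.ambiguous |= lk.ambiguous
    return XLNetwork(graph=g, self_links=self_links)


@dataclass
class ReferenceEdgeSet:
    name: str
    pairs: frozenset[tuple[str, str]]

    @classmethod
    def from_pairs(cls, name: str, pairs: Iterable[tuple[str, str]]) -> "ReferenceEdgeSet":
        return cls(name, frozenset(tuple(sorted(p)) for p in pairs if p[0] != p[1]))

    @classmethod
    def from_tsv(cls, path: str | Path, name: str | None = None) -> "ReferenceEdgeSet":
        import pandas as pd

        df = pd.read_csv(path, sep="\t")
        cols = df.columns[:2]
        return cls.from_pairs(
            name or Path(path).stem,
            zip(df[cols[0]].astype(str), df[cols[1]].astype(str)),
        )


@dataclass
class OverlapResult:
    shared: set[tuple[str, str]]
    novel: set[tuple[str, str]]

    @property
    def shared_fraction(self) -> float:
        total = len(self.shared) + len(self.novel)
        return len(self.shared) / total if total else 0.0

    @property
    def novel_fraction(self) -> float:
        total = len(self.shared) + len(self.novel)
        return len(self.novel) / total if total else 0.0


def overlap_with(network: XLNetwork, reference: ReferenceEdgeSet) -> OverlapResult:
    """Set intersection of normalized XL edges with a reference edge set."""
    xl_pairs = {e.pair for e in network.edges}
    return OverlapResult(
        shared=xl_pairs & reference.pairs, novel=xl_pairs - reference.pairs
    )


@dataclass(frozen=True)
class ComplexDefinition:
    complex_id: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError("a complex needs at least 2 members")


def load_complexes(path: str | Path) -> list[ComplexDefinition]:
    """Complex table: TSV with columns complex_id and a ;-separated members
    column."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    return [
        ComplexDefinition(str(r.complex_id), frozenset(str(r.members).split(";")))
        for r in df.itertuples()
    ]


@dataclass
class ComplexCoverage:
    per_complex: dict[str, float]  # identified complexes only (>=1 member)
    histogram: dict[str, int]

    @property
    def n_identified(self) -> int:
        return len(self.per_complex)

    @property
    def fraction_over_half(self) -> float:
        """Fraction of identified complexes with strictly more than 50%
        subunit recovery."""
        if not self.per_complex:
            return 0.0
        return sum(1 for f in self.per_complex.values() if f > 0.5) / len(self.per_complex)


def complex_coverage(
    nodes: Iterable[str],
    complexes: Sequence[ComplexDefinition],
    bins: Sequence[float] = (0.25, 0.5, 0.75, 1.0),
) -> ComplexCoverage:
    """Recovered-subunit fraction per complex with >=1 recovered member, and a
    histogram over ``bins`` (right-closed: (prev, b])."""
    node_set = set(nodes)
    per_complex: dict[str, float] = {}
    for cx in complexes:
        hit = len(cx.members & node_set)
        if hit:
            per_complex[cx.complex_id] = hit / len(cx.members)
    histogram: dict[str, int] = {}
    edges = [0.0] + list(bins)
    for lo, hi in zip(edges[:-1], edges[1:]):
        label = f"({lo:g}, {hi:g}]"
        histogram[label] = sum(1 for f in per_complex.values() if lo < f <= hi)
    return ComplexCoverage(per_complex=per_complex, histogram=histogram)


def linker_concordance(linkages: Sequence[UniqueLinkage]) -> dict[str, dict[int, int]]:
    """Counts of linkages and of inter-protein edges supported by 1, 2 or 3+
    linkers.  Edge-level linker sets are unions over supporting linkages."""
    link_counts: dict[int, int] = {}
    for lk in linkages:
        n = len(lk.linkers)
        link_counts[n] = link_counts.get(n, 0) + 1
    edge_linkers: dict[tuple[str, str], set[str]] = {}
    for lk in linkages:
        if lk.is_intra:
            continue
        pair = tuple(sorted((lk.protein_a, lk.protein_b)))
        edge_linkers.setdefault(pair, set()).update(lk.linkers)
    edge_counts: dict[int, int] = {}
    for linkers in edge_linkers.values():
        n = len(linkers)
        edge_counts[n] = edge_counts.get(n, 0) + 1
    return {"linkages": link_counts, "edges": edge_counts}


def write_graphml(network: XLNetwork, path: str | Path) -> None:
    g = nx.Graph()
    g.add_nodes_from(network.graph.nodes)
    for edge in network.edges:
        g.add_edge(
            *edge.pair,
            linkage_count=edge.linkage_count,
            linkers=";".join(sorted(edge.linkers)),
        )
    nx.write_graphml(g, str(path))
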