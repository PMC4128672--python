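"""Interaction-evidence consolidation and crosstalk network assembly.

Physical-interaction catalogues from several databases are consolidated
into one undirected edge set (gene pairs normalized lexicographically,
provenance identifiers merged per pair).  The crosstalk network then links
one cell type's secreted factors to the OTHER cell type's membrane
proteins: an edge (s, m) appears iff the pair is in the catalogue and
either s is germ-cell secreted and m Sertoli-cell membrane, or s is
Sertoli-cell secreted and m germ-cell membrane.  The network is bipartite
by construction between secreted and membrane roles.

A gene may legitimately act both as a secreted factor of its own cell and
as a membrane protein of that same cell; such dual-role genes are kept as
two role-specific nodes, exported with ``|sec`` / ``|mem`` suffixes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx

from .integrate import CellGeneSets

GC_SECRETED = "GC_secreted"
SC_SECRETED = "SC_secreted"
GC_MEMBRANE = "GC_membrane"
SC_MEMBRANE = "SC_membrane"
NODE_CLASSES = (GC_SECRETED, SC_SECRETED, GC_MEMBRANE, SC_MEMBRANE)
_SECRETED = {GC_SECRETED, SC_SECRETED}


@dataclass
class InteractionCatalog:
    """Undirected gene-pair edges with per-pair provenance label sets."""

    edges: dict[tuple[str, str], set[str]] = field(default_factory=dict)

    def add(self, gene_a: str, gene_b: str, provenance: str, allow_self: bool = False) -> None:
        if gene_a == gene_b and not allow_self:
            raise ValueError(f"self-interaction {gene_a!r} not allowed (pass allow_self=True)")
        pair = (gene_a, gene_b) if gene_a <= gene_b else (gene_b, gene_a)
        self.edges.setdefault(pair, set()).add(provenance)

    def __len__(self) -> int:
        return len(self.edges)


def consolidate_interactions(sources: Sequence[InteractionCatalog]) -> InteractionCatalog:
    """Union of catalogues; duplicate (pair, provenance) records collapse."""
    out = InteractionCatalog()
    for cat in sources:
        for pair, prov in cat.edges.items():
            out.edges.setdefault(pair, set()).update(prov)
    return out


@dataclass
class CrosstalkNetwork:
    """Bipartite secreted->membrane network with provenance.

    nodes: node id -> (gene, class); node ids equal gene ids except for
    dual-role genes, which get ``gene|sec`` / ``gene|mem``.
    edges: (secreted node id, membrane node id, provenance frozenset).
    """

    nodes: dict[str, tuple[str, str]] = field(default_factory=dict)
    edges: list[tuple[str, str, frozenset[str]]] = field(default_factory=list)

    @property
    def class_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in NODE_CLASSES}
        for _, klass in self.nodes.values():
            counts[klass] += 1
        return counts

    @property
    def provenance_count(self) -> int:
        distinct: set[str] = set()
        for _, _, prov in self.edges:
            distinct |= prov
        return len(distinct)

    def gene_pairs(self) -> set[tuple[str, str]]:
        """Underlying unordered gene pairs (lexicographic), role-agnostic."""
        pairs = set()
        for s, m, _ in self.edges:
            a, b = self.nodes[s][0], self.nodes[m][0]
            pairs.add((a, b) if a <= b else (b, a))
        return pairs

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for node_id, (gene, klass) in self.nodes.items():
            g.add_node(node_id, gene=gene, **{"class": klass})
        for s, m, prov in self.edges:
            g.add_edge(s, m, provenance=";".join(sorted(prov)))
        return g


def build_crosstalk(
    gc: CellGeneSets, sc: CellGeneSets, catalog: InteractionCatalog
) -> CrosstalkNetwork:
    """Assemble the four-class crosstalk network from catalogued pairs.

    Requires the two transcriptomes to be disjoint (conflict rule applied
    upstream).  Nodes without any edge are excluded; self-pairs never
    qualify because the endpoint sets belong to different transcriptomes.
    """
    if gc.transcriptome & sc.transcriptome:
        raise ValueError(
            "germ and Sertoli transcriptomes overlap; apply conflict resolution first"
        )

    semantic: list[tuple[str, str, str, str, frozenset[str]]] = []
    for (a, b), prov in catalog.edges.items():
        prov_f = frozenset(prov)
        for s, m in ((a, b), (b, a)):
            if s in gc.cell_secretome and m in sc.cell_membranome:
                semantic.append((s, m, GC_SECRETED, SC_MEMBRANE, prov_f))
            if s in sc.cell_secretome and m in gc.cell_membranome:
                semantic.append((s, m, SC_SECRETED, GC_MEMBRANE, prov_f))

    roles: dict[str, set[str]] = {}
    for s, m, cs, cm, _ in semantic:
        roles.setdefault(s, set()).add(cs)
        roles.setdefault(m, set()).add(cm)

    def node_id(gene: str, klass: str) -> str:
        if len(roles[gene]) == 1:
            return gene
        return f"{gene}|sec" if klass in _SECRETED else f"{gene}|mem"

    net = CrosstalkNetwork()
    seen: set[tuple[str, str]] = set()
    for s, m, cs, cm, prov_f in sorted(semantic, key=lambda e: (e[0], e[1], e[2])):
        sid, mid = node_id(s, cs), node_id(m, cm)
        net.nodes[sid] = (s, cs)
        net.nodes[mid] = (m, cm)
        if (sid, mid) not in seen:
            seen.add((sid, mid))
            net.edges.append((sid, mid, prov_f))
    return net


def network_summary(net: CrosstalkNetwork) -> dict:
    """Node counts per class, edge count, provenance count, degree histogram."""
    degree: dict[str, int] = {n: 0 for n in net.nodes}
    for s, m, _ in net.edges:
        degree[s] += 1
        degree[m] += 1
    hist: dict[int, int] = {}
    for d in degree.values():
        hist[d] = hist.get(d, 0) + 1
    return {
        "class_counts": net.class_counts,
        "n_nodes": len(net.nodes),
        "n_edges": len(net.edges),
        "n_provenance": net.provenance_count,
        "degree_distribution": dict(sorted(hist.items())),
    }


# ---------------------------------------------------------------------------
# I/O


def read_interactions(path: str | Path) -> InteractionCatalog:
    """Read a (geneA, geneB, provenance) TSV with a header line."""
    cat = InteractionCatalog()
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        if not header.strip():
            raise ValueError(f"{path}: missing header line")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns")
            cat.add(parts[0], parts[1], parts[2])
    return cat


def write_interactions(cat: InteractionCatalog, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("geneA\tgeneB\tprovenance\n")
        for (a, b) in sorted(cat.edges):
            for prov in sorted(cat.edges[(a, b)]):
                fh.write(f"{a}\t{b}\t{prov}\n")


def write_graphml(net: CrosstalkNetwork, path: str | Path) -> None:
    nx.write_graphml(net.to_networkx(), path)


def read_graphml(path: str | Path) -> CrosstalkNetwork:
    g = nx.read_graphml(path)
    net = CrosstalkNetwork()
    for node_id, data in g.nodes(data=True):
        net.nodes[node_id] = (data["gene"], data["class"])
    for u, v, data in g.edges(data=True):
        prov = frozenset(data["provenance"].split(";")) if data.get("provenance") else frozenset()
        # GraphML loses edge orientation; recover secreted->membrane from classes
        if net.nodes[u][1] in _SECRETED:
            net.edges.append((u, v, prov))
        else:
            net.edges.append((v, u, prov))
    net.edges.sort(key=lambda e: (e[0], e[1]))
    return net


def write_sif(net: CrosstalkNetwork, path: str | Path) -> None:
    """SIF export: one `secreted <tab> secretes_to <tab> membrane` line per edge."""
    with open(path, "w", encoding="utf-8") as fh:
        for s, m, _ in sorted(net.edges):
            fh.write(f"{s}\tsecretes_to\t{m}\n")


def write_edge_table(net: CrosstalkNetwork, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("secreted\tsecreted_class\tmembrane\tmembrane_class\tprovenance\n")
        for s, m, prov in sorted(net.edges):
            fh.write(
                f"{net.nodes[s][0]}\t{net.nodes[s][1]}\t{net.nodes[m][0]}\t"
                f"{net.nodes[m][1]}\t{';'.join(sorted(prov))}\n"
            )
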