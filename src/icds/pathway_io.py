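"""Pathways as undirected gene graphs: edge-list and KGML-subset readers.

A pathway is modelled as a simple undirected graph with gene symbols as
nodes and biological relations as edges.  The canonical interchange format
is a four-column TSV edge list ``(pathway_id, pathway_name, gene_a,
gene_b)``; a reader for a subset of KEGG's KGML XML is also provided.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import networkx as nx
from lxml import etree

from .errors import IcdsError, ValidationError

logger = logging.getLogger("icds")


@dataclass
class PathwayGraph:
    pathway_id: str
    name: str
    graph: nx.Graph = field(default_factory=nx.Graph)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[frozenset[str]]:
        return {frozenset(e) for e in self.graph.edges}

    def __contains__(self, gene: str) -> bool:
        return gene in self.graph

    def add_edge(self, a: str, b: str) -> None:
        if a == b:
            logger.warning("%s: dropping self-loop on %s (node kept)", self.pathway_id, a)
            self.graph.add_node(a)
            return
        self.graph.add_edge(a, b)


class PathwayGraphSet:
    """Insertion-ordered collection of pathway graphs keyed by pathway_id."""

    def __init__(self, graphs: list[PathwayGraph] | None = None):
        self._graphs: dict[str, PathwayGraph] = {}
        for g in graphs or []:
            self.add(g)

    def add(self, g: PathwayGraph) -> None:
        if g.pathway_id in self._graphs:
            raise ValidationError(f"duplicate pathway_id {g.pathway_id!r}")
        self._graphs[g.pathway_id] = g

    def __getitem__(self, pathway_id: str) -> PathwayGraph:
        return self._graphs[pathway_id]

    def __iter__(self) -> Iterator[PathwayGraph]:
        return iter(self._graphs.values())

    def __len__(self) -> int:
        return len(self._graphs)

    def __contains__(self, pathway_id: str) -> bool:
        return pathway_id in self._graphs

    @property
    def pathway_ids(self) -> tuple[str, ...]:
        return tuple(self._graphs)

    def gene_universe(self) -> tuple[str, ...]:
        """All genes appearing in any pathway, sorted for determinism."""
        genes: set[str] = set()
        for g in self:
            genes |= g.nodes
        return tuple(sorted(genes))


def read_edgelist(path: str | Path) -> PathwayGraphSet:
    """Read the four-column TSV edge-list format.

    Duplicate and reversed edges collapse onto one undirected edge;
    self-loops are dropped with a warning (the node is kept).
    """
    path = Path(path)
    graphs = PathwayGraphSet()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValidationError(
                    f"{path}: line {lineno}: expected 4 tab-separated fields, got {len(fields)}"
                )
            pid, name, a, b = (f.strip() for f in fields[:4])
            if pid not in graphs:
                graphs.add(PathwayGraph(pid, name))
            graphs[pid].add_edge(a, b)
    return graphs


def write_edgelist(graphs: PathwayGraphSet, path: str | Path) -> None:
    """Writer mirroring :func:`read_edgelist` (edges sorted per pathway)."""
    with open(path, "w") as fh:
        for pg in graphs:
            for a, b in sorted(tuple(sorted(e)) for e in pg.graph.edges):
                fh.write(f"{pg.pathway_id}\t{pg.name}\t{a}\t{b}\n")


def _entry_genes(entry: etree._Element) -> list[str]:
    if entry.get("type") != "gene":
        return []
    names = (entry.get("name") or "").split()
    genes = []
    for n in names:
        genes.append(n.split(":", 1)[1] if ":" in n else n)
    return genes


def read_kgml(path: str | Path) -> PathwayGraph:
    """Read a KGML (KEGG XML) subset into an undirected gene graph.

    Gene-type entries contribute their genes as nodes.  A relation between
    two entries yields all pairwise gene-gene edges across the two entries;
    no clique is drawn within a multi-gene entry (its members are
    alternatives, not interactors).  Compound and map entries are ignored.
    """
    path = Path(path)
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise IcdsError(f"{path}: malformed KGML XML: {exc}") from exc
    root = tree.getroot()
    pg = PathwayGraph(root.get("name", path.stem), root.get("title", ""))
    genes_by_entry: dict[str, list[str]] = {}
    for entry in root.findall("entry"):
        genes = _entry_genes(entry)
        if genes:
            genes_by_entry[entry.get("id")] = genes
            pg.graph.add_nodes_from(genes)
    for rel in root.findall("relation"):
        a_genes = genes_by_entry.get(rel.get("entry1"), [])
        b_genes = genes_by_entry.get(rel.get("entry2"), [])
        for a in a_genes:
            for b in b_genes:
                if a != b:
                    pg.add_edge(a, b)
    return pg


def induced_diameter(graph: PathwayGraph, genes) -> float:
    """Diameter of the subgraph induced by ``genes``.

    Returns the maximum shortest-path distance between any two of the genes
    measured *inside* the induced subgraph; ``inf`` if that subgraph is
    disconnected.  This is the locality constraint of the greedy search.
    """
    genes = set(genes)
    if not genes:
        raise IcdsError("induced_diameter: empty gene set")
    missing = genes - graph.nodes
    if missing:
        raise IcdsError(f"induced_diameter: genes not in pathway {graph.pathway_id}: {sorted(missing)}")
    if len(genes) == 1:
        return 0
    sub = graph.graph.subgraph(genes)
    if not nx.is_connected(sub):
        return math.inf
    return nx.diameter(sub)


def full_graph_max_distance(graph: PathwayGraph, genes,
                            _cache: dict | None = None) -> float:
    """Maximum pairwise shortest-path distance measured in the full pathway.

    Alternative distance semantics, switchable in the search config.
    """
    genes = sorted(set(genes))
    if not genes:
        raise IcdsError("full_graph_max_distance: empty gene set")
    cache = _cache if _cache is not None else {}
    best = 0.0
    for g in genes:
        if g not in cache:
            cache[g] = nx.single_source_shortest_path_length(graph.graph, g)
        dists = cache[g]
        for h in genes:
            if h == g:
                continue
            best = max(best, dists.get(h, math.inf))
    return best
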