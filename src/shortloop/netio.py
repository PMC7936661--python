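"""Reading, merging, filtering and writing protein-protein interaction networks.

Networks are simple undirected graphs: proteins are nodes (accession strings in
a single namespace, case-sensitive), physical interactions are edges. Self
interactions and duplicate records are dropped on ingest; each retained edge
remembers the set of source labels it was seen in, so a network merged from
several interaction databases keeps per-edge provenance.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx

logger = logging.getLogger(__name__)

_EDGE_FORMATS = ("tsv", "sif", "graphml")


class Network:
    """Simple undirected PPI graph with per-edge source provenance.

    Thin wrapper over :class:`networkx.Graph` that enforces the invariants of
    the domain: no self-loops, no parallel edges, every edge endpoint present
    as a node, and a ``sources`` set attached to every edge.
    """

    def __init__(self, graph: nx.Graph | None = None):
        self.graph = graph if graph is not None else nx.Graph()

    # -- construction -----------------------------------------------------

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str]],
        source_label: str | None = None,
        nodes: Iterable[str] = (),
    ) -> "Network":
        """Build a network from an iterable of accession pairs.

        Self pairs are dropped; repeated pairs (in either order) collapse to a
        single edge whose source set accumulates ``source_label``.
        """
        net = cls()
        for extra in nodes:
            net.graph.add_node(extra)
        for a, b in edges:
            net.add_edge(a, b, source_label)
        return net

    def add_edge(self, a: str, b: str, source_label: str | None = None) -> None:
        if a == b:
            return
        g = self.graph
        if g.has_edge(a, b):
            if source_label is not None:
                g.edges[a, b]["sources"].add(source_label)
        else:
            sources = {source_label} if source_label is not None else set()
            g.add_edge(a, b, sources=sources)

    # -- views ------------------------------------------------------------

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[frozenset[str]]:
        return {frozenset(e) for e in self.graph.edges}

    def edge_sources(self, a: str, b: str) -> set[str]:
        return set(self.graph.edges[a, b]["sources"])

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def has_edge(self, a: str, b: str) -> bool:
        return self.graph.has_edge(a, b)

    def degree(self, node: str) -> int:
        return self.graph.degree(node)

    def copy(self) -> "Network":
        return Network(self.graph.copy())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Network):
            return NotImplemented
        return self.nodes == other.nodes and self.edges == other.edges

    def __repr__(self) -> str:
        return f"Network(n_nodes={self.n_nodes}, n_edges={self.n_edges})"


def _parse_columns(row: list[str], dialect: Mapping[str, int]) -> tuple[str, str]:
    ia = dialect.get("col_a", 0)
    ib = dialect.get("col_b", 1)
    return row[ia].strip(), row[ib].strip()


def read_edge_list(
    path: str | Path,
    source_label: str = "",
    *,
    keep_isolated: bool = False,
    id_mapping: Mapping[str, str] | None = None,
    dialect: Mapping[str, int] | None = None,
) -> Network:
    """Read a two-column (plus optional source column) edge TSV into a Network.

    Lines starting with ``#`` are comments. Self-loops are removed and
    duplicate rows collapsed. When ``keep_isolated`` is true, a node whose only
    record was a self-loop is retained as an isolated node; by default it is
    dropped, since protein membership in a PPIN is defined by having an
    interaction. ``id_mapping`` optionally translates accessions before
    merging; rows with an unmapped accession are dropped (count logged).

    Raises ``ValueError`` naming the line number on a malformed row.
    """
    path = Path(path)
    dialect = dialect or {}
    net = Network()
    n_rows = 0
    n_unmapped = 0
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                parts = line.split()
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected at least 2 columns, got {line!r}")
            a, b = _parse_columns(parts, dialect)
            if not a or not b:
                raise ValueError(f"{path}:{lineno}: empty accession in row {line!r}")
            if id_mapping is not None:
                if a not in id_mapping or b not in id_mapping:
                    n_unmapped += 1
                    continue
                a, b = id_mapping[a], id_mapping[b]
            n_rows += 1
            if a == b:
                if keep_isolated:
                    net.graph.add_node(a)
                continue
            net.add_edge(a, b, source_label)
    if id_mapping is not None and n_unmapped:
        logger.info("%s: dropped %d rows with unmapped accessions", path, n_unmapped)
    if n_rows == 0:
        warnings.warn(f"{path}: no interaction rows found; returning empty network")
    return net


def merge_networks(networks: list[Network]) -> Network:
    """Union-merge networks: node union, edge union, per-edge source union.

    Duplicate interactions collapse to one edge; the merged network contains
    no self-loops (none of the inputs may, by invariant).
    """
    if not networks:
        raise ValueError("merge_networks requires at least one network")
    merged = Network()
    for net in networks:
        for node in net.graph.nodes:
            merged.graph.add_node(node)
        for a, b, data in net.graph.edges(data=True):
            sources = data.get("sources", set())
            if merged.graph.has_edge(a, b):
                merged.graph.edges[a, b]["sources"].update(sources)
            else:
                merged.graph.add_edge(a, b, sources=set(sources))
    return merged


def induce_subnetwork(
    network: Network, proteins: set[str]
) -> tuple[Network, int]:
    """Extract the subnetwork induced by a protein set.

    Nodes are the intersection of ``proteins`` with the network; edges are all
    network edges with both endpoints in that intersection. Returns the induced
    network together with the mapping coverage, ``100 * |mapped| / |input|``
    rounded to the nearest integer percent (0 for an empty input set).
    """
    mapped = proteins & set(network.graph.nodes)
    coverage = round(100 * len(mapped) / len(proteins)) if proteins else 0
    if proteins and not mapped:
        warnings.warn("no input proteins map to the network; empty subnetwork")
    sub = Network(nx.Graph(network.graph.subgraph(mapped)))
    # subgraph copies edge attrs shallowly; deep-copy the source sets
    for a, b in sub.graph.edges:
        sub.graph.edges[a, b]["sources"] = set(sub.graph.edges[a, b].get("sources", set()))
    return sub, coverage


def read_protein_set(path: str | Path) -> set[str]:
    """Read a protein set: one accession per line, ``#`` comments skipped."""
    out: set[str] = set()
    with Path(path).open() as fh:
        for line in fh:
            acc = line.strip()
            if acc and not acc.startswith("#"):
                out.add(acc)
    return out


def read_id_mapping(path: str | Path) -> dict[str, str]:
    """Read a two-column old-accession -> new-accession TSV."""
    mapping: dict[str, str] = {}
    with Path(path).open() as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            old, new = line.split("\t")[:2]
            mapping[old.strip()] = new.strip()
    return mapping


def write_network(network: Network, path: str | Path, fmt: str = "tsv") -> None:
    """Write a network as edge TSV (``protein_a<TAB>protein_b<TAB>sources``),
    SIF (``A pp B``) or GraphML. Edges are written in lexicographic order so
    output is byte-stable."""
    path = Path(path)
    if fmt not in _EDGE_FORMATS:
        raise ValueError(f"unknown format {fmt!r}; expected one of {_EDGE_FORMATS}")
    ordered = sorted(tuple(sorted((a, b))) for a, b in network.graph.edges)
    if fmt == "tsv":
        with path.open("w") as fh:
            fh.write("#protein_a\tprotein_b\tsources\n")
            for a, b in ordered:
                srcs = ",".join(sorted(network.edge_sources(a, b)))
                fh.write(f"{a}\t{b}\t{srcs}\n")
            for node in sorted(nx.isolates(network.graph)):
                fh.write(f"#node\t{node}\n")
    elif fmt == "sif":
        with path.open("w") as fh:
            for a, b in ordered:
                fh.write(f"{a} pp {b}\n")
            for node in sorted(nx.isolates(network.graph)):
                fh.write(f"{node}\n")
    else:  # graphml
        g = nx.Graph()
        g.add_nodes_from(network.graph.nodes)
        for a, b in network.graph.edges:
            g.add_edge(a, b, sources=",".join(sorted(network.edge_sources(a, b))))
        nx.write_graphml(g, path)


def read_network(path: str | Path, fmt: str = "tsv") -> Network:
    """Read a network previously written by :func:`write_network`."""
    path = Path(path)
    if fmt not in _EDGE_FORMATS:
        raise ValueError(f"unknown format {fmt!r}; expected one of {_EDGE_FORMATS}")
    if fmt == "tsv":
        net = Network()
        with path.open() as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line.strip():
                    continue
                if line.startswith("#node\t"):
                    net.graph.add_node(line.split("\t")[1])
                    continue
                if line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 2:
                    raise ValueError(f"{path}:{lineno}: malformed edge row {line!r}")
                a, b = parts[0], parts[1]
                srcs = parts[2].split(",") if len(parts) > 2 and parts[2] else []
                net.add_edge(a, b)
                for s in srcs:
                    net.graph.edges[a, b]["sources"].add(s)
        return net
    if fmt == "sif":
        net = Network()
        with path.open() as fh:
            for line in fh:
                parts = line.split()
                if len(parts) == 3 and parts[1] == "pp":
                    net.add_edge(parts[0], parts[2])
                elif len(parts) == 1:
                    net.graph.add_node(parts[0])
        return net
    g = nx.read_graphml(path)
    net = Network()
    net.graph.add_nodes_from(g.nodes)
    for a, b, data in g.edges(data=True):
        srcs = [s for s in str(data.get("sources", "")).split(",") if s]
        net.add_edge(a, b)
        for s in srcs:
            net.graph.edges[a, b]["sources"].add(s)
    return net
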