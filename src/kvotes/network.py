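"""Undirected interaction networks over string gene identifiers.

An :class:`InteractionNetwork` is a named simple undirected graph whose
vertices are gene/protein identifiers (opaque string tokens, typically
Entrez IDs).  Edges are stored canonically as lexicographically ordered
pairs; self-loops and duplicate edges are dropped on ingest, so every
network satisfies simple-graph semantics by construction.  The vertex set
of a network read from an edge list is exactly the set of edge endpoints
unless an explicit vertex list is supplied.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping
from pathlib import Path
from typing import Union

import networkx as nx

__all__ = [
    "InteractionNetwork",
    "NetworkEnsemble",
    "canonical_edge",
    "read_edge_list",
    "write_edge_list",
    "read_id_mapping",
    "apply_id_mapping",
]

#: An edge in canonical form: a pair (u, v) of vertex ids with u < v.
Edge = tuple[str, str]

_HEADER_TOKENS = {"protein_a", "protein_b", "gene_a", "gene_b", "source", "target"}


class ParseError(ValueError):
    """Raised for malformed edge-list / mapping / GMT rows."""


def _check_gene_id(token: str) -> str:
    if not token or any(ch.isspace() for ch in token):
        raise ValueError(f"invalid gene identifier: {token!r}")
    return token


def canonical_edge(u: str, v: str) -> Edge:
    """Return the unordered pair {u, v} in canonical (lexicographic) order.

    Raises ValueError for a self-pair: self-interactions have no canonical
    edge because the networks are simple graphs.
    """
    if u == v:
        raise ValueError(f"self-loop {u!r}-{v!r} has no canonical form")
    return (u, v) if u < v else (v, u)


class InteractionNetwork:
    """A named simple undirected graph of interacting genes/proteins.

    Parameters
    ----------
    name:
        Label for the network (e.g. the source database name).
    edges:
        Iterable of (u, v) pairs.  Order within a pair is irrelevant;
        duplicates collapse; self-pairs are discarded.
    vertices:
        Optional explicit vertex list; endpoints of ``edges`` are always
        included in addition.
    """

    def __init__(
        self,
        name: str,
        edges: Iterable[tuple[str, str]] = (),
        vertices: Iterable[str] = (),
    ):
        g = nx.Graph()
        for v in vertices:
            g.add_node(_check_gene_id(v))
        for u, v in edges:
            _check_gene_id(u)
            _check_gene_id(v)
            if u == v:
                continue
            g.add_edge(*canonical_edge(u, v))
        self.name = name
        self.graph = g

    # -- basic queries -------------------------------------------------
    @property
    def vertices(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[Edge]:
        return {canonical_edge(u, v) for u, v in self.graph.edges}

    @property
    def n_vertices(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def has_edge(self, u: str, v: str) -> bool:
        return self.graph.has_edge(u, v)

    def degree(self, v: str) -> int:
        """Number of distinct neighbors of ``v`` (errors on unknown vertex)."""
        if v not in self.graph:
            raise KeyError(f"unknown vertex {v!r} in network {self.name!r}")
        return self.graph.degree(v)

    def neighbors(self, v: str) -> set[str]:
        if v not in self.graph:
            raise KeyError(f"unknown vertex {v!r} in network {self.name!r}")
        return set(self.graph.neighbors(v))

    def sorted_edges(self) -> list[Edge]:
        """All edges in canonical form, lexicographically sorted."""
        return sorted(self.edges)

    # -- dunder helpers ------------------------------------------------
    def __contains__(self, v: str) -> bool:
        return v in self.graph

    def __eq__(self, other) -> bool:
        if not isinstance(other, InteractionNetwork):
            return NotImplemented
        return self.vertices == other.vertices and self.edges == other.edges

    def __hash__(self):  # mutable container semantics
        raise TypeError("InteractionNetwork is not hashable")

    def __repr__(self) -> str:
        return (
            f"InteractionNetwork(name={self.name!r}, "
            f"|V|={self.n_vertices}, |E|={self.n_edges})"
        )


class NetworkEnsemble:
    """An ordered committee of uniquely named interaction networks."""

    def __init__(self, networks: Iterable[InteractionNetwork]):
        nets = list(networks)
        if not nets:
            raise ValueError("ensemble must contain at least one network")
        names = [n.name for n in nets]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate network names in ensemble: {names}")
        self.networks = nets

    @property
    def names(self) -> list[str]:
        return [n.name for n in self.networks]

    def __len__(self) -> int:
        return len(self.networks)

    def __iter__(self):
        return iter(self.networks)

    def __getitem__(self, i) -> InteractionNetwork:
        return self.networks[i]

    def __repr__(self) -> str:
        return f"NetworkEnsemble({self.names})"


# ---------------------------------------------------------------------
# Edge-list I/O
# ---------------------------------------------------------------------

def _iter_lines(path):
    with open(path, "rt", encoding="utf-8") as fh:
        yield from enumerate(fh, start=1)


def read_edge_list(
    path: Union[str, Path],
    format: str = "tsv",
    name: str | None = None,
    vertices: Iterable[str] = (),
) -> InteractionNetwork:
    """Read an undirected network from a TSV edge list or a SIF file.

    TSV rows carry the two interactors in the first two tab-separated
    columns; extra columns (interaction type, evidence codes) are ignored.
    Lines starting with ``#`` are comments, and a single leading header
    row is skipped when its first two fields look like column names
    (``protein_a``/``protein_b`` and similar).  SIF rows are
    ``source relation target [target2 ...]``; the relation token is
    ignored and multi-target rows expand to one edge per target.

    Self-loops are dropped and duplicate rows collapse, so the result is
    always a canonical simple graph.  ``vertices`` optionally adds
    isolated vertices beyond the edge endpoints.
    """
    if format not in ("tsv", "sif"):
        raise ValueError(f"unknown edge-list format {format!r}")
    path = Path(path)
    label = name if name is not None else path.stem
    edges: list[tuple[str, str]] = []
    first_data_line = True
    for lineno, raw in _iter_lines(path):
        line = raw.rstrip("\n").rstrip("\r")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split("\t") if format == "tsv" else line.split()
        if format == "sif" and len(fields) == 1:
            fields = line.split("\t")
        if len(fields) < 2:
            raise ParseError(
                f"{path}:{lineno}: expected at least 2 fields, got {len(fields)}"
            )
        if first_data_line:
            first_data_line = False
            if format == "tsv" and fields[0].strip().lower() in _HEADER_TOKENS:
                continue
        if format == "tsv":
            u, v = fields[0].strip(), fields[1].strip()
            if not u or not v:
                raise ParseError(f"{path}:{lineno}: empty interactor field")
            edges.append((u, v))
        else:  # sif: u relation v1 [v2 ...]; bare "u" rows declare a vertex
            u = fields[0].strip()
            for tgt in fields[2:]:
                tgt = tgt.strip()
                if tgt:
                    edges.append((u, tgt))
    return InteractionNetwork(label, edges, vertices=vertices)


def write_edge_list(net: InteractionNetwork, path: Union[str, Path]) -> None:
    """Write ``net`` as a two-column TSV, one canonical edge per sorted line.

    ``read_edge_list(write_edge_list(net))`` reproduces the network exactly
    (isolated vertices excepted, as they are not representable in an edge
    list).
    """
    path = Path(path)
    with open(path, "wt", encoding="utf-8") as fh:
        for u, v in net.sorted_edges():
            fh.write(f"{u}\t{v}\n")


def read_id_mapping(path: Union[str, Path]) -> dict[str, str]:
    """Read a two-column TSV mapping (source_id -> unified_id).

    Duplicate source keys are an error: the mapping must be single-valued.
    """
    mapping: dict[str, str] = {}
    path = Path(path)
    for lineno, raw in _iter_lines(path):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 2:
            raise ParseError(f"{path}:{lineno}: expected 2 fields")
        src, dst = fields[0].strip(), fields[1].strip()
        if src in mapping and mapping[src] != dst:
            raise ValueError(f"{path}:{lineno}: duplicate source id {src!r}")
        mapping[src] = dst
    return mapping


def apply_id_mapping(
    net: InteractionNetwork,
    mapping: Mapping[str, str],
    unmapped_policy: str = "keep",
) -> InteractionNetwork:
    """Re-key a network's vertices through an ID-unification table.

    Edges are re-canonicalized and deduplicated after mapping; edges whose
    endpoints collapse onto the same unified ID become self-loops and are
    removed.  Vertices absent from ``mapping`` are kept under their
    original ID (``unmapped_policy="keep"``) or dropped together with
    their incident edges (``"drop"``).
    """
    if unmapped_policy not in ("drop", "keep"):
        raise ValueError(f"unknown unmapped_policy {unmapped_policy!r}")
    edges = []
    for u, v in net.edges:
        if unmapped_policy == "drop" and (u not in mapping or v not in mapping):
            continue
        mu, mv = mapping.get(u, u), mapping.get(v, v)
        if mu != mv:
            edges.append((mu, mv))
    vertices = []
    for v in net.vertices:
        if net.degree(v) == 0:  # keep explicit isolated vertices, mapped
            if v in mapping:
                vertices.append(mapping[v])
            elif unmapped_policy == "keep":
                vertices.append(v)
    return InteractionNetwork(net.name, edges, vertices=vertices)
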