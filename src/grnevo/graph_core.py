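"""Graph data model for weighted, partially directed gene networks.

A gene regulatory network mixes strictly directed regulatory edges
(e.g. transcription factor -> target) with undirected association edges.
Internally every edge is stored as directed arcs: an undirected edge
between ``a`` and ``b`` becomes the two reciprocal arcs ``a->b`` and
``b->a`` sharing one weight.  All downstream computations (modularity,
centrality, efficiency) operate on this arc representation.

Distances are unweighted hop counts by default: edge weights in these
networks are confidence scores, not lengths.  A weighted mode that maps
weight ``w`` to length ``1/w`` is available but non-default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import networkx as nx
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

__all__ = [
    "GeneNetwork",
    "DistanceOracle",
    "GraphValidationError",
    "EdgeListParseError",
    "load_edge_list",
    "write_edge_list",
    "shortest_path_distances",
]

UNREACHABLE = np.inf


class GraphValidationError(ValueError):
    """An edge or graph violates a structural invariant (self-loop, bad weight)."""


class EdgeListParseError(ValueError):
    """A row of an edge-list file could not be parsed; the message names the line."""


def canonical_symbol(gene: str) -> str:
    """Canonicalize a gene symbol: strip surrounding whitespace and uppercase."""
    s = str(gene).strip().upper()
    if not s:
        raise GraphValidationError("empty gene symbol")
    return s


class GeneNetwork:
    """Weighted, partially directed graph over gene symbols.

    Arcs carry a positive ``weight`` and a boolean ``directed`` flag;
    ``directed=False`` marks the two reciprocal arcs of an undirected edge.
    """

    def __init__(self) -> None:
        self._g = nx.DiGraph()

    # -- construction -------------------------------------------------

    def add_node(self, gene: str) -> str:
        gene = canonical_symbol(gene)
        self._g.add_node(gene)
        return gene

    def add_edge(
        self,
        source: str,
        target: str,
        weight: float = 1.0,
        directed: bool = True,
        merge: str = "max",
    ) -> None:
        """Add one edge; undirected edges are expanded to reciprocal arcs.

        Duplicate arcs are merged by ``merge`` ('max', 'sum', or 'error').
        An arc becomes undirected if any contributing edge was undirected
        (an undirected edge implies both arcs exist).
        """
        u = canonical_symbol(source)
        v = canonical_symbol(target)
        if u == v:
            raise GraphValidationError(f"self-loop on gene {u!r} is not allowed")
        w = float(weight)
        if not np.isfinite(w) or w <= 0:
            raise GraphValidationError(
                f"edge {u}->{v}: weight must be strictly positive, got {weight!r}"
            )
        self._add_arc(u, v, w, directed, merge)
        if not directed:
            self._add_arc(v, u, w, directed, merge)

    def _add_arc(self, u: str, v: str, w: float, directed: bool, merge: str) -> None:
        if self._g.has_edge(u, v):
            if merge == "error":
                raise GraphValidationError(f"duplicate edge {u}->{v}")
            old = self._g[u][v]
            if merge == "sum":
                old["weight"] = old["weight"] + w
            elif merge == "max":
                old["weight"] = max(old["weight"], w)
            else:
                raise ValueError(f"unknown merge rule {merge!r}")
            old["directed"] = old["directed"] and directed
        else:
            self._g.add_edge(u, v, weight=w, directed=directed)

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple],
        default_directed: bool = True,
        merge: str = "max",
    ) -> "GeneNetwork":
        """Build a network from (source, target[, weight[, directed]]) tuples."""
        g = cls()
        for e in edges:
            source, target = e[0], e[1]
            weight = e[2] if len(e) > 2 else 1.0
            directed = e[3] if len(e) > 3 else default_directed
            g.add_edge(source, target, weight=weight, directed=bool(directed), merge=merge)
        return g

    def copy(self) -> "GeneNetwork":
        other = GeneNetwork()
        other._g = self._g.copy()
        return other

    # -- basic queries -------------------------------------------------

    @property
    def nodes(self) -> list[str]:
        """Node symbols in sorted order (the canonical matrix order)."""
        return sorted(self._g.nodes)

    @property
    def n(self) -> int:
        return self._g.number_of_nodes()

    @property
    def m(self) -> float:
        """Total arc weight (each undirected edge contributes twice)."""
        return float(sum(d["weight"] for _, _, d in self._g.edges(data=True)))

    @property
    def n_arcs(self) -> int:
        return self._g.number_of_edges()

    def __contains__(self, gene: str) -> bool:
        return gene in self._g

    def has_arc(self, u: str, v: str) -> bool:
        return self._g.has_edge(u, v)

    def arcs(self) -> Iterator[tuple[str, str, float, bool]]:
        """Iterate over all arcs as (source, target, weight, directed)."""
        for u, v, d in self._g.edges(data=True):
            yield u, v, d["weight"], d["directed"]

    def directed_arcs(self) -> list[tuple[str, str, float]]:
        """Strictly directed arcs (no undirected partner)."""
        return [(u, v, d["weight"]) for u, v, d in self._g.edges(data=True) if d["directed"]]

    def undirected_edges(self) -> list[tuple[str, str, float]]:
        """Undirected edges, each reported once with u < v."""
        return [
            (u, v, d["weight"])
            for u, v, d in self._g.edges(data=True)
            if not d["directed"] and u < v
        ]

    def out_degree(self, gene: str | None = None):
        if gene is not None:
            return self._g.out_degree(gene)
        return dict(self._g.out_degree())

    def in_degree(self, gene: str | None = None):
        if gene is not None:
            return self._g.in_degree(gene)
        return dict(self._g.in_degree())

    # -- exports -------------------------------------------------------

    def node_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.nodes)}

    def adjacency(self, weighted: bool = True) -> csr_matrix:
        """Arc adjacency W[i, j] = weight of arc i->j in sorted node order."""
        idx = self.node_index()
        rows, cols, vals = [], [], []
        for u, v, w, _ in self.arcs():
            rows.append(idx[u])
            cols.append(idx[v])
            vals.append(w if weighted else 1.0)
        n = self.n
        return csr_matrix((vals, (rows, cols)), shape=(n, n))

    def to_networkx(self) -> nx.DiGraph:
        """The arc-level directed view (a copy)."""
        return self._g.copy()

    def to_igraph(self):
        """Directed igraph view in sorted node order, with arc weights."""
        import igraph

        nodes = self.nodes
        idx = {g: i for i, g in enumerate(nodes)}
        edges, weights = [], []
        for u, v, w, _ in self.arcs():
            edges.append((idx[u], idx[v]))
            weights.append(w)
        ig = igraph.Graph(n=len(nodes), edges=edges, directed=True)
        ig.vs["name"] = nodes
        ig.es["weight"] = weights
        return ig

    def as_undirected(self) -> "GeneNetwork":
        """Copy with every arc converted to an undirected edge."""
        g = GeneNetwork()
        for u, v, w, _ in self.arcs():
            if not g.has_arc(u, v):
                g.add_edge(u, v, weight=w, directed=False)
        return g

    def __repr__(self) -> str:  # pragma: no cover
        return f"GeneNetwork(n={self.n}, arcs={self.n_arcs}, m={self.m:g})"


# -- distances ---------------------------------------------------------


@dataclass
class DistanceOracle:
    """Shortest-path distances d(i, j) = distance from source j to target i.

    ``matrix[k, t]`` holds the distance from ``sources[k]`` to node
    ``nodes[t]``; unreachable pairs are ``inf``.
    """

    nodes: list[str]
    sources: list[str]
    matrix: np.ndarray
    _node_idx: dict[str, int] = field(repr=False, default_factory=dict)
    _src_idx: dict[str, int] = field(repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        self._node_idx = {g: i for i, g in enumerate(self.nodes)}
        self._src_idx = {g: i for i, g in enumerate(self.sources)}

    def d(self, target: str, source: str) -> float:
        """Distance from ``source`` to ``target`` (inf if unreachable)."""
        try:
            r = self._src_idx[source]
        except KeyError:
            raise KeyError(f"gene {source!r} is not a source of this oracle") from None
        try:
            c = self._node_idx[target]
        except KeyError:
            raise KeyError(f"unknown gene {target!r}") from None
        return float(self.matrix[r, c])


def shortest_path_distances(
    g: GeneNetwork,
    sources: Sequence[str] | None = None,
    weighted: bool = False,
) -> DistanceOracle:
    """BFS hop-count distances from each source to every node.

    Distances follow arc directions on the full network.  With
    ``weighted=True``, arc weight ``w`` is treated as length ``1/w`` and
    Dijkstra is used instead of BFS.
    """
    nodes = g.nodes
    idx = {x: i for i, x in enumerate(nodes)}
    if sources is None:
        src_list = nodes
    else:
        src_list = [canonical_symbol(s) for s in sources]
        for s in src_list:
            if s not in idx:
                raise KeyError(f"unknown source gene {s!r}")
    adj = g.adjacency(weighted=weighted)
    if weighted:
        adj = adj.copy()
        adj.data = 1.0 / adj.data
    indices = np.array([idx[s] for s in src_list], dtype=np.intp)
    mat = shortest_path(
        adj, method="D", directed=True, unweighted=not weighted, indices=indices
    )
    mat = np.atleast_2d(mat)
    return DistanceOracle(nodes=nodes, sources=src_list, matrix=mat)


# -- edge-list I/O -----------------------------------------------------

_TRUTHY = {"1", "true", "t", "yes"}
_FALSY = {"0", "false", "f", "no"}


def load_edge_list(
    path,
    default_directed: bool = True,
    merge: str = "max",
) -> GeneNetwork:
    """Read a TSV edge list with header ``source  target  [weight]  [directed]``.

    Missing ``weight`` defaults to 1; missing ``directed`` defaults to
    ``default_directed``.  Duplicate arcs merge by ``merge`` (default: keep
    the maximum weight).  Malformed rows raise :class:`EdgeListParseError`
    naming the offending line.
    """
    g = GeneNetwork()
    with open(path) as fh:
        header: list[str] | None = None
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = [f.strip().lower() for f in fields]
                if "source" not in header or "target" not in header:
                    raise EdgeListParseError(
                        f"line {lineno}: header must contain 'source' and 'target' columns"
                    )
                col = {name: i for i, name in enumerate(header)}
                continue
            if len(fields) < len([c for c in ("source", "target") if c in col]):
                raise EdgeListParseError(f"line {lineno}: too few fields")
            try:
                source = fields[col["source"]]
                target = fields[col["target"]]
            except IndexError:
                raise EdgeListParseError(f"line {lineno}: too few fields") from None
            weight = 1.0
            if "weight" in col and col["weight"] < len(fields) and fields[col["weight"]].strip():
                try:
                    weight = float(fields[col["weight"]])
                except ValueError:
                    raise EdgeListParseError(
                        f"line {lineno}: non-numeric weight {fields[col['weight']]!r}"
                    ) from None
            directed = default_directed
            if (
                "directed" in col
                and col["directed"] < len(fields)
                and fields[col["directed"]].strip()
            ):
                tok = fields[col["directed"]].strip().lower()
                if tok in _TRUTHY:
                    directed = True
                elif tok in _FALSY:
                    directed = False
                else:
                    raise EdgeListParseError(
                        f"line {lineno}: directed flag must be 0/1, got {tok!r}"
                    )
            try:
                g.add_edge(source, target, weight=weight, directed=directed, merge=merge)
            except GraphValidationError as exc:
                raise GraphValidationError(f"line {lineno}: {exc}") from None
        if header is None:
            raise EdgeListParseError("empty edge-list file (header required)")
    return g


def write_edge_list(g: GeneNetwork, path, header_comment: str | None = None) -> None:
    """Write the network as a TSV edge list (undirected edges written once)."""
    with open(path, "w") as fh:
        if header_comment:
            for ln in header_comment.splitlines():
                fh.write(f"# {ln}\n")
        fh.write("source\ttarget\tweight\tdirected\n")
        for u, v, w, directed in sorted(g.arcs()):
            if not directed and u > v:
                continue  # reciprocal arc of an undirected edge already written
            fh.write(f"{u}\t{v}\t{w:g}\t{int(directed)}\n")
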