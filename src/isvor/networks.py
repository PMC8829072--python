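"""Contact-network substrates for the agent-based rumor simulation.

Two random-graph families stand in for real social topologies: the
Watts–Strogatz small-world graph (uniform degree, short paths) and the
Barabási–Albert scale-free graph (heavy-tailed degree, hubs).  Generation is
delegated to :mod:`networkx`; graphs are then frozen into a light immutable
:class:`Graph` whose CSR adjacency feeds the vectorized simulator.

Node ids are 0-based everywhere, including in edge-list files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Literal

import networkx as nx
import numpy as np
import scipy.sparse as sp

from .errors import FormatError, ParameterError

__all__ = [
    "Graph",
    "NetworkSpec",
    "generate_ws",
    "generate_ba",
    "generate",
    "degree_summary",
    "read_edgelist",
    "write_edgelist",
    "ring_graph",
    "path_graph",
    "complete_graph",
    "star_graph",
]


def _canonical_edges(edges: Iterable[tuple[int, int]], n: int) -> np.ndarray:
    """Validate and canonicalize an edge collection: 0-based ids, no
    self-loops, no duplicates; each edge stored as (min, max) and the array
    sorted lexicographically."""
    arr = np.asarray(sorted({(min(u, v), max(u, v)) for u, v in edges}), dtype=np.int64)
    if arr.size == 0:
        return arr.reshape(0, 2)
    if arr.min() < 0 or arr.max() >= n:
        raise ParameterError(
            f"edge endpoint outside node range 0..{n - 1}"
        )
    if np.any(arr[:, 0] == arr[:, 1]):
        raise ParameterError("self-loops are not allowed")
    return arr


@dataclass(frozen=True)
class Graph:
    """Undirected simple graph on nodes ``0..n_nodes-1``.

    ``edges`` is a canonical ``(E, 2)`` integer array with ``u < v`` per row,
    rows sorted.  ``provenance`` records the generator and its parameters.
    """

    n_nodes: int
    edges: np.ndarray
    provenance: dict[str, Any] = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if self.n_nodes <= 0:
            raise ParameterError("graph must have at least one node")
        object.__setattr__(
            self, "edges", _canonical_edges(map(tuple, np.atleast_2d(self.edges)
                                                if len(self.edges) else []),
                                            self.n_nodes)
        )

    @property
    def n_edges(self) -> int:
        return int(self.edges.shape[0])

    def adjacency(self) -> sp.csr_matrix:
        """Symmetric CSR adjacency with 0/1 entries (cached)."""
        cached = self.__dict__.get("_adj")
        if cached is None:
            e = self.edges
            ones = np.ones(2 * len(e), dtype=np.int64)
            rows = np.concatenate([e[:, 0], e[:, 1]])
            cols = np.concatenate([e[:, 1], e[:, 0]])
            cached = sp.csr_matrix(
                (ones, (rows, cols)), shape=(self.n_nodes, self.n_nodes)
            )
            self.__dict__["_adj"] = cached
        return cached

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_nodes, dtype=np.int64)
        if self.n_edges:
            np.add.at(deg, self.edges[:, 0], 1)
            np.add.at(deg, self.edges[:, 1], 1)
        return deg

    def edge_set(self) -> set[tuple[int, int]]:
        return {tuple(row) for row in self.edges.tolist()}

    @classmethod
    def from_networkx(cls, g: nx.Graph, provenance: dict[str, Any] | None = None) -> "Graph":
        n = g.number_of_nodes()
        mapping = {node: i for i, node in enumerate(sorted(g.nodes()))}
        edges = [(mapping[u], mapping[v]) for u, v in g.edges()]
        return cls(n, np.asarray(edges, dtype=np.int64).reshape(-1, 2),
                   provenance or {})

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        g.add_edges_from(map(tuple, self.edges))
        return g


@dataclass(frozen=True)
class NetworkSpec:
    """Declarative description of a network substrate.

    family ``ws``: Watts–Strogatz with ring-lattice degree ``ws_k`` and
    rewiring probability ``ws_p``; family ``ba``: Barabási–Albert with
    ``ba_m`` edges per new node; ``edgelist`` loads ``path``.
    """

    family: Literal["ws", "ba", "edgelist"]
    n: int = 2000
    ws_k: int = 10
    ws_p: float = 0.4
    ba_m: int = 5
    path: str | None = None

    def __post_init__(self) -> None:
        if self.family not in ("ws", "ba", "edgelist"):
            raise ParameterError(f"unknown network family {self.family!r}")
        if self.family == "ws":
            if self.ws_k % 2 or not (2 <= self.ws_k < self.n):
                raise ParameterError(
                    f"ws_k={self.ws_k} must be even and in [2, n)"
                )
            if not (0.0 <= self.ws_p <= 1.0):
                raise ParameterError(f"ws_p={self.ws_p} outside [0, 1]")
        if self.family == "ba" and not (1 <= self.ba_m < self.n):
            raise ParameterError(f"ba_m={self.ba_m} must satisfy 1 <= m < n")
        if self.family == "edgelist" and self.path is None:
            raise ParameterError("edgelist family requires a path")

    def realize(self, seed: int | None = None) -> Graph:
        if self.family == "ws":
            return generate_ws(self.n, self.ws_k, self.ws_p, seed)
        if self.family == "ba":
            return generate_ba(self.n, self.ba_m, seed)
        return read_edgelist(self.path)  # type: ignore[arg-type]


def generate(spec: NetworkSpec, seed: int | None = None) -> Graph:
    """Realize a :class:`NetworkSpec` into a concrete graph."""
    return spec.realize(seed)


def generate_ws(n: int, k: int, p: float, seed: int | None = None) -> Graph:
    """Watts–Strogatz small-world graph.

    Ring lattice where each node links to its ``k`` nearest neighbors
    (``k/2`` each side), then every lattice edge is rewired with probability
    ``p``.  Rewiring preserves the edge count, so ``|E| = n*k/2`` exactly and
    the mean degree is ``k``.
    """
    if k % 2 or not (2 <= k < n):
        raise ParameterError(f"k={k} must be even and satisfy 2 <= k < n={n}")
    if not (0.0 <= p <= 1.0):
        raise ParameterError(f"p={p} outside [0, 1]")
    g = nx.watts_strogatz_graph(n, k, p, seed=seed)
    return Graph.from_networkx(
        g, {"generator": "ws", "n": n, "k": k, "p": p, "seed": seed}
    )


def generate_ba(n: int, m: int, seed: int | None = None) -> Graph:
    """Barabási–Albert scale-free graph.

    Preferential attachment from an initial star of ``m + 1`` nodes; each of
    the remaining ``n - m - 1`` nodes attaches ``m`` edges preferentially by
    degree.  Mean degree approaches ``2m`` for large ``n``; the power-law
    degree tail is emergent, not enforced.
    """
    if not (1 <= m < n):
        raise ParameterError(f"m={m} must satisfy 1 <= m < n={n}")
    initial = nx.star_graph(m)  # m + 1 nodes
    if n == m + 1:
        g = initial
    else:
        g = nx.barabasi_albert_graph(n, m, seed=seed, initial_graph=initial)
    return Graph.from_networkx(
        g, {"generator": "ba", "n": n, "m": m, "seed": seed}
    )


def degree_summary(g: Graph) -> dict[str, Any]:
    """Mean degree, max degree, and the degree histogram of ``g``."""
    deg = g.degrees()
    values, counts = np.unique(deg, return_counts=True)
    return {
        "mean_degree": 2.0 * g.n_edges / g.n_nodes,
        "max_degree": int(deg.max()),
        "degree_histogram": {int(v): int(c) for v, c in zip(values, counts)},
    }


_EDGELIST_HEADER = "# isvor edge list: 0-based node ids, one 'u v' pair per line\n"


def write_edgelist(g: Graph, path: str | Path) -> None:
    """Write ``g`` as whitespace-separated 0-based node pairs, one per line."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(_EDGELIST_HEADER)
        fh.write(f"# n_nodes {g.n_nodes}\n")
        for u, v in g.edges.tolist():
            fh.write(f"{u} {v}\n")


def read_edgelist(path: str | Path) -> Graph:
    """Read an edge list written by :func:`write_edgelist` or any file of
    whitespace-separated integer pairs (``#`` lines ignored)."""
    path = Path(path)
    edges: list[tuple[int, int]] = []
    n_declared: int | None = None
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if line.startswith("#"):
                parts = line[1:].split()
                if parts[:1] == ["n_nodes"] and len(parts) == 2:
                    n_declared = int(parts[1])
                continue
            if not line:
                continue
            parts = line.split()
            if len(parts) != 2:
                raise FormatError(
                    f"{path}:{lineno}: expected two integers, got {line!r}"
                )
            try:
                u, v = int(parts[0]), int(parts[1])
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: non-integer node id in {line!r}"
                ) from None
            if u == v:
                raise FormatError(f"{path}:{lineno}: self-loop {u}-{v}")
            if u < 0 or v < 0:
                raise FormatError(f"{path}:{lineno}: negative node id")
            edges.append((u, v))
    if not edges and n_declared is None:
        raise FormatError(f"{path}: no edges and no n_nodes header")
    n = n_declared if n_declared is not None else 1 + max(max(e) for e in edges)
    return Graph(n, np.asarray(edges, dtype=np.int64).reshape(-1, 2),
                 {"generator": "edgelist", "path": str(path)})


# ---------------------------------------------------------------------------
# Deterministic fixture graphs for exact tests.

def ring_graph(n: int) -> Graph:
    """Cycle of ``n`` nodes (WS lattice with k=2, p=0)."""
    edges = [(i, (i + 1) % n) for i in range(n)]
    return Graph(n, np.asarray(edges), {"generator": "ring", "n": n})


def path_graph(n: int) -> Graph:
    edges = [(i, i + 1) for i in range(n - 1)]
    return Graph(n, np.asarray(edges).reshape(-1, 2),
                 {"generator": "path", "n": n})


def complete_graph(n: int) -> Graph:
    edges = [(i, j) for i in range(n) for j in range(i + 1, n)]
    return Graph(n, np.asarray(edges), {"generator": "complete", "n": n})


def star_graph(n: int) -> Graph:
    """Node 0 at the center, n-1 leaves."""
    edges = [(0, i) for i in range(1, n)]
    return Graph(n, np.asarray(edges).reshape(-1, 2),
                 {"generator": "star", "n": n})
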