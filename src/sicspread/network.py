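"""Graph construction, edge-list I/O and spectral utilities.

Networks are undirected by default, with 0-based integer node ids and no
self-loops. The adjacency matrix convention follows the spreading equations:
``A[j, i] = 1`` iff there is an edge from node *i* towards node *j*, so that
column *i* lists the neighbours that can transmit to *i* (for undirected
networks the matrix is symmetric and the distinction is moot).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla


class ParameterError(ValueError):
    """Invalid model or generator parameter."""


class EdgeListParseError(ValueError):
    """Malformed edge-list file."""


@dataclass(frozen=True)
class Network:
    """An unweighted graph on nodes ``0..n-1``.

    Parameters
    ----------
    n : int
        Number of nodes (``>= 1``).
    edges : frozenset of (int, int)
        Unordered node pairs for undirected graphs; ordered ``(u, v)``
        (meaning u -> v) pairs for directed graphs. No self-loops.
    directed : bool
        Whether edge pairs are interpreted as directed.
    """

    n: int
    edges: frozenset = field(default_factory=frozenset)
    directed: bool = False

    def __post_init__(self):
        if self.n < 1:
            raise ParameterError(f"node count must be >= 1, got {self.n}")
        for u, v in self.edges:
            if u == v:
                raise ParameterError(f"self-loop on node {u} is not allowed")
            if not (0 <= u < self.n and 0 <= v < self.n):
                raise ParameterError(f"edge ({u}, {v}) outside node range 0..{self.n - 1}")

    @property
    def adjacency(self) -> sp.csr_matrix:
        """Sparse 0/1 adjacency matrix with ``A[j, i] = 1`` iff i -> j."""
        if not self.edges:
            return sp.csr_matrix((self.n, self.n))
        us, vs = zip(*self.edges)
        rows = np.asarray(vs)  # A[j, i]: edge i -> j
        cols = np.asarray(us)
        if not self.directed:
            rows, cols = np.concatenate([rows, cols]), np.concatenate([cols, rows])
        data = np.ones(len(rows))
        a = sp.csr_matrix((data, (rows, cols)), shape=(self.n, self.n))
        a.data[:] = 1.0  # collapse duplicates
        return a

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def degrees(self) -> np.ndarray:
        return np.asarray(self.adjacency.sum(axis=0)).ravel()

    def neighbors(self, i: int) -> np.ndarray:
        """Nodes that can transmit to node *i* (in-neighbours if directed)."""
        return self.adjacency[:, [i]].tocoo().row


def _canon(u: int, v: int) -> tuple:
    return (u, v) if u < v else (v, u)


def generate_ba(n: int, m: int, seed: int) -> Network:
    """Barabási–Albert preferential-attachment graph.

    Starts from ``m`` isolated nodes; each subsequent node attaches to ``m``
    distinct existing nodes drawn with probability proportional to degree
    plus a small constant (so the degenerate all-zero start is well defined).
    The resulting edge count is exactly ``m * (n - m)``.
    """
    if m < 1 or m >= n:
        raise ParameterError(f"need 1 <= m < n, got m={m}, n={n}")
    rng = np.random.default_rng(seed)
    degree = np.zeros(n)
    edges = set()
    eps = 1e-9
    for new in range(m, n):
        weights = degree[:new] + eps
        targets = rng.choice(new, size=m, replace=False, p=weights / weights.sum())
        for t in targets:
            edges.add(_canon(new, int(t)))
            degree[new] += 1
            degree[t] += 1
    return Network(n=n, edges=frozenset(edges))


def generate_fixture(kind: str, size: int) -> Network:
    """Canonical test graphs: ``complete``, ``star``, ``path`` or ``ring``.

    For ``star``, *size* counts all nodes (centre + leaves); node 0 is the
    centre.
    """
    if size < 2:
        raise ParameterError(f"fixture size must be >= 2, got {size}")
    if kind == "complete":
        edges = {(i, j) for i in range(size) for j in range(i + 1, size)}
    elif kind == "star":
        edges = {(0, i) for i in range(1, size)}
    elif kind == "path":
        edges = {(i, i + 1) for i in range(size - 1)}
    elif kind == "ring":
        edges = {(i, (i + 1) % size) for i in range(size)}
        edges = {_canon(u, v) for u, v in edges}
    else:
        raise ParameterError(f"unknown fixture kind {kind!r}")
    return Network(n=size, edges=frozenset(edges))


def read_edgelist(path, directed: bool = False) -> Network:
    """Read a whitespace-delimited integer edge list.

    One ``u v`` pair per line; blank lines and lines starting with ``#`` are
    ignored; duplicate edges collapse; self-loops are rejected. Node count is
    ``max id + 1``.
    """
    edges = set()
    max_id = -1
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.split()
            if len(tokens) != 2:
                raise EdgeListParseError(f"{path}:{lineno}: expected two tokens, got {len(tokens)}")
            try:
                u, v = int(tokens[0]), int(tokens[1])
            except ValueError:
                raise EdgeListParseError(f"{path}:{lineno}: non-integer token in {line!r}") from None
            if u < 0 or v < 0:
                raise EdgeListParseError(f"{path}:{lineno}: negative node id")
            if u == v:
                raise ParameterError(f"{path}:{lineno}: self-loop on node {u}")
            edges.add((u, v) if directed else _canon(u, v))
            max_id = max(max_id, u, v)
    if max_id < 0:
        raise EdgeListParseError(f"{path}: no edges found")
    return Network(n=max_id + 1, edges=frozenset(edges), directed=directed)


def write_edgelist(net: Network, path) -> None:
    with open(path, "w") as fh:
        fh.write("# u v (0-based node ids)\n")
        for u, v in sorted(net.edges):
            fh.write(f"{u} {v}\n")


def is_connected(net: Network) -> bool:
    if net.n == 1:
        return True
    ncomp, _ = sp.csgraph.connected_components(net.adjacency, directed=net.directed)
    return ncomp == 1


def spectral_radius(net: Network, tol: float = 1e-10) -> float:
    """Largest eigenvalue of the adjacency matrix.

    By Perron–Frobenius the leading eigenvalue of a connected undirected
    graph is a positive real. Warns (does not fail) on disconnected input;
    returns 0 for an empty edge set.
    """
    if not net.edges:
        warnings.warn("network has no edges; spectral radius is 0", stacklevel=2)
        return 0.0
    if not is_connected(net):
        warnings.warn("network is not connected; spectral radius refers to the full graph", stacklevel=2)
    a = net.adjacency
    if net.directed:
        return float(np.max(np.abs(np.linalg.eigvals(a.toarray()))))
    if net.n <= 64:
        return float(np.max(np.linalg.eigvalsh(a.toarray())))
    vals = spla.eigsh(a, k=1, which="LA", tol=tol, return_eigenvectors=False)
    return float(vals[0])
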