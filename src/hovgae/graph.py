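"""Graph container, edge-list I/O and symmetric normalization.

A protein-protein interaction network is held as an undirected, unweighted
graph: an ordered list of string node labels plus a sparse symmetric binary
adjacency matrix with an all-zero diagonal.  Self-loops are never stored;
they are added transiently (``A + I``) inside :func:`normalize_adjacency`
and inside the reconstruction target of the model, which is where the
"every node is connected to itself" convention is actually needed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

__all__ = ["Graph", "read_edge_list", "write_edge_list", "normalize_adjacency", "density"]


@dataclass
class Graph:
    """Undirected unweighted graph over string-labelled nodes.

    Attributes
    ----------
    node_ids:
        Node labels in a fixed order; all matrices use this order.
    A:
        ``n x n`` sparse symmetric binary adjacency (CSR), zero diagonal.
    """

    node_ids: list[str]
    A: sp.csr_matrix
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.A = sp.csr_matrix(self.A)
        self.A.eliminate_zeros()
        self._index = {label: i for i, label in enumerate(self.node_ids)}
        if len(self._index) != len(self.node_ids):
            raise ValueError("duplicate node labels")
        if self.A.shape != (self.n, self.n):
            raise ValueError("adjacency shape does not match node count")

    @property
    def n(self) -> int:
        return len(self.node_ids)

    @property
    def degrees(self) -> np.ndarray:
        """Integer degree vector d_i = sum_j a_ij (no self-loops)."""
        return np.asarray(self.A.sum(axis=1)).ravel().astype(np.int64)

    @property
    def n_edges(self) -> int:
        return int(self.A.nnz // 2)

    def index_of(self, label: str) -> int:
        try:
            return self._index[label]
        except KeyError:
            raise KeyError(f"unknown node label: {label!r}") from None

    def edge_set(self) -> set[tuple[int, int]]:
        """All edges as index pairs with i < j."""
        coo = sp.triu(self.A, k=1).tocoo()
        return set(zip(coo.row.tolist(), coo.col.tolist()))

    def has_edge(self, i: int, j: int) -> bool:
        return bool(self.A[i, j])

    @classmethod
    def from_edges(cls, node_ids: list[str], edges, n: int | None = None) -> "Graph":
        """Build from (i, j) index pairs; symmetrized, self-pairs rejected."""
        n = len(node_ids) if n is None else n
        edges = [(int(i), int(j)) for i, j in edges]
        for i, j in edges:
            if i == j:
                raise ValueError(f"self-loop ({i},{i}) not allowed")
        if edges:
            rows = np.array([i for i, j in edges] + [j for i, j in edges])
            cols = np.array([j for i, j in edges] + [i for i, j in edges])
            A = sp.csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
            A.data[:] = 1.0  # collapse duplicates
        else:
            A = sp.csr_matrix((n, n))
        return cls(node_ids=list(node_ids), A=A)


class EdgeListParseError(ValueError):
    pass


def read_edge_list(path, delimiter: str | None = None) -> Graph:
    """Read a two-column edge list into a :class:`Graph`.

    Lines starting with ``#`` are ignored.  Reversed duplicates are merged,
    repeated rows deduplicated, and self-loop rows dropped with a warning.
    Node order is first-appearance order, which fixes the label-to-index map
    used by every matrix downstream.

    Parameters
    ----------
    path:
        File with at least two delimited label columns per data line.
    delimiter:
        Column separator; ``None`` splits on any whitespace (default).
    """
    node_ids: list[str] = []
    index: dict[str, int] = {}
    edges: set[tuple[int, int]] = set()
    n_loops = 0
    n_data_lines = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(delimiter)
            if len(parts) < 2:
                raise EdgeListParseError(
                    f"{path}: line {lineno}: expected >= 2 columns, got {len(parts)}"
                )
            n_data_lines += 1
            u, v = parts[0], parts[1]
            for label in (u, v):
                if label not in index:
                    index[label] = len(node_ids)
                    node_ids.append(label)
            if u == v:
                n_loops += 1
                continue
            i, j = index[u], index[v]
            edges.add((min(i, j), max(i, j)))
    if n_data_lines == 0:
        raise EdgeListParseError(f"{path}: empty edge list")
    if n_loops:
        warnings.warn(f"{path}: dropped {n_loops} self-loop row(s)", stacklevel=2)
    return Graph.from_edges(node_ids, sorted(edges))


def write_edge_list(g: Graph, path, delimiter: str = "\t") -> None:
    """Write edges in canonical sorted form (min label first per row)."""
    rows = []
    for i, j in sorted(g.edge_set()):
        a, b = g.node_ids[i], g.node_ids[j]
        if b < a:
            a, b = b, a
        rows.append((a, b))
    rows.sort()
    with open(path, "w") as fh:
        for a, b in rows:
            fh.write(f"{a}{delimiter}{b}\n")


def normalize_adjacency(g: Graph) -> sp.csr_matrix:
    """Symmetrically normalized adjacency with self-loops.

    Returns ``D~^(-1/2) (A + I) D~^(-1/2)`` where ``D~`` is the degree
    matrix of ``A + I``.  Isolated nodes get a diagonal entry of 1 (pure
    self-influence), so the matrix is well defined on any graph and its
    eigenvalues lie in [-1, 1].
    """
    A_tilde = (g.A + sp.identity(g.n, format="csr")).tocsr()
    deg = np.asarray(A_tilde.sum(axis=1)).ravel()
    d_inv_sqrt = 1.0 / np.sqrt(deg)
    D = sp.diags(d_inv_sqrt)
    return (D @ A_tilde @ D).tocsr()


def density(g: Graph, with_self_loops: bool = True) -> float:
    """Edge density of the (loss-target) adjacency: nnz / n^2.

    With ``with_self_loops`` the diagonal counts as all-ones, matching the
    reconstruction target the balanced cross-entropy is computed against.
    Raises if the density is 0 or 1, where the balanced loss is undefined.
    """
    nnz = g.A.nnz + (g.n if with_self_loops else 0)
    d = nnz / float(g.n) ** 2
    if d <= 0.0 or d >= 1.0:
        raise ValueError(f"degenerate adjacency density d={d}; balanced loss undefined")
    return d
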