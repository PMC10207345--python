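"""Spatial adjacency graphs and the intrinsic-CAR (ICAR) precision structure.

The structured half of a BYM2 spatial random effect is an intrinsic
conditional autoregression on an undirected neighborhood graph.  Its
precision matrix is the graph Laplacian Q = D - A (degree matrix minus
adjacency), which is rank-deficient: the constant vector on every connected
component lies in its null space, so ICAR effects are used together with a
per-component sum-to-zero constraint.

The BYM2 reparameterization additionally requires the structured effect to
be scaled so that its generalized (geometric-mean) marginal variance is one;
the scaling constant for each component is computed here from the
pseudo-inverse of the component's Laplacian block.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

__all__ = [
    "AdjacencyGraph",
    "IcarPrecision",
    "build_graph",
    "read_edge_list",
    "icar_precision",
    "bym2_scaling_factor",
]

#: eigenvalues below this fraction of the largest are treated as null space
NULLSPACE_RTOL = 1e-10


@dataclass(frozen=True)
class AdjacencyGraph:
    """Undirected neighborhood structure over a fixed, ordered node set.

    Edges are stored as index pairs ``(i, j)`` with ``i < j``; the edge set
    is deduplicated and symmetric by construction and self-loops are
    rejected at build time.
    """

    node_ids: tuple
    edges: tuple

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def index(self) -> dict:
        """Mapping node id -> position in the node ordering."""
        return {nid: i for i, nid in enumerate(self.node_ids)}

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_nodes, dtype=int)
        for i, j in self.edges:
            deg[i] += 1
            deg[j] += 1
        return deg

    def adjacency(self) -> sp.csr_matrix:
        n = self.n_nodes
        if not self.edges:
            return sp.csr_matrix((n, n))
        rows = [e[0] for e in self.edges] + [e[1] for e in self.edges]
        cols = [e[1] for e in self.edges] + [e[0] for e in self.edges]
        data = np.ones(2 * len(self.edges))
        return sp.csr_matrix((data, (rows, cols)), shape=(n, n))

    def reorder(self, node_ids) -> "AdjacencyGraph":
        """Return the same graph with nodes listed in a new order.

        ``node_ids`` must be a permutation of the current node set.
        """
        if set(node_ids) != set(self.node_ids) or len(node_ids) != self.n_nodes:
            raise ValueError("new node ordering must be a permutation of the node set")
        old_index = self.index()
        perm = {old_index[nid]: k for k, nid in enumerate(node_ids)}
        edges = tuple(
            sorted(tuple(sorted((perm[i], perm[j]))) for i, j in self.edges)
        )
        return AdjacencyGraph(node_ids=tuple(node_ids), edges=edges)


@dataclass(frozen=True)
class IcarPrecision:
    """ICAR precision matrix with connectivity and BYM2 scaling metadata.

    Attributes
    ----------
    Q : scipy.sparse.csr_matrix
        Graph Laplacian, ``Q = D - A``. Row sums are exactly zero and
        ``rank(Q) = n - n_components``.
    component_labels : ndarray of int
        Connected-component label per node.
    scaling_factor : ndarray of float
        BYM2 scaling constant per component: the geometric mean of the
        marginal variances of the constrained ICAR effect on that
        component.  Components with a single node get 1 by convention.
    """

    Q: sp.csr_matrix
    component_labels: np.ndarray
    scaling_factor: np.ndarray

    @property
    def n_components(self) -> int:
        return len(self.scaling_factor)

    def node_scaling(self) -> np.ndarray:
        """Scaling constant broadcast to each node."""
        return self.scaling_factor[self.component_labels]


def build_graph(node_ids, edges) -> AdjacencyGraph:
    """Build a validated adjacency graph from node labels and label pairs.

    Edges are given as pairs of node labels; duplicates (in either
    orientation) are collapsed. Unknown labels and self-loops raise
    ``ValueError``.
    """
    node_ids = tuple(node_ids)
    if len(set(node_ids)) != len(node_ids):
        raise ValueError("node labels must be unique")
    index = {nid: i for i, nid in enumerate(node_ids)}
    edge_set = set()
    for a, b in edges:
        if a not in index:
            raise ValueError(f"edge endpoint {a!r} is not a known node label")
        if b not in index:
            raise ValueError(f"edge endpoint {b!r} is not a known node label")
        i, j = index[a], index[b]
        if i == j:
            raise ValueError(f"self-loop at node {a!r} is not allowed")
        edge_set.add((min(i, j), max(i, j)))
    return AdjacencyGraph(node_ids=node_ids, edges=tuple(sorted(edge_set)))


def read_edge_list(path, node_ids) -> AdjacencyGraph:
    """Read a tab-separated edge list file.

    One edge per line as ``node_id_1<TAB>node_id_2``; blank lines and lines
    starting with ``#`` are ignored.  The node universe is supplied
    separately (typically from the panel) so isolated nodes are
    representable.
    """
    edges = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(
                    f"{path}:{lineno}: expected two tab-separated node ids, got {line!r}"
                )
            edges.append((parts[0], parts[1]))
    return build_graph(node_ids, edges)


def write_edge_list(graph: AdjacencyGraph, path) -> None:
    with open(path, "w") as fh:
        fh.write("# edge list: node_id_1<TAB>node_id_2\n")
        for i, j in graph.edges:
            fh.write(f"{graph.node_ids[i]}\t{graph.node_ids[j]}\n")


def icar_precision(graph: AdjacencyGraph) -> IcarPrecision:
    """Assemble the ICAR precision (graph Laplacian) and its metadata.

    Results are cached per graph (graphs are immutable); repeated draws on
    the same graph skip the eigendecomposition behind the scaling constant.
    """
    return _icar_precision_cached(graph)


@lru_cache(maxsize=128)
def _icar_precision_cached(graph: AdjacencyGraph) -> IcarPrecision:
    A = graph.adjacency()
    deg = np.asarray(A.sum(axis=1)).ravel()
    Q = sp.diags(deg) - A
    Q = sp.csr_matrix(Q)
    n_comp, labels = connected_components(A, directed=False)
    if graph.n_nodes == 0:
        raise ValueError("graph has no nodes")
    icar = IcarPrecision(
        Q=Q, component_labels=labels, scaling_factor=np.ones(n_comp)
    )
    kappa = bym2_scaling_factor(icar)
    return IcarPrecision(Q=Q, component_labels=labels, scaling_factor=kappa)


def bym2_scaling_factor(icar: IcarPrecision) -> np.ndarray:
    """BYM2 scaling constant per connected component.

    For each component with >= 2 nodes, the marginal variances of the
    sum-to-zero-constrained ICAR effect are the diagonal of the
    Moore-Penrose pseudo-inverse of the component's Laplacian block (the
    null space of the block is exactly the constrained direction).  The
    scaling constant is their geometric mean,
    ``kappa = exp(mean(log(diag(Q_c^+))))``.  Singleton components have no
    structured effect and get ``kappa = 1`` by convention.
    """
    labels = icar.component_labels
    n_comp = labels.max() + 1 if labels.size else 0
    Q = icar.Q.toarray()
    kappa = np.ones(n_comp)
    for c in range(n_comp):
        idx = np.flatnonzero(labels == c)
        if idx.size < 2:
            continue
        Qc = Q[np.ix_(idx, idx)]
        evals, evecs = np.linalg.eigh(Qc)
        tol = NULLSPACE_RTOL * evals.max()
        keep = evals > tol
        if keep.sum() != idx.size - 1:
            raise ArithmeticError(
                f"component {c}: Laplacian block numerically singular beyond "
                f"its one-dimensional null space ({idx.size - keep.sum()} "
                "eigenvalues below tolerance)"
            )
        marg_var = ((evecs[:, keep] ** 2) / evals[keep]).sum(axis=1)
        kappa[c] = np.exp(np.mean(np.log(marg_var)))
    return kappa


def constrained_icar_covariance(icar: IcarPrecision, scaled: bool = True) -> np.ndarray:
    """Dense covariance of the (optionally BYM2-scaled) constrained ICAR effect.

    Used by the simulator and by oracle tests; the covariance is the
    pseudo-inverse of the Laplacian, divided per component by the scaling
    constant when ``scaled``.
    """
    Q = icar.Q.toarray()
    labels = icar.component_labels
    cov = np.zeros_like(Q)
    for c in range(icar.n_components):
        idx = np.flatnonzero(labels == c)
        if idx.size < 2:
            continue
        Qc = Q[np.ix_(idx, idx)]
        cov_c = np.linalg.pinv(Qc, hermitian=True)
        if scaled:
            cov_c = cov_c / icar.scaling_factor[c]
        cov[np.ix_(idx, idx)] = cov_c
    return cov
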