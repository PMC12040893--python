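"""Volume entropy and directed information-flow capacities on metric graphs.

An undirected thresholded correlation graph is turned into a metric graph:
each edge gets a length l(e) = 1 - r (clipped below at eps > 0), so similar
voxels are metrically close.  Unrolling the graph into its universal cover —
the infinite tree of non-backtracking paths — the volume of a geodesic ball
of radius R grows like exp(h R); the growth rate h is the volume entropy, a
topological invariant measuring the graph's total information-flow capacity.

Computationally h is found through the non-backtracking edge operator
A(h) on directed edges, with A[(u,v),(v,w)] = exp(-h l(v,w)) for w != u.
The spectral radius rho(A(h)) decreases strictly in h, and the volume entropy
is the unique h* >= 0 with rho(A(h*)) = 1, located by bisection.  At h* the
right Perron eigenvector of A(h*), normalised to sum 1, assigns each directed
edge a capacity; summing capacities of a node's incoming (outgoing) directed
edges gives its afferent (efferent) node capacity.  Afferent and efferent
capacities generally differ — the flow through a node is directional even
though the underlying measurements are symmetric correlations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.sparse import coo_matrix, csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.sparse.linalg import ArpackNoConvergence, LinearOperator, eigs

from .windows import WindowedGraphSet

logger = logging.getLogger(__name__)

__all__ = [
    "MetricGraph",
    "EdgeOperator",
    "FlowResult",
    "AcyclicGraphError",
    "to_metric_graph",
    "build_edge_operator",
    "spectral_radius",
    "solve_volume_entropy",
    "edge_capacity_matrix",
    "flow_timecourse",
]

#: Lower clip for edge lengths 1 - r, keeping all lengths strictly positive.
LENGTH_EPS = 0.05

#: Operators at or below this directed-edge count use dense eigensolves.
_DENSE_LIMIT = 600


class AcyclicGraphError(ValueError):
    """Volume entropy is undefined on trees (the universal cover is finite)."""


@dataclass
class MetricGraph:
    """Largest connected component of a thresholded channel, with lengths.

    ``edges`` holds each undirected edge once as (u, v) in local node
    indexing; directed edge 2k is u->v and 2k+1 is v->u, so |D| = 2E.
    """

    nodes: np.ndarray           # original voxel ids of the component
    edges: np.ndarray           # (E, 2) int, local indices
    lengths: np.ndarray         # (E,) float > 0
    weights: np.ndarray         # (E,) float, channel correlation magnitudes
    component_fraction: float   # |component| / n_input_nodes

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def n_directed(self) -> int:
        return 2 * self.n_edges

    def directed_endpoints(self) -> tuple[np.ndarray, np.ndarray]:
        """(tail, head) node index per directed edge id."""
        u, v = self.edges.T
        tails = np.empty(self.n_directed, dtype=int)
        heads = np.empty(self.n_directed, dtype=int)
        tails[0::2], heads[0::2] = u, v
        tails[1::2], heads[1::2] = v, u
        return tails, heads

    def directed_lengths(self) -> np.ndarray:
        return np.repeat(self.lengths, 2)

    def has_cycle(self) -> bool:
        # connected: cyclic iff E >= n
        return self.n_edges >= self.n_nodes

    def scaled(self, c: float) -> "MetricGraph":
        return MetricGraph(self.nodes, self.edges, self.lengths * c,
                           self.weights, self.component_fraction)


def to_metric_graph(
    adjacency: np.ndarray,
    weights: np.ndarray | None = None,
    eps: float = LENGTH_EPS,
    length_transform: str = "one-minus-r",
) -> MetricGraph:
    """Restrict to the largest connected component and attach edge lengths.

    The default transform is l = 1 - r clipped below at ``eps`` (similarity
    is monotonically shortening, and lengths stay strictly positive even for
    near-perfect correlations).  Alternatives: ``inverse-r`` (1/r) and
    ``neg-log-r`` (-ln r), both clipped at ``eps`` as well.
    """
    adj = np.asarray(adjacency, dtype=bool)
    n = adj.shape[0]
    if n == 0 or not adj.any():
        raise ValueError("metric graph needs a nonempty input graph")
    if weights is None:
        weights = adj.astype(float)
    weights = np.asarray(weights, dtype=float)

    n_comp, labels = connected_components(csr_matrix(adj), directed=False)
    # largest component among nodes that actually have edges
    occupied = adj.any(axis=0)
    sizes = np.bincount(labels[occupied], minlength=n_comp)
    keep = labels == np.argmax(sizes)
    keep &= occupied
    nodes = np.flatnonzero(keep)
    local = -np.ones(n, dtype=int)
    local[nodes] = np.arange(len(nodes))

    iu, ju = np.nonzero(np.triu(adj, k=1))
    sel = keep[iu] & keep[ju]
    edges = np.column_stack([local[iu[sel]], local[ju[sel]]])
    w = np.abs(weights[iu[sel], ju[sel]])

    if length_transform == "one-minus-r":
        lengths = 1.0 - w
    elif length_transform == "inverse-r":
        with np.errstate(divide="ignore"):
            lengths = np.where(w > 0, 1.0 / np.maximum(w, 1e-12), np.inf)
    elif length_transform == "neg-log-r":
        lengths = -np.log(np.clip(w, 1e-12, None))
    else:
        raise ValueError(f"unknown length transform {length_transform!r}")
    lengths = np.clip(lengths, eps, None)

    frac = len(nodes) / n
    if frac < 1.0:
        logger.info("metric graph restricted to giant component: %d/%d nodes (%.2f)",
                    len(nodes), n, frac)
    return MetricGraph(nodes=nodes, edges=edges, lengths=lengths,
                       weights=w, component_fraction=frac)


@dataclass
class EdgeOperator:
    """Non-backtracking operator structure S with directed-edge lengths.

    S is the 0/1 incidence of allowed continuations: S[i, j] = 1 iff directed
    edge j starts where i ends and j is not i's reversal.  The weighted
    operator at entropy parameter h is A(h) = S @ diag(exp(-h * l_j)), so a
    single structure matrix serves every h during the bisection.
    """

    S: csr_matrix               # (D, D) 0/1 continuation structure
    lengths: np.ndarray         # (D,) length of each directed edge
    h: float = 0.0

    @property
    def n_directed(self) -> int:
        return self.S.shape[0]

    def column_weights(self, h: float | None = None) -> np.ndarray:
        if h is None:
            h = self.h
        return np.exp(-h * self.lengths)

    def matvec(self, x: np.ndarray, h: float | None = None) -> np.ndarray:
        return self.S @ (self.column_weights(h) * x)

    def matrix(self, h: float | None = None) -> csr_matrix:
        w = self.column_weights(h)
        m = self.S.tocsr(copy=True).astype(float)
        m.data *= w[m.indices]
        return m


def build_edge_operator(g: MetricGraph, h: float = 0.0) -> EdgeOperator:
    if h < 0:
        raise ValueError("entropy parameter h must be >= 0")
    tails, heads = g.directed_endpoints()
    D = g.n_directed
    # group directed edges by tail node: j continues i iff tail(j) == head(i)
    order = np.argsort(tails, kind="stable")
    starts = np.searchsorted(tails[order], np.arange(g.n_nodes))
    ends = np.searchsorted(tails[order], np.arange(g.n_nodes) + 1)

    rows, cols = [], []
    rev = np.arange(D) ^ 1      # reversal partner: 2k <-> 2k+1
    for i in range(D):
        v = heads[i]
        out = order[starts[v]:ends[v]]
        out = out[out != rev[i]]
        rows.append(np.full(len(out), i))
        cols.append(out)
    rows = np.concatenate(rows) if rows else np.array([], dtype=int)
    cols = np.concatenate(cols) if cols else np.array([], dtype=int)
    S = coo_matrix((np.ones(len(rows), dtype=np.int8), (rows, cols)),
                   shape=(D, D)).tocsr()
    return EdgeOperator(S=S, lengths=g.directed_lengths(), h=h)


def _growth_rate(op: EdgeOperator, h: float, iters: int = 3000,
                 tail: int = 200) -> float:
    """Geometric-mean growth rate of repeated application to the ones vector.

    Robust for periodic (e.g. pure-cycle) and nilpotent operators where a
    plain power iteration would oscillate or die.
    """
    x = np.ones(op.n_directed)
    logs = []
    for _ in range(iters):
        y = op.matvec(x, h)
        nrm = np.linalg.norm(y)
        if nrm < 1e-300:
            return 0.0
        logs.append(np.log(nrm / np.linalg.norm(x)))
        x = y / nrm
        if len(logs) > 2 * tail:
            a = float(np.mean(logs[-2 * tail:-tail]))
            b = float(np.mean(logs[-tail:]))
            if abs(a - b) < 1e-12:
                break
    return float(np.exp(np.mean(logs[-tail:])))


def spectral_radius(op: EdgeOperator, h: float | None = None,
                    tol: float = 1e-10) -> float:
    """Largest-magnitude eigenvalue modulus of A(h).

    Dense eigvals for small operators (exact, handles nilpotent and periodic
    cases); ARPACK with a deterministic all-ones start for large ones, with a
    growth-rate power iteration as fallback.
    """
    if h is None:
        h = op.h
    D = op.n_directed
    if D == 0:
        return 0.0
    if D <= _DENSE_LIMIT:
        m = op.matrix(h).toarray()
        return float(np.abs(np.linalg.eigvals(m)).max())
    w = op.column_weights(h)
    lo = LinearOperator((D, D), matvec=lambda x: op.S @ (w * x), dtype=float)
    try:
        vals = eigs(lo, k=1, which="LM", v0=np.ones(D), tol=tol,
                    maxiter=50 * D, return_eigenvectors=False)
        return float(np.abs(vals[0]))
    except ArpackNoConvergence:
        logger.warning("ARPACK did not converge at h=%.6g; using growth-rate fallback", h)
        return _growth_rate(op, h)


def solve_volume_entropy(
    g: MetricGraph, tol: float = 1e-8, max_iter: int = 200,
    rho_tol: float = 1e-10,
) -> float:
    """Unique h* >= 0 with rho(A(h*)) = 1, by bisection.

    rho(A(h)) is strictly decreasing in h, so bisection on [0, h_hi] (with
    h_hi doubled until rho < 1) converges unconditionally; iteration stops
    when |rho - 1| <= tol.  Trees raise (their operator is nilpotent and
    rho = 0 for every h: the volume entropy does not exist).
    """
    if not g.has_cycle():
        raise AcyclicGraphError("volume entropy undefined (tree)")
    op = build_edge_operator(g)
    rho0 = spectral_radius(op, 0.0, rho_tol)
    if rho0 < 1.0 - tol:
        raise AcyclicGraphError(
            f"spectral radius at h=0 is {rho0:.6g} < 1; no solution with h >= 0"
        )
    if abs(rho0 - 1.0) <= tol:
        return 0.0
    hi = 1.0
    for _ in range(60):
        if spectral_radius(op, hi, rho_tol) < 1.0:
            break
        hi *= 2.0
    else:
        raise RuntimeError("failed to bracket the volume entropy")
    lo = 0.0
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        rho = spectral_radius(op, mid, rho_tol)
        if abs(rho - 1.0) <= tol:
            return mid
        if rho > 1.0:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-15 * max(1.0, hi):
            break
    return 0.5 * (lo + hi)


@dataclass
class FlowResult:
    """Volume entropy and Perron edge capacities of one window's channel."""

    h: float
    graph: MetricGraph
    capacities: np.ndarray          # (D,) nonnegative, sums to 1
    afferent: np.ndarray            # per component node, sums to 1
    efferent: np.ndarray            # per component node, sums to 1
    reducible: bool = False

    def node_capacity(self, n_voxels: int, kind: str = "afferent") -> np.ndarray:
        """Capacity lifted back to the full voxel index (0 outside the LCC)."""
        vec = {"afferent": self.afferent, "efferent": self.efferent}[kind]
        out = np.zeros(n_voxels)
        out[self.graph.nodes] = vec
        return out

    def capacity_matrix(self, dense: bool = True):
        """Asymmetric node x node capacity matrix M[u, v] = c(u -> v)."""
        tails, heads = self.graph.directed_endpoints()
        n = self.graph.n_nodes
        m = coo_matrix((self.capacities, (tails, heads)), shape=(n, n))
        return m.toarray() if dense else m.tocsr()


def _perron_vector(op: EdgeOperator, h: float, tol: float) -> np.ndarray:
    """Right Perron eigenvector of A(h), normalised to sum 1.

    For a nonnegative operator the spectral radius rho is itself an
    eigenvalue (Perron-Frobenius); the dense path therefore selects the
    eigenvalue closest to +rho rather than the first of maximal modulus,
    which matters for periodic operators (pure cycles) whose spectrum has
    several eigenvalues on the circle |z| = rho.
    """
    D = op.n_directed
    if D <= _DENSE_LIMIT:
        m = op.matrix(h).toarray()
        vals, vecs = np.linalg.eig(m)
        rho = np.abs(vals).max()
        v = vecs[:, np.argmin(np.abs(vals - rho))]
        v = np.real(v)
    else:
        w = op.column_weights(h)
        lo = LinearOperator((D, D), matvec=lambda x: op.S @ (w * x), dtype=float)
        try:
            _, vecs = eigs(lo, k=1, which="LM", v0=np.ones(D), tol=tol,
                           maxiter=50 * D)
            v = np.real(vecs[:, 0])
        except ArpackNoConvergence:
            logger.warning("ARPACK eigenvector did not converge; power iteration fallback")
            v = np.ones(D)
            for _ in range(5000):
                y = op.matvec(v, h)
                nrm = np.linalg.norm(y)
                if nrm < 1e-300:
                    break
                y /= nrm
                if np.linalg.norm(y - v) < tol:
                    v = y
                    break
                v = y
    if v.sum() < 0:
        v = -v
    v = np.clip(v, 0.0, None)
    s = v.sum()
    if s <= 0:
        raise RuntimeError("degenerate Perron vector")
    return v / s


def edge_capacity_matrix(g: MetricGraph, h: float, tol: float = 1e-10) -> FlowResult:
    """Edge capacities and afferent/efferent node capacities at entropy h.

    The capacity vector is the right Perron eigenvector of A(h) normalised to
    sum 1; a node's afferent capacity sums its incoming directed edges and its
    efferent capacity its outgoing ones, so both vectors also sum to 1.  On
    reducible operators (e.g. graphs with pendant trees) the eigenvector is
    supported on edges feeding the dominant strongly connected part; this is
    flagged on the result.
    """
    op = build_edge_operator(g)
    c = _perron_vector(op, h, tol)
    tails, heads = g.directed_endpoints()
    afferent = np.bincount(heads, weights=c, minlength=g.n_nodes)
    efferent = np.bincount(tails, weights=c, minlength=g.n_nodes)
    # zero-capacity directed edges mean the operator is reducible and the
    # eigenvector lives on (edges feeding) its dominant part
    reducible = bool((c < 1e-12).any())
    if reducible:
        logger.info("reducible edge operator: capacities supported on dominant part")
    return FlowResult(h=h, graph=g, capacities=c, afferent=afferent,
                      efferent=efferent, reducible=reducible)


def solve_flow(
    adjacency: np.ndarray,
    weights: np.ndarray | None = None,
    eps: float = LENGTH_EPS,
    tol: float = 1e-8,
    length_transform: str = "one-minus-r",
) -> FlowResult:
    """Convenience: metric graph -> h* -> capacities in one call."""
    g = to_metric_graph(adjacency, weights, eps=eps,
                        length_transform=length_transform)
    h = solve_volume_entropy(g, tol=tol)
    return edge_capacity_matrix(g, h)


def flow_timecourse(
    graphset: WindowedGraphSet,
    channel: str,
    eps: float = LENGTH_EPS,
    tol: float = 1e-8,
    length_transform: str = "one-minus-r",
    window_indices: Sequence[int] | None = None,
    min_component: int = 3,
) -> dict[int, FlowResult | None]:
    """Per-window flow solves for one channel.

    Windows whose channel graph is empty, smaller than ``min_component``
    nodes, or acyclic yield None (honest gaps, not zeros).  Windows are
    independent, so any subset (``window_indices``) or evaluation order gives
    identical results.
    """
    idx = range(graphset.n_windows) if window_indices is None else window_indices
    results: dict[int, FlowResult | None] = {}
    for w in idx:
        g = graphset.graphs[w]
        adj = g.adjacency(channel)
        if not adj.any():
            logger.info("window %d (%s): empty graph, flow undefined", w, channel)
            results[w] = None
            continue
        mg = to_metric_graph(adj, g.weights(channel), eps=eps,
                             length_transform=length_transform)
        if mg.n_nodes < min_component or not mg.has_cycle():
            logger.info("window %d (%s): component too small or acyclic", w, channel)
            results[w] = None
            continue
        h = solve_volume_entropy(mg, tol=tol)
        results[w] = edge_capacity_matrix(mg, h)
    return results
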